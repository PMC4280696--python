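"""Surface-EMG processing chain for foot-sole stimulation experiments.

Two channels — tibialis anterior (TA) and soleus (SOL) — are sampled at
1200 Hz together with a plate trigger.  The chain is: 5-500 Hz band-pass,
50 Hz notch, full-wave rectification; MVC normalization (RMS in a 500 ms
window centered at the maximal voluntary contraction peak, best of three
repetitions); per-trial baseline statistics (mean + SD of the rectified
signal over the 0.8 s before stimulus onset) defining the reflex threshold;
and a run-length detector — a reflex occurred when the rectified signal
stays strictly above threshold for at least 10 ms during the 0.8 s stimulus
window.

Baseline statistics are computed on the rectified, filtered signal by
default so that threshold and burst live on the same scale (the mean of the
signed signal is ~0 and would reduce the threshold to the SD alone);
``baseline_domain="raw"`` preserves the signed-signal reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import signal

from .stimulus import ProtocolSchedule, StimulusEvent

Muscle = Literal["TA", "SOL"]
MUSCLES: tuple[Muscle, Muscle] = ("TA", "SOL")


class ProcessingError(RuntimeError):
    pass


@dataclass
class EmgRecording:
    """Two-channel EMG plus trigger on one 1200 Hz time grid."""

    times: np.ndarray
    channels: dict[str, np.ndarray]
    trigger: np.ndarray | None = None
    state: Literal["raw", "filtered", "rectified"] = "raw"

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) + 1.0 / self.sample_rate

    def to_csv(self, path) -> None:
        import pandas as pd

        trig = self.trigger if self.trigger is not None else np.zeros(len(self.times))
        pd.DataFrame(
            {
                "time": self.times,
                "ta_uv": self.channels["TA"],
                "sol_uv": self.channels["SOL"],
                "trigger": trig,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EmgRecording":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            times=df["time"].to_numpy(),
            channels={"TA": df["ta_uv"].to_numpy(), "SOL": df["sol_uv"].to_numpy()},
            trigger=df["trigger"].to_numpy(),
        )


@dataclass(frozen=True)
class MvcReference:
    """Maximal-voluntary-contraction RMS reference (µV) for one muscle."""

    muscle: Muscle
    mvc_rms: float
    window: float = 0.5
    n_repetitions: int = 3

    def __post_init__(self) -> None:
        if self.mvc_rms <= 0:
            raise ValueError("mvc_rms must be > 0")


@dataclass(frozen=True)
class BaselineStats:
    """Pre-stimulus baseline level; threshold = mean + SD."""

    muscle: Muscle
    mean: float
    sd: float
    window: float = 0.8

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def threshold(self) -> float:
        return self.mean + self.sd


@dataclass(frozen=True)
class ReflexEvent:
    """Detection outcome for one stimulus and one muscle."""

    trial: int
    muscle: Muscle
    occurred: bool
    onset_latency: float | None = None
    peak_amplitude: float = 0.0
    double_burst: bool = False
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")


@dataclass(frozen=True)
class RmsSummary:
    """Mean normalized RMS for one stimulus condition and muscle."""

    condition: tuple
    muscle: Muscle
    mean_rms: float
    n_trials: int


def design_filters(sample_rate: float, band=(5.0, 500.0), notch=50.0, q=30.0):
    """Second-order-section band-pass and notch coefficients."""
    nyq = sample_rate / 2.0
    if band[1] >= nyq:
        raise ProcessingError(
            f"band edge {band[1]} Hz requires sample rate > {2 * band[1]} Hz"
        )
    sos = signal.butter(4, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    b, a = signal.iirnotch(notch, q, fs=sample_rate)
    return sos, (b, a)


def preprocess(rec: EmgRecording, band=(5.0, 500.0), notch=50.0, q=30.0) -> EmgRecording:
    """Band-pass, notch and full-wave rectify every channel (zero-phase).

    Zero-phase (forward-backward) filtering preserves burst onset latency.
    Returns a new recording in the ``rectified`` state; the input must be
    ``raw``.
    """
    if rec.state != "raw":
        raise ProcessingError(f"preprocess expects a raw recording, got {rec.state}")
    sos, (b, a) = design_filters(rec.sample_rate, band, notch, q)
    out = {}
    for name, x in rec.channels.items():
        y = signal.sosfiltfilt(sos, np.asarray(x, float))
        y = signal.filtfilt(b, a, y)
        out[name] = np.abs(y)
    return EmgRecording(times=rec.times, channels=out, trigger=rec.trigger, state="rectified")


def rms(series: np.ndarray) -> float:
    """Root-mean-square amplitude of a sample window."""
    series = np.asarray(series, float)
    if series.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(series**2)))


def _slice(rec: EmgRecording, muscle: str, t0: float, t1: float) -> np.ndarray:
    fs = rec.sample_rate
    i0 = int(round((t0 - rec.times[0]) * fs))
    i1 = int(round((t1 - rec.times[0]) * fs))
    if i0 < 0 or i1 > len(rec.times) or i1 <= i0:
        raise ValueError(f"window [{t0}, {t1}) outside recording")
    return rec.channels[muscle][i0:i1]


def mvc_reference(trials: Sequence[EmgRecording], muscle: Muscle, window: float = 0.5) -> MvcReference:
    """MVC reference: best of the repetitions' peak-centered window RMS.

    Per repetition, the 500 ms window is centered at the maximal rectified
    sample and truncated symmetrically where it meets a recording edge.
    """
    values = []
    for rec in trials:
        if rec.state != "rectified":
            raise ProcessingError("MVC trials must be preprocessed first")
        x = rec.channels[muscle]
        fs = rec.sample_rate
        peak = int(np.argmax(x))
        half = int(round(window * fs / 2))
        half = min(half, peak, len(x) - 1 - peak)
        values.append(rms(x[peak - half : peak + half + 1]))
    return MvcReference(muscle=muscle, mvc_rms=max(values), window=window, n_repetitions=len(trials))


def baseline_stats(
    rec: EmgRecording,
    muscle: Muscle,
    onset: float,
    pre_window: float = 0.8,
    ddof: int = 1,
) -> BaselineStats:
    """Mean and SD of the pre-stimulus baseline; threshold = mean + SD."""
    if rec.state != "rectified":
        raise ProcessingError("baseline_stats expects a preprocessed recording")
    x = _slice(rec, muscle, onset - pre_window, onset)
    return BaselineStats(
        muscle=muscle,
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=ddof)) if len(x) > ddof else 0.0,
        window=pre_window,
    )


def _qualifying_runs(above: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Start/stop indices (half-open) of runs of True of length >= min_len."""
    runs = []
    start = None
    for i, v in enumerate(above):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(above) - start >= min_len:
        runs.append((start, len(above)))
    return runs


def detect_reflex(
    rec: EmgRecording,
    muscle: Muscle,
    event: StimulusEvent,
    baseline: BaselineStats,
    mvc: MvcReference | None = None,
    min_duration: float = 0.010,
    window: float = 0.8,
    double_burst_gap: float = 0.020,
    trial: int = 0,
) -> ReflexEvent:
    """Threshold/duration reflex detection in the stimulus window.

    A reflex occurred when the rectified signal is strictly above
    ``baseline.threshold`` for at least ``min_duration`` (10 ms = 12
    consecutive samples at 1200 Hz) within ``[onset, onset + window)``.
    Latency is the first sample of the first qualifying run; the peak is
    normalized to %MVC when a reference is given.  Two qualifying runs
    separated by at least ``double_burst_gap`` below threshold flag a
    double burst (withdrawal-reflex signature).
    """
    if rec.state != "rectified":
        raise ProcessingError("detect_reflex expects a preprocessed recording")
    fs = rec.sample_rate
    x = _slice(rec, muscle, event.onset, event.onset + window)
    above = x > baseline.threshold
    need = int(np.ceil(min_duration * fs))
    runs = _qualifying_runs(above, need)
    occurred = bool(runs)
    latency = runs[0][0] / fs if occurred else None
    peak = float(np.max(x)) if len(x) else 0.0
    if mvc is not None:
        peak = 100.0 * peak / mvc.mvc_rms
    gap_need = int(np.ceil(double_burst_gap * fs))
    double = any(b[0] - a[1] >= gap_need for a, b in zip(runs, runs[1:]))
    return ReflexEvent(
        trial=trial,
        muscle=muscle,
        occurred=occurred,
        onset_latency=latency,
        peak_amplitude=peak,
        double_burst=double,
    )


def reflex_occurrence(events: Sequence[ReflexEvent]) -> float:
    """Percentage of (non-excluded) trials in which a reflex occurred."""
    kept = [e for e in events if not e.excluded]
    if not kept:
        raise ValueError("no trials to score")
    return 100.0 * sum(e.occurred for e in kept) / len(kept)


def single_pulse_rms(
    rec: EmgRecording,
    muscle: Muscle,
    event: StimulusEvent,
    mvc: MvcReference,
    window: float = 0.8,
) -> float:
    """RMS over the stimulation window, as % of the MVC reference."""
    if rec.state != "rectified":
        raise ProcessingError("single_pulse_rms expects a preprocessed recording")
    if event.onset + window > rec.times[-1] + 1.0 / rec.sample_rate + 1e-9:
        raise ValueError("stimulation window truncated by recording end")
    x = _slice(rec, muscle, event.onset, event.onset + window)
    return 100.0 * rms(x) / mvc.mvc_rms


def cyclic_rms_ratio(
    rec: EmgRecording,
    muscle: Muscle,
    schedule: ProtocolSchedule,
    rest_window: float = 5.0,
) -> float:
    """Stimulation-period RMS relative to the pre-stimulation rest RMS.

    The numerator pools every sample inside any stimulation window of the
    cyclic schedule; the denominator is the RMS over the ``rest_window``
    seconds immediately before the first event.
    """
    if rec.state != "rectified":
        raise ProcessingError("cyclic_rms_ratio expects a preprocessed recording")
    if schedule.kind != "cyclic":
        raise ValueError("cyclic_rms_ratio requires a cyclic schedule")
    first = min(e.onset for e in schedule.events)
    if first - rest_window < rec.times[0] - 1e-9:
        raise ValueError("recording has no full rest period before stimulation")
    fs = rec.sample_rate
    mask = np.zeros(len(rec.times), dtype=bool)
    for e in schedule.events:
        i0 = int(round((e.onset - rec.times[0]) * fs))
        i1 = int(round((e.offset - rec.times[0]) * fs))
        mask[i0:i1] = True
    stim = rec.channels[muscle][mask]
    rest = _slice(rec, muscle, first - rest_window, first)
    return rms(stim) / rms(rest)


def flag_noisy_trials(
    baselines: Sequence[BaselineStats], factor: float = 5.0
) -> list[bool]:
    """Automated stand-in for visual outlier screening.

    A trial is flagged (excluded) when its baseline SD exceeds ``factor``
    times the session median baseline SD — the operational version of
    discarding recordings with high background noise.
    """
    sds = np.array([b.sd for b in baselines])
    med = float(np.median(sds))
    return [bool(sd > factor * med) for sd in sds]
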