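"""Synthetic stimulation sessions: EMG, markers, triggers and ground truth.

No raw recordings are distributed with the study this package models, so
every pipeline stage is exercised on generated sessions that carry the
statistical structure the analysis assumes:

* baseline EMG is band-limited (5-500 Hz) Gaussian noise calibrated to the
  published rest levels (~1.26 µV TA, ~1.32 µV SOL rectified RMS);
* maximal-voluntary-contraction trials hold a noise plateau whose windowed
  RMS equals the subject's MVC reference;
* reflexes are Bernoulli events per stimulus whose probability and burst
  amplitude (in %MVC) grow with pressure and with the fast rise speed;
  bursts are Gaussian-windowed band-limited noise, optionally doubled
  (withdrawal-reflex signature);
* markers hold a neutral shank-foot angle of ~150 deg, with ramp-and-hold
  excursions per plate extension (heel -1.33 deg, forefoot +1.07 deg by
  default) and an optional ~1 deg transient perturbation for strong fast
  stimuli in susceptible subjects.

Every stochastic draw is recorded in the session's ground truth, keyed by
event, so estimators can be checked against the generating parameters.
The 60 ms reflex latency default is a placeholder (no measured latencies
are available for this protocol) and is labelled as such in ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal

from .emg import EmgRecording, MUSCLES
from .kinematics import MarkerFrameSeries
from .stimulus import ProtocolSchedule, StimulusEvent, trigger_trace

EMG_RATE = 1200.0
MARKER_RATE = 100.0


@dataclass
class SubjectProfile:
    """Generating parameters for one synthetic subject.

    ``reflex_gain`` is %MVC of burst peak per bar of supply pressure, per
    (muscle, location); ``fast_multiplier`` scales both occurrence odds and
    burst amplitude for fast-rising stimuli; ``reflex_probability`` is the
    per-stimulus base occurrence probability for slow stimuli.
    """

    subject_id: str = "SYN1"
    rest_rms: dict[str, float] = field(default_factory=lambda: {"TA": 1.26, "SOL": 1.32})
    mvc_rms: dict[str, float] = field(default_factory=lambda: {"TA": 189.16, "SOL": 68.89})
    reflex_gain: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            (m, loc): 10.0 for m in MUSCLES for loc in ("heel", "forefoot")
        }
    )
    reflex_probability: float = 0.5
    latency: float = 0.06  # s; placeholder value, no published latencies
    fast_multiplier: float = 3.0
    perturbation_susceptible: bool = False
    neutral_angle: float = 150.0
    heel_angle_change: float = -1.33
    forefoot_angle_change: float = 1.07
    perturbation_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.fast_multiplier <= 1:
            raise ValueError("fast_multiplier must be > 1")
        if not 0.0 <= self.reflex_probability <= 1.0:
            raise ValueError("reflex_probability must be in [0, 1]")
        if any(g < 0 for g in self.reflex_gain.values()):
            raise ValueError("reflex gains must be >= 0")

    def occurrence_probability(self, event: StimulusEvent) -> float:
        p = self.reflex_probability
        if event.rise_speed == "fast":
            p = p * self.fast_multiplier
        return float(min(1.0, p))

    def burst_amplitude_pct(self, event: StimulusEvent, muscle: str) -> float:
        amp = self.reflex_gain[(muscle, event.location)] * event.pressure
        if event.rise_speed == "fast":
            amp *= self.fast_multiplier
        return amp


@dataclass
class SyntheticSession:
    """One generated session with its event-level ground truth."""

    emg: EmgRecording
    markers: MarkerFrameSeries
    schedule: ProtocolSchedule
    ground_truth: list[dict]
    profile: SubjectProfile


def _bandlimited_noise(
    n: int,
    sample_rate: float,
    rng: np.random.Generator,
    band: tuple[float, float] = (5.0, 500.0),
) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to a frequency band."""
    sos = signal.butter(
        4, [band[0] / (sample_rate / 2), band[1] / (sample_rate / 2)], btype="band", output="sos"
    )
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


#: Burst/plateau carrier band: the flat interior of the 5-500 Hz analysis
#: pass-band (and the bulk of real surface-EMG power), so re-filtering in
#: the analysis chain leaves injected amplitudes essentially unchanged.
CARRIER_BAND = (20.0, 250.0)


def gen_baseline_emg(
    rest_rms: float,
    duration: float,
    sample_rate: float = EMG_RATE,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Resting EMG: band-limited noise with rectified RMS ``rest_rms`` (µV).

    The realization is rescaled to the target RMS, so the calibration is
    exact for any duration; reproducible for a fixed seed.
    """
    if rest_rms <= 0:
        raise ValueError("rest_rms must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    return rest_rms * _bandlimited_noise(n, sample_rate, rng)


#: Zero-padding (s) prepended and appended to a generated burst so the
#: analysis-band filtering inside the generator can spread freely; callers
#: adding a burst at latency t must place the array at t - BURST_LEAD.
BURST_LEAD = 0.15


def gen_reflex_burst(
    amplitude_pct_mvc: float,
    mvc_rms: float,
    burst_duration: float = 0.06,
    double: bool = False,
    sample_rate: float = EMG_RATE,
    seed: int | np.random.Generator = 0,
    gap: float = 0.1,
) -> np.ndarray:
    """Additive reflex burst: Gaussian-windowed band-limited noise.

    Weak bursts carry a positive pedestal under the Gaussian envelope,
    emulating the elevated rectified envelope of a motor-unit interference
    burst: the rectified profile then stays supra-threshold throughout the
    burst core instead of dipping at carrier zero-crossings, so a burst
    whose amplitude clears the detection threshold satisfies the 10 ms
    duration criterion.  The pedestal tapers to zero for strong bursts
    (where noise alone is tens of times the threshold and the pedestal's
    low-frequency energy would smear rectified ringing between double
    bursts).  The finished burst is filtered through the 5-500 Hz + notch
    analysis chain and then rescaled, so its spectrum is confined to the
    pass-band and the peak rectified value equals
    ``amplitude_pct_mvc / 100 * mvc_rms`` exactly, surviving the analysis
    refiltering within a few percent.

    With ``double`` a second burst at 70 % amplitude follows after ``gap``
    seconds (>= the detector's 20 ms separation rule).  The returned array
    starts :data:`BURST_LEAD` seconds before the burst proper.
    """
    if amplitude_pct_mvc < 0:
        raise ValueError("amplitude must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peak = amplitude_pct_mvc / 100.0 * mvc_rms
    n = int(round(burst_duration * sample_rate))
    n_gap = int(round(gap * sample_rate))
    n_pad = int(round(BURST_LEAD * sample_rate))
    total = 2 * n_pad + (2 * n + n_gap if double else n)
    if peak == 0:
        return np.zeros(total)
    # pedestal fraction: 0.7 for bursts below ~20x threshold, 0 above ~40x
    ped = 0.7 * float(np.clip((100.0 - peak) / 50.0, 0.0, 1.0))

    def one(scale: float) -> np.ndarray:
        env = signal.windows.gaussian(n, std=n / 5.0)
        noise = _bandlimited_noise(n, sample_rate, rng, CARRIER_BAND)
        return scale * env * (ped + (1.0 - ped) * noise / np.max(np.abs(noise)))

    core = one(1.0)
    if double:
        core = np.concatenate([core, np.zeros(n_gap), one(0.7)])
    pad = np.zeros(n_pad)
    x = np.concatenate([pad, core, pad])
    sos = signal.butter(
        4, [5.0 / (sample_rate / 2), 500.0 / (sample_rate / 2)], btype="band", output="sos"
    )
    b, a = signal.iirnotch(50.0, 30.0, fs=sample_rate)
    x = signal.filtfilt(b, a, signal.sosfiltfilt(sos, x))
    return peak * x / np.max(np.abs(x))


def gen_mvc_recording(
    mvc_rms: dict[str, float],
    rest_rms: dict[str, float] | None = None,
    duration: float = 3.0,
    plateau: float = 1.0,
    sample_rate: float = EMG_RATE,
    seed: int | np.random.Generator = 0,
) -> EmgRecording:
    """One maximal-contraction trial: rest noise with a central noise plateau.

    The plateau (``plateau`` seconds, centered) carries a mild center-peaked
    envelope so the signal's maximal sample falls near the plateau middle,
    and it is scaled so the RMS of the 500 ms window around the center
    equals the muscle's target MVC level.  The surrounding signal sits at
    rest level, so the peak-centered reference window the analysis uses
    lands inside the plateau and recovers the target.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rest_rms = rest_rms or {m: 1.3 for m in mvc_rms}
    n = int(round(duration * sample_rate))
    times = np.arange(n) / sample_rate
    i0 = int(round((duration - plateau) / 2 * sample_rate))
    i1 = i0 + int(round(plateau * sample_rate))
    m_pl = i1 - i0
    # envelope: flat plateau plus a narrow center boost that pins the
    # recording's maximal sample to the plateau middle
    center = m_pl / 2.0
    env = 1.0 + 2.0 * np.exp(-0.5 * ((np.arange(m_pl) - center) / (0.02 * sample_rate)) ** 2)
    w0 = int(round(center - 0.25 * sample_rate))
    w1 = int(round(center + 0.25 * sample_rate))
    channels = {}
    for muscle, target in mvc_rms.items():
        x = rest_rms[muscle] * _bandlimited_noise(n, sample_rate, rng)
        burst = env * _bandlimited_noise(m_pl, sample_rate, rng, CARRIER_BAND)
        burst *= target / np.sqrt(np.mean(burst[w0:w1] ** 2))
        x[i0:i1] = burst
        channels[muscle] = x
    return EmgRecording(times=times, channels=channels, state="raw")


def _angle_trace(
    times: np.ndarray,
    profile: SubjectProfile,
    schedule: ProtocolSchedule,
    perturbed_events: set[int],
) -> np.ndarray:
    """Ideal ankle-angle trace: neutral + per-event ramp-and-hold (+ bumps)."""
    theta = np.full(len(times), profile.neutral_angle, dtype=float)
    for idx, e in enumerate(schedule.events):
        delta = (
            profile.heel_angle_change
            if e.location == "heel"
            else profile.forefoot_angle_change
        )
        rise = e.rise_time
        up = np.clip((times - e.onset) / rise, 0.0, 1.0)
        down = np.clip((times - e.offset) / rise, 0.0, 1.0)
        theta += delta * (up - down)
        if idx in perturbed_events:
            # transient extra deflection mid-event, clear of the plateau
            center = e.onset + 0.35 * e.duration
            width = 0.3
            local = (times - (center - width / 2)) / width
            bump = np.sin(np.pi * np.clip(local, 0.0, 1.0))
            theta += np.sign(delta) * profile.perturbation_deg * bump
    return theta


def gen_marker_traces(
    profile: SubjectProfile,
    schedule: ProtocolSchedule,
    seed: int | np.random.Generator = 0,
    perturbed_events: set[int] | None = None,
    pad: float = 2.0,
    jitter_m: float = 1e-4,
    shank_length: float = 0.4,
    foot_length: float = 0.15,
) -> MarkerFrameSeries:
    """Marker trajectories whose ankle angle follows the event timeline.

    Knee and ankle are fixed (plus isotropic 0.1 mm jitter); the metatarsal
    is rotated about the ankle so the interior shank-foot angle tracks the
    ideal ramp-and-hold trace.  ``perturbed_events`` lists event indices
    that additionally receive the ~1 deg reflex-induced transient.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = schedule.total_duration + pad
    n = int(round(total * MARKER_RATE))
    times = np.arange(n) / MARKER_RATE
    theta = _angle_trace(times, profile, schedule, perturbed_events or set())
    ankle = np.zeros((n, 2))
    shank_dir = np.deg2rad(105.0)  # arbitrary fixed shank orientation
    knee = np.column_stack(
        [shank_length * np.cos(shank_dir) * np.ones(n), shank_length * np.sin(shank_dir) * np.ones(n)]
    )
    foot_dir = shank_dir - np.deg2rad(theta)
    metatarsal = np.column_stack(
        [foot_length * np.cos(foot_dir), foot_length * np.sin(foot_dir)]
    )
    out = MarkerFrameSeries(
        times=times,
        knee=knee + rng.normal(0, jitter_m, (n, 2)),
        ankle=ankle + rng.normal(0, jitter_m, (n, 2)),
        metatarsal=metatarsal + rng.normal(0, jitter_m, (n, 2)),
    )
    return out


def gen_session(
    profile: SubjectProfile,
    schedule: ProtocolSchedule,
    seed: int = 0,
    pad: float = 2.0,
) -> SyntheticSession:
    """Compose a full session: EMG (1200 Hz), markers (100 Hz), ground truth.

    Per event and muscle, reflex occurrence is a Bernoulli draw at the
    profile's (speed-adjusted) probability; occurring reflexes inject a
    burst at ``profile.latency`` after onset with amplitude linear in
    pressure.  Strong fast stimuli (3.5 bar) in susceptible subjects get a
    double burst and a reflex-induced angle perturbation.  All draws are
    recorded in ``ground_truth`` (one record per event).
    """
    rng = np.random.default_rng(seed)
    fs = EMG_RATE
    total = schedule.total_duration + pad
    n = int(round(total * fs))
    times = np.arange(n) / fs
    channels = {
        m: gen_baseline_emg(profile.rest_rms[m], total, fs, rng) for m in MUSCLES
    }
    ground_truth: list[dict] = []
    perturbed: set[int] = set()
    for idx, e in enumerate(schedule.events):
        p = profile.occurrence_probability(e)
        record: dict = {
            "event_index": idx,
            "onset": e.onset,
            "location": e.location,
            "rise_speed": e.rise_speed,
            "pressure": e.pressure,
            "occurrence_probability": p,
            "latency_s": profile.latency,
            "latency_is_placeholder": True,
            "angle_change_deg": (
                profile.heel_angle_change
                if e.location == "heel"
                else profile.forefoot_angle_change
            ),
            "muscles": {},
        }
        strong_fast = e.rise_speed == "fast" and e.pressure >= 3.5
        any_occurred = False
        for m in MUSCLES:
            occurred = bool(rng.random() < p)
            amp = profile.burst_amplitude_pct(e, m) if occurred else 0.0
            double = occurred and strong_fast and profile.perturbation_susceptible
            if occurred and amp > 0:
                burst = gen_reflex_burst(
                    amp, profile.mvc_rms[m], double=double, sample_rate=fs, seed=rng
                )
                i0 = int(round((e.onset + profile.latency - BURST_LEAD) * fs))
                j0 = max(0, -i0)
                i1 = min(i0 + len(burst), n)
                channels[m][i0 + j0 : i1] += burst[j0 : i1 - i0]
            record["muscles"][m] = {
                "occurred": occurred,
                "amplitude_pct_mvc": amp,
                "double_burst": double,
            }
            any_occurred = any_occurred or occurred
        perturb = bool(strong_fast and profile.perturbation_susceptible and any_occurred)
        record["perturbation"] = perturb
        if perturb:
            perturbed.add(idx)
        ground_truth.append(record)
    trig = trigger_trace(schedule, fs, total)
    emg = EmgRecording(
        times=times,
        channels=channels,
        trigger=np.maximum(trig["heel"], trig["forefoot"]),
        state="raw",
    )
    markers = gen_marker_traces(
        profile, schedule, seed=rng, perturbed_events=perturbed, pad=pad
    )
    return SyntheticSession(
        emg=emg,
        markers=markers,
        schedule=schedule,
        ground_truth=ground_truth,
        profile=profile,
    )
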