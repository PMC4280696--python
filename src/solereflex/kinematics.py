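"""Sagittal ankle-joint kinematics from three surface markers.

Markers sit at the medial knee joint, the medial ankle joint and the first
metatarsal head; coordinates are 2-D sagittal (meters, y up) sampled at
100 Hz.  The ankle angle is the shank-foot angle obtained by the law of
cosines from the three inter-marker distances.  Reduction of the angle is
dorsiflexion; increase is plantarflexion.

Two angle conventions are available.  The ``interior`` convention (default)
reports the interior triangle angle at the ankle, which matches the
described neutral supine posture of roughly 150 deg.  The ``printed_offset``
convention adds 180 deg and is retained because the source formula is
sometimes rendered with that offset; every angle series records which
convention produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .stimulus import RISE_TIMES, StimulusEvent

Convention = Literal["interior", "printed_offset"]


class GeometryError(ValueError):
    """Degenerate marker geometry (coincident or collinear beyond tolerance)."""


@dataclass
class MarkerFrameSeries:
    """Knee / ankle / first-metatarsal marker trajectories on a uniform grid."""

    times: np.ndarray
    knee: np.ndarray        # (n, 2)
    ankle: np.ndarray       # (n, 2)
    metatarsal: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("knee", "ankle", "metatarsal"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 2):
                raise ValueError(f"{name} must have shape ({n}, 2)")
            setattr(self, name, arr)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time": self.times,
                "xk": self.knee[:, 0], "yk": self.knee[:, 1],
                "xa": self.ankle[:, 0], "ya": self.ankle[:, 1],
                "xm": self.metatarsal[:, 0], "ym": self.metatarsal[:, 1],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MarkerFrameSeries":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            times=df["time"].to_numpy(),
            knee=df[["xk", "yk"]].to_numpy(),
            ankle=df[["xa", "ya"]].to_numpy(),
            metatarsal=df[["xm", "ym"]].to_numpy(),
        )


@dataclass
class AnkleAngleSeries:
    """Ankle angle over time, in degrees, tagged with its convention."""

    times: np.ndarray
    theta_deg: np.ndarray
    convention: Convention = "interior"
    smoothed: bool = False

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class AngleChangeResult:
    """Plate-induced angle change and reflex-perturbation verdict for a trial."""

    plate_induced_change: float
    perturbation_detected: bool
    perturbation_magnitude: float

    def __post_init__(self) -> None:
        if self.perturbation_magnitude < 0:
            raise ValueError("perturbation_magnitude must be >= 0")
        if not self.perturbation_detected and self.perturbation_magnitude != 0.0:
            raise ValueError("magnitude must be 0 when no perturbation is detected")


def segment_lengths(
    knee: np.ndarray, ankle: np.ndarray, metatarsal: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euclidean distances knee-ankle, ankle-metatarsal, knee-metatarsal.

    Accepts single frames ``(2,)`` or stacked frames ``(n, 2)``.  Coincident
    markers raise :class:`GeometryError`.
    """
    knee, ankle, metatarsal = (np.asarray(a, float) for a in (knee, ankle, metatarsal))
    l_ka = np.linalg.norm(knee - ankle, axis=-1)
    l_am = np.linalg.norm(ankle - metatarsal, axis=-1)
    l_km = np.linalg.norm(knee - metatarsal, axis=-1)
    if np.any(l_ka == 0) or np.any(l_am == 0) or np.any(l_km == 0):
        raise GeometryError("coincident markers in at least one frame")
    return l_ka, l_am, l_km


def ankle_angle(
    knee: np.ndarray,
    ankle: np.ndarray,
    metatarsal: np.ndarray,
    convention: Convention = "interior",
) -> np.ndarray:
    """Ankle angle (degrees) at the ankle vertex by the law of cosines.

    ``interior`` gives arccos((L_ka^2 + L_am^2 - L_km^2) / (2 L_ka L_am));
    ``printed_offset`` adds 180 deg.  The arccos argument is clipped to
    [-1, 1] within a 1e-9 tolerance; larger excursions raise
    :class:`GeometryError`.
    """
    l_ka, l_am, l_km = segment_lengths(knee, ankle, metatarsal)
    arg = (l_ka**2 + l_am**2 - l_km**2) / (2.0 * l_ka * l_am)
    if np.any(np.abs(arg) > 1.0 + 1e-9):
        raise GeometryError("law-of-cosines argument outside [-1, 1]")
    theta = np.degrees(np.arccos(np.clip(arg, -1.0, 1.0)))
    if convention == "printed_offset":
        theta = theta + 180.0
    return theta


def ankle_angle_series(
    markers: MarkerFrameSeries, convention: Convention = "interior"
) -> AnkleAngleSeries:
    """Ankle angle for every frame of a marker series."""
    theta = ankle_angle(markers.knee, markers.ankle, markers.metatarsal, convention)
    return AnkleAngleSeries(times=markers.times, theta_deg=theta, convention=convention)


def smooth_motion(
    series: AnkleAngleSeries,
    window: int = 5,
    loess_span: float = 0.1,
    stage1: Literal["mean", "median"] = "mean",
) -> AnkleAngleSeries:
    """Two-stage motion smoothing: short moving filter, then LOESS.

    Stage 1 is a centered moving average of odd length ``window`` (a moving
    median is available for spike-heavy traces); edges use a shrunken
    symmetric window so output length equals input length.  Stage 2 is
    degree-1 LOESS with span ``loess_span`` (fraction of the series).  A
    constant series passes through unchanged and first-order trends are
    preserved away from the edges.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if not 0 < loess_span <= 1:
        raise ValueError("loess_span must be in (0, 1]")
    y = np.asarray(series.theta_deg, float)
    n = len(y)
    if n < window:
        raise ValueError(f"series of length {n} shorter than window {window}")
    half = window // 2
    out = np.empty(n)
    if stage1 == "mean":
        # cumulative-sum moving average with symmetric edge shrinking
        c = np.concatenate([[0.0], np.cumsum(y)])
        for i in range(n):
            h = min(half, i, n - 1 - i)
            out[i] = (c[i + h + 1] - c[i - h]) / (2 * h + 1)
    else:
        for i in range(n):
            h = min(half, i, n - 1 - i)
            out[i] = np.median(y[i - h : i + h + 1])
    if max(2, int(np.ceil(loess_span * n))) < n:
        out = lowess(
            out, series.times, frac=loess_span, it=0, return_sorted=False
        )
    return AnkleAngleSeries(
        times=series.times, theta_deg=out, convention=series.convention, smoothed=True
    )


def _window_mean(series: AnkleAngleSeries, t0: float, t1: float) -> float:
    mask = (series.times >= t0) & (series.times < t1)
    if not mask.any():
        raise ValueError(f"no samples in window [{t0}, {t1})")
    return float(series.theta_deg[mask].mean())


def plate_induced_change(
    series: AnkleAngleSeries,
    event: StimulusEvent,
    baseline_window: float = 0.5,
    plateau_window: float = 0.2,
) -> float:
    """Signed angle change (deg) produced by the plate extension.

    Mean angle over the plateau (the final ``plateau_window`` seconds of the
    event, after the plate has reached full extension) minus the mean over
    ``baseline_window`` seconds immediately before onset.  Negative values
    are dorsiflexion (heel plate), positive plantarflexion (forefoot plate).
    """
    if event.onset - baseline_window < series.times[0] - 1e-9:
        raise ValueError("baseline window precedes the recording")
    if event.offset > series.times[-1] + 1e-9:
        raise ValueError("event extends past the recording")
    base = _window_mean(series, event.onset - baseline_window, event.onset)
    plateau = _window_mean(series, event.offset - plateau_window, event.offset)
    return plateau - base


def detect_perturbation(
    series: AnkleAngleSeries,
    event: StimulusEvent,
    threshold: float = 0.5,
    min_duration: float = 0.05,
    baseline_window: float = 0.5,
    plateau_window: float = 0.2,
) -> AngleChangeResult:
    """Flag reflex-induced ankle perturbation on top of the plate movement.

    The expected trace is an idealized ramp-and-hold: baseline level,
    linear ramp over the plate rise time to baseline + plate-induced change,
    then hold.  A perturbation is declared when the residual (observed minus
    idealized) exceeds ``threshold`` degrees in absolute value for at least
    ``min_duration`` seconds within the event window; its magnitude is the
    maximum absolute residual during the event.
    """
    change = plate_induced_change(series, event, baseline_window, plateau_window)
    base = _window_mean(series, event.onset - baseline_window, event.onset)
    rise = RISE_TIMES.get(event.rise_speed, 0.2)
    mask = (series.times >= event.onset) & (series.times < event.offset)
    t = series.times[mask]
    ideal = base + change * np.clip((t - event.onset) / rise, 0.0, 1.0)
    residual = series.theta_deg[mask] - ideal
    over = np.abs(residual) > threshold
    need = int(np.ceil(min_duration * series.sample_rate))
    detected = _has_run(over, need)
    magnitude = float(np.max(np.abs(residual))) if detected else 0.0
    return AngleChangeResult(
        plate_induced_change=change,
        perturbation_detected=detected,
        perturbation_magnitude=magnitude,
    )


def _has_run(mask: np.ndarray, min_len: int) -> bool:
    run = 0
    for v in mask:
        run = run + 1 if v else 0
        if run >= min_len:
            return True
    return False
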