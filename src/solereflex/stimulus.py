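"""Pneumatic shoe-platform stimulation model.

A dynamic shoe platform loads the sole of a supine subject's foot through two
pneumatically actuated pressure plates (heel and forefoot).  This module
models the commanded force output of the plates and builds the two
stimulation protocols used in the experiments:

* **single-pulse** — 0.8 s pulses every 30 s, a fully crossed design of
  4 pressures x 2 rise speeds x 2 locations, each combination repeated
  4 times in seeded random order (64 trials);
* **cyclic** — a walking-like loading pattern in which the heel plate is up
  for the first 40 % of each gait cycle and the forefoot plate for
  20-60 % of it, preceded by a rest period.

Forces are the manufacturer's static amplitudes per supply pressure; the
pressure-to-force table is exactly linear (80 N/bar heel, 50 N/bar forefoot)
so intermediate pressures are linearly interpolated.  Extrapolation outside
the calibrated range is refused.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

Location = Literal["heel", "forefoot"]
RiseSpeed = Literal["fast", "slow"]

#: Plate full-extension times (s): "fast" is the unrestricted cylinder,
#: "slow" goes through the one-way flow control valve.
RISE_TIMES: dict[str, float] = {"fast": 0.05, "slow": 0.2}


class ProtocolError(ValueError):
    """Invalid protocol configuration."""


@dataclass(frozen=True)
class ActuatorSpec:
    """Geometry and speed limits of one pressure-plate cylinder."""

    location: Location
    stroke_mm: float
    diameter_mm: float
    rise_time_fast: float = 0.05
    rise_time_slow: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.rise_time_fast < self.rise_time_slow):
            raise ValueError(
                "require 0 < rise_time_fast < rise_time_slow, got "
                f"{self.rise_time_fast} / {self.rise_time_slow}"
            )


#: Default cylinders: the heel plate uses the longer-stroke, larger-bore one.
HEEL_ACTUATOR = ActuatorSpec("heel", stroke_mm=20.0, diameter_mm=32.0)
FOREFOOT_ACTUATOR = ActuatorSpec("forefoot", stroke_mm=10.0, diameter_mm=25.0)


@dataclass(frozen=True)
class PressureForceMap:
    """Static force amplitude per supply pressure, per plate.

    Entries are (pressure bar, heel force N, forefoot force N), strictly
    increasing in pressure.  The default is the manufacturer calibration.
    """

    entries: tuple[tuple[float, float, float], ...] = (
        (2.0, 160.0, 100.0),
        (2.5, 200.0, 125.0),
        (3.0, 240.0, 150.0),
        (3.5, 280.0, 175.0),
    )

    def __post_init__(self) -> None:
        p = np.array([e[0] for e in self.entries])
        h = np.array([e[1] for e in self.entries])
        f = np.array([e[2] for e in self.entries])
        if len(self.entries) < 2:
            raise ValueError("need at least two calibration rows")
        if not (np.all(np.diff(p) > 0) and np.all(np.diff(h) > 0) and np.all(np.diff(f) > 0)):
            raise ValueError("forces must strictly increase with pressure")
        if not np.all(h > f):
            raise ValueError("heel force must exceed forefoot force at equal pressure")

    @property
    def pressure_range(self) -> tuple[float, float]:
        return self.entries[0][0], self.entries[-1][0]


DEFAULT_FORCE_MAP = PressureForceMap()


def force_amplitude(
    location: Location, pressure: float, force_map: PressureForceMap = DEFAULT_FORCE_MAP
) -> float:
    """Commanded plate force (N) at a supply pressure (bar).

    Tabulated pressures return the calibrated value exactly; intermediate
    pressures are linearly interpolated.  Pressures outside the calibrated
    range raise ``ValueError`` (the calibration cannot be extrapolated).
    """
    lo, hi = force_map.pressure_range
    if not lo <= pressure <= hi:
        raise ValueError(f"pressure {pressure} bar outside calibrated range [{lo}, {hi}]")
    col = {"heel": 1, "forefoot": 2}[location]
    p = [e[0] for e in force_map.entries]
    f = [e[col] for e in force_map.entries]
    return float(np.interp(pressure, p, f))


@dataclass(frozen=True)
class ForceProfile:
    """Commanded plate force over time on a uniform grid."""

    times: np.ndarray
    force: np.ndarray
    location: Location
    rise_time: float
    hold_amplitude: float

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.force])
        np.savetxt(path, arr, delimiter=",", header="time,value", comments="")


def trapezoid_profile(
    amplitude: float,
    rise_time: float,
    total_duration: float,
    fall_time: float | None = None,
    sample_rate: float = 1000.0,
    location: Location = "heel",
) -> ForceProfile:
    """Piecewise-linear (trapezoidal) force command: rise, hold, fall.

    The plate extends linearly from 0 to ``amplitude`` over ``rise_time``,
    holds, and retracts over ``fall_time`` (defaults to ``rise_time``; the
    platform's true retraction speed is not calibrated, so a symmetric
    trapezoid is assumed).  ``rise_time`` of 0 is a step.
    """
    if fall_time is None:
        fall_time = rise_time
    if rise_time < 0 or fall_time < 0 or sample_rate <= 0:
        raise ValueError("rise_time, fall_time must be >= 0 and sample_rate > 0")
    if rise_time + fall_time > total_duration:
        raise ValueError(
            f"rise ({rise_time}) + fall ({fall_time}) exceed total duration {total_duration}"
        )
    n = int(round(total_duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    f = np.full(n, amplitude, dtype=float)
    if rise_time > 0:
        ramp = t < rise_time
        f[ramp] = amplitude * t[ramp] / rise_time
    fall_start = total_duration - fall_time
    if fall_time > 0:
        falling = t > fall_start
        f[falling] = amplitude * np.clip((total_duration - t[falling]) / fall_time, 0.0, 1.0)
    f[0] = 0.0 if rise_time > 0 else f[0]
    f[-1] = 0.0 if fall_time > 0 else f[-1]
    return ForceProfile(t, f, location, rise_time, amplitude)


@dataclass(frozen=True)
class StimulusEvent:
    """One plate extension: when, where, how fast, how hard."""

    onset: float
    duration: float
    location: Location
    pressure: float
    rise_speed: RiseSpeed

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def rise_time(self) -> float:
        return RISE_TIMES[self.rise_speed]

    @property
    def stimulus_type(self) -> tuple:
        return (self.location, self.rise_speed, self.pressure)


@dataclass
class ProtocolSchedule:
    """Ordered stimulation events plus protocol-level metadata."""

    events: list[StimulusEvent]
    kind: Literal["single_pulse", "cyclic"]
    cycle_duration: float | None = None
    n_cycles: int | None = None
    lead_in_rest: float = 0.0

    def __post_init__(self) -> None:
        for loc in ("heel", "forefoot"):
            evs = sorted(
                (e for e in self.events if e.location == loc), key=lambda e: e.onset
            )
            for a, b in zip(evs, evs[1:]):
                if b.onset < a.offset:
                    raise ProtocolError(
                        f"overlapping {loc} events at {a.onset:.3f} and {b.onset:.3f} s"
                    )

    @property
    def total_duration(self) -> float:
        return max((e.offset for e in self.events), default=0.0)

    def events_at(self, location: Location) -> list[StimulusEvent]:
        return [e for e in self.events if e.location == location]

    def to_json(self, path=None) -> str:
        doc = {
            "kind": self.kind,
            "cycle_duration": self.cycle_duration,
            "n_cycles": self.n_cycles,
            "lead_in_rest": self.lead_in_rest,
            "events": [
                {
                    "onset": e.onset,
                    "duration": e.duration,
                    "location": e.location,
                    "pressure": e.pressure,
                    "rise_speed": e.rise_speed,
                }
                for e in self.events
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ProtocolSchedule":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            doc = json.loads(source)
        events = [StimulusEvent(**e) for e in doc["events"]]
        return cls(
            events=events,
            kind=doc["kind"],
            cycle_duration=doc.get("cycle_duration"),
            n_cycles=doc.get("n_cycles"),
            lead_in_rest=doc.get("lead_in_rest", 0.0),
        )


def single_pulse_protocol(
    pressures: Sequence[float] = (2.0, 2.5, 3.0, 3.5),
    rise_speeds: Sequence[RiseSpeed] = ("slow", "fast"),
    locations: Sequence[Location] = ("heel", "forefoot"),
    reps: int = 4,
    interval: float = 30.0,
    pulse_duration: float = 0.8,
    seed: int = 0,
    lead_in_rest: float = 30.0,
    mid_session_rest: float = 0.0,
) -> ProtocolSchedule:
    """Fully crossed single-pulse session in seeded random order.

    Every (pressure, speed, location) combination appears exactly ``reps``
    times; the trial order is a uniform permutation drawn from
    ``numpy.random.default_rng(seed)``.  Pulses of ``pulse_duration`` are
    spaced ``interval`` apart.  ``mid_session_rest`` optionally inserts an
    extra gap after the first half of the trials (the experiment's
    mid-session break); it shifts onsets only.
    """
    if reps < 1:
        raise ProtocolError("reps must be >= 1")
    if not (pressures and rise_speeds and locations):
        raise ProtocolError("pressures, rise_speeds and locations must be non-empty")
    if interval <= pulse_duration:
        raise ProtocolError("interval must exceed pulse_duration")
    trials = [
        (loc, spd, p)
        for loc, spd, p in itertools.product(locations, rise_speeds, pressures)
        for _ in range(reps)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    events = []
    half = len(trials) // 2
    for slot, idx in enumerate(order):
        loc, spd, p = trials[idx]
        onset = lead_in_rest + slot * interval + (mid_session_rest if slot >= half else 0.0)
        events.append(StimulusEvent(onset, pulse_duration, loc, p, spd))
    return ProtocolSchedule(events=events, kind="single_pulse", lead_in_rest=lead_in_rest)


def cyclic_protocol(
    cycle_duration: float = 5.0,
    pressure: float = 3.5,
    n_cycles: int = 9,
    lead_in_rest: float = 5.0,
    rise_speed: RiseSpeed = "slow",
) -> ProtocolSchedule:
    """Walking-like loading: heel up 0-40 %, forefoot 20-60 % of each cycle.

    With the 5 s cycle this reproduces the published timing (heel 0-2 s,
    forefoot 1-3 s of every 5 s interval); plates overlap for 20 % of the
    cycle, emulating mid-stance double support of the sole.
    """
    if cycle_duration <= 0 or n_cycles < 1:
        raise ProtocolError("cycle_duration must be > 0 and n_cycles >= 1")
    T = cycle_duration
    events = []
    for k in range(n_cycles):
        base = lead_in_rest + k * T
        events.append(StimulusEvent(base, 0.4 * T, "heel", pressure, rise_speed))
        events.append(StimulusEvent(base + 0.2 * T, 0.4 * T, "forefoot", pressure, rise_speed))
    return ProtocolSchedule(
        events=events,
        kind="cyclic",
        cycle_duration=T,
        n_cycles=n_cycles,
        lead_in_rest=lead_in_rest,
    )


def walking_speed(cycle_duration: float, step_length: float = 0.85) -> float:
    """Walking speed (km/h) for a gait-cycle duration and step length.

    One gait cycle covers two steps, so speed = 2 * step_length /
    cycle_duration, converted from m/s to km/h.
    """
    if cycle_duration <= 0 or step_length <= 0:
        raise ValueError("cycle_duration and step_length must be > 0")
    return 2.0 * step_length / cycle_duration * 3.6


def trigger_trace(
    schedule: ProtocolSchedule,
    sample_rate: float,
    total_duration: float | None = None,
) -> dict[str, np.ndarray]:
    """Binary synchronization channel per plate: 1 while the plate is up.

    Event windows are half-open ``[onset, offset)``; the rising-edge count
    of each trace equals the number of events at that plate.
    """
    if total_duration is None:
        total_duration = schedule.total_duration
    if schedule.events and schedule.total_duration > total_duration + 1e-9:
        raise ValueError("total_duration does not cover all scheduled events")
    n = int(round(total_duration * sample_rate))
    out = {}
    for loc in ("heel", "forefoot"):
        trace = np.zeros(n, dtype=np.int8)
        for e in schedule.events_at(loc):
            i0 = int(round(e.onset * sample_rate))
            i1 = int(round(e.offset * sample_rate))
            trace[i0:i1] = 1
        out[loc] = trace
    return out
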