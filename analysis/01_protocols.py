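"""Build the stimulation protocols and commanded force patterns.

Writes the single-pulse session (16 stimulus types x 4 repetitions, 0.8 s
pulses every 30 s, seeded random order), the walking-like cyclic schedules
for the 5 s and 2 s gait cycles (heel 0-40 %, forefoot 20-60 % of each
cycle, 5 s lead-in rest, 9 cycles), trapezoidal force profiles at each
calibrated pressure, trigger traces, and the walking speeds the two cycle
durations correspond to.
"""

import json
from pathlib import Path

import numpy as np

from solereflex import stimulus

OUT = Path(__file__).resolve().parent.parent / "results" / "protocols"
OUT.mkdir(parents=True, exist_ok=True)

single = stimulus.single_pulse_protocol(seed=42)
single.to_json(OUT / "single_pulse_schedule.json")
print(f"single-pulse session: {len(single.events)} trials, "
      f"{single.total_duration / 60:.1f} min")

for cycle in (5.0, 2.0):
    sched = stimulus.cyclic_protocol(cycle, pressure=3.5, n_cycles=9, lead_in_rest=5.0)
    sched.to_json(OUT / f"cyclic_{cycle:.0f}s_schedule.json")
    speed = stimulus.walking_speed(cycle, step_length=0.85)
    heel = sched.events_at("heel")[0]
    fore = sched.events_at("forefoot")[0]
    print(f"cyclic {cycle:.0f} s cycle: heel [{heel.onset:.1f}, {heel.offset:.1f}] s, "
          f"forefoot [{fore.onset:.1f}, {fore.offset:.1f}] s, "
          f"walking speed {speed:.2f} km/h")

forces = {}
for pressure in (2.0, 2.5, 3.0, 3.5):
    for loc in ("heel", "forefoot"):
        amp = stimulus.force_amplitude(loc, pressure)
        forces[f"{loc}_{pressure}bar"] = amp
        for speed_name, rise in stimulus.RISE_TIMES.items():
            prof = stimulus.trapezoid_profile(
                amp, rise, total_duration=0.8, sample_rate=1000.0, location=loc
            )
            prof.to_csv(OUT / f"force_{loc}_{pressure}bar_{speed_name}.csv")
with open(OUT / "force_amplitudes.json", "w") as fh:
    json.dump(forces, fh, indent=1)
print("force amplitudes (N):", forces)

traces = stimulus.trigger_trace(
    stimulus.cyclic_protocol(5.0, 3.5, 9, 5.0), sample_rate=100.0
)
np.savetxt(
    OUT / "trigger_cyclic_5s.csv",
    np.column_stack([np.arange(len(traces["heel"])) / 100.0, traces["heel"], traces["forefoot"]]),
    delimiter=",", header="time,heel,forefoot", comments="",
)
print(f"wrote protocol artifacts to {OUT}")
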