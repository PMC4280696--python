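# solereflex

Reflex and kinematics analysis of pneumatic foot-sole stimulation.

To retrain walking in bed-bound patients, a pneumatic shoe platform can
load the sole of a supine foot the way the ground does during gait: a heel
plate and a forefoot plate extend with adjustable force (160–280 N heel,
100–175 N forefoot at 2–3.5 bar) and adjustable rise time (0.05 s "fast",
0.2 s "slow"), either as isolated 0.8 s pulses or as a walking-like cycle
(heel up for 0–40 % of the gait cycle, forefoot for 20–60 %). Such loading
evokes reflexes in the tibialis anterior (TA) and soleus (SOL); the
engineering question is which stimulation parameters produce walking-like
sensory input *without* strong reflexes that perturb the ankle.

This package implements the complete analysis for that question, for
researchers in neurorehabilitation engineering and electrophysiological
signal processing:

* **`solereflex.stimulus`** — plate force model (linear pressure→force
  calibration, trapezoidal profiles) and protocol schedules (randomized
  single-pulse crossing; cyclic walking-like loading; trigger traces).
* **`solereflex.emg`** — the EMG chain at 1200 Hz: band-pass 5–500 Hz,
  50 Hz notch, full-wave rectification; MVC reference (RMS in a 500 ms
  window at the maximal peak, best of three); reflex threshold
  *mean + SD* of the 0.8 s pre-stimulus baseline with a 10 ms
  supra-threshold duration criterion; occurrence percentages; %MVC RMS
  summaries and cyclic stimulation-to-rest RMS ratios.
* **`solereflex.kinematics`** — sagittal ankle angle from knee/ankle/
  metatarsal markers by the law of cosines
  (θₐ = arccos[(L²ₖₐ + L²ₐₘ − L²ₖₘ)/(2 Lₖₐ Lₐₘ)]), two-stage smoothing
  (moving average + LOESS), plate-induced angle change and
  reflex-perturbation detection.
* **`solereflex.stats_report`** — per-subject aggregation (mean ± SD),
  paired one-sided t-tests (fast > slow, α = 0.05), report tables; the
  published per-subject summary tables ship as fixtures.
* **`solereflex.synthetic`** — a full session generator (EMG, markers,
  triggers, per-event ground truth) so every pipeline stage is testable
  without human recordings.

The numbered scripts under `analysis/` are the shell-facing drivers: they
run each stage over generated data and write tables under `results/`.

## Worked example

Reproduce the aggregate tables and the rise-speed comparison from the
packaged per-subject fixtures:

```sh
python analysis/04_tables_and_tests.py
```

```
rest_mvc: {'rest_ta': '1.26 ± 0.25', 'rest_sol': '1.32 ± 0.27', 'mvc_ta': '189.16 ± 97.33', 'mvc_sol': '68.89 ± 33.08'}
slow_rms: {'heel_ta': '2.12 ± 1.30', 'heel_sol': '2.30 ± 0.76', 'forefoot_ta': '1.61 ± 0.95', 'forefoot_sol': '1.97 ± 0.90'}
angle_change: {'heel': '-1.33 ± 0.63', 'forefoot': '1.07 ± 0.53'}
fast_rms: {'heel_ta': '5.94 ± 4.97', 'heel_sol': '5.36 ± 3.64', 'forefoot_ta': '3.91 ± 5.19', 'forefoot_sol': '3.60 ± 2.25'}
paired one-sided t-tests (fast > slow):
  heel_ta: t = 3.204, df = 9, p = 0.0054 (significant)
  heel_sol: t = 3.094, df = 9, p = 0.0064 (significant)
  forefoot_ta: t = 1.525, df = 9, p = 0.0808 (trend)
  forefoot_sol: t = 2.726, df = 9, p = 0.0117 (significant)
```

Reading the output: at rest the muscles sit near 1.3 µV RMS; slow 3.5 bar
pulses evoke ~2 % of MVC_RMS while fast pulses evoke ~4–6 %, and the
paired tests show the fast rise significantly increases the response in
three of four conditions (Forefoot-TA only trends). The plates themselves
rotate the ankle by about −1.3° (heel, dorsiflexion) and +1.1°
(forefoot, plantarflexion).

The other drivers: `01_protocols.py` builds the schedules and force
patterns (64-trial single-pulse session; cyclic heel 0–2 s / forefoot
1–3 s per 5 s cycle, i.e. 1.22 km/h at a 0.85 m step);
`02_synthetic_cohort.py` generates a ten-subject synthetic cohort and runs
the full EMG detection chain over it; `03_kinematics.py` measures
plate-induced angle changes and screens fast trials for reflex-induced
perturbations.

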