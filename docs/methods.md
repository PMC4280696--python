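# Methods

## The measurement problem

A pneumatic shoe platform loads the sole of a supine subject's foot through
two pressure plates (heel and forefoot) to emulate the ground reaction
forces of walking. Loading the sole evokes reflexes in the lower-leg
muscles — tibialis anterior (TA) and soleus (SOL) — and mechanically moves
the ankle. The analysis pipeline quantifies three things per stimulus:

1. whether a reflex occurred (surface-EMG burst detection),
2. how large the evoked activity was (MVC-normalized RMS), and
3. how much the plate extension itself rotated the ankle, and whether a
   strong reflex added an extra perturbation on top of that movement.

No raw recordings are available for this protocol, so a synthetic-session
generator supplies EMG, marker and trigger data with the statistical
structure the pipeline assumes; the published per-subject summary tables
ship as fixtures and anchor the statistics stage exactly.

## Stimulation model

Plate force amplitude is the manufacturer's static calibration per supply
pressure: 160/200/240/280 N on the heel and 100/125/150/175 N on the
forefoot at 2/2.5/3/3.5 bar. The table is exactly linear (80 N/bar heel,
50 N/bar forefoot), so intermediate pressures are linearly interpolated;
extrapolation outside [2, 3.5] bar is refused because the calibration's
behavior there is unknown.

The commanded force over time is a trapezoid: linear rise over the plate's
full-extension time (0.05 s "fast", 0.2 s "slow"), hold, linear fall. The
true rise shape is not measured; a piecewise-linear profile is the simplest
shape consistent with the platform's target pattern. The retraction speed
is likewise uncalibrated, so the fall time defaults to the rise time and is
configurable.

Two protocols are generated:

* **single-pulse** — the full crossing of 4 pressures × 2 rise speeds ×
  2 locations, each combination 4 times (64 trials), 0.8 s pulses every
  30 s in seeded random order (`numpy.random.default_rng(seed).permutation`);
  an optional gap after trial 32 models the mid-session rest.
* **cyclic walking-like loading** — per gait cycle of duration *T*, the
  heel plate is up for [0, 0.4 T] and the forefoot plate for
  [0.2 T, 0.6 T], after a 5 s lead-in rest, for 9 cycles. With *T* = 5 s
  this is heel 0–2 s and forefoot 1–3 s of every cycle; the plates overlap
  for 0.2 T (mid-stance), and the sole is unloaded for 0.4 T (swing).
  Walking speed for a cycle is `2 · step_length / T` (two steps per
  cycle), 1.22 km/h for *T* = 5 s and 3.06 km/h for *T* = 2 s at a 0.85 m
  step.

Event windows are half-open `[onset, onset + duration)` in seconds from
recording start; window lengths in samples are `round(duration · rate)`.

## EMG chain

Sampling is 1200 Hz. Preprocessing applies a 4th-order Butterworth
band-pass (5–500 Hz) and a quality-factor-30 notch at 50 Hz, both
zero-phase (forward–backward), then full-wave rectification. Zero-phase
filtering is used so that filter group delay does not bias burst onset
latencies.

* **MVC reference** — per maximal-contraction repetition, the RMS in a
  500 ms window centered at the maximal rectified sample (truncated
  symmetrically at recording edges); the reference is the maximum over the
  three repetitions. EMG is expressed as %MVC_RMS.
* **Baseline and threshold** — mean and sample SD of the rectified signal
  over the 0.8 s before stimulus onset; threshold = mean + SD. The
  baseline is computed on the rectified signal by default so threshold and
  burst live on the same scale (the mean of the signed signal is ≈ 0,
  which would collapse the threshold to the SD alone); a raw-domain option
  preserves the signed reading.
* **Reflex detection** — a reflex occurred when the rectified signal is
  strictly above threshold for at least 10 ms — 12 consecutive samples at
  1200 Hz — within the 0.8 s stimulation window. Latency is the start of
  the first qualifying run. Two qualifying runs separated by ≥ 20 ms below
  threshold flag a double burst (withdrawal-reflex signature).
* **Occurrence** — percent of repetitions evoking a reflex; with 4
  repetitions the resolution is 25 points.
* **Activity** — single-pulse trials: RMS over the 0.8 s stimulation
  window as %MVC; cyclic trials: RMS pooled over all stimulation windows
  divided by the RMS of the 5 s pre-stimulation rest.
* **Quality flag** — visual outlier screening is replaced by an automated
  rule: a trial is excluded when its baseline SD exceeds 5× the session
  median baseline SD.

## Ankle kinematics

Markers at the medial knee, medial ankle and first metatarsal head are
tracked in the sagittal plane (meters, y up) at 100 Hz. The ankle angle is
obtained by the law of cosines from the three inter-marker distances; the
reported angle is the interior shank–foot angle at the ankle vertex, which
matches the described neutral supine posture of ≈ 150° and decreases under
dorsiflexion. A `printed_offset` convention (+180°) is also implemented
because the source formula is sometimes rendered with that offset; every
angle series records its convention, and the offset reading is never
applied silently.

Motion smoothing is two-stage: a centered moving average of 5 samples
(a moving median is available for spike-heavy traces), then degree-1 LOESS.
The LOESS span defaults to 0.1 of the series; for per-event analysis the
pipeline uses a span equivalent to ≈ 0.15 s, because a local-regression
window must stay shorter than the 0.2 s event plateau — a span of several
seconds would flatten the 0.8 s ramp-and-hold excursions it is supposed to
denoise.

The plate-induced angle change is the mean angle over the final 0.2 s of
the event (the plate is fully extended after at most 0.2 s, so this
plateau excludes the ramp) minus the mean over the 0.5 s before onset.
Negative changes are dorsiflexion (heel plate), positive plantarflexion
(forefoot plate). Reflex-induced perturbations are scored against an
idealized ramp-and-hold fit (baseline level, linear ramp over the plate
rise time to baseline + measured change, hold): a perturbation is declared
when the absolute residual exceeds 0.5° for at least 50 ms within the
event, with magnitude = max |residual|. The 0.5°/50 ms rule makes a 1°
excursion unambiguous while marker-jitter and smoothing residuals
(≈ 0.05°) never fire.

## Statistics

Across-subject aggregates are mean ± sample SD (n − 1), displayed to two
decimals with round-half-away-from-zero (matching the published rendering
of 189.155 → 189.16). The slow-versus-fast comparison at 3.5 bar is a
paired one-sided t-test per condition (Heel-TA, Heel-SOL, Forefoot-TA,
Forefoot-SOL): d = fast − slow, t = mean(d)/(sd(d)/√n), p from the upper
tail of Student's t with n − 1 df, α = 0.05 with strict inequality. The
four conditions are treated as separate experiments; no multiplicity
correction is applied, by design. The published per-subject columns are
shipped as package fixtures; the report module pairs the slow-stimulus RMS
table with the fast-stimulus RMS table (the published footnote citing the
occurrence table instead is a typo, noted in the report output). The test
implementation is cross-checked in the suite against an independent oracle
that integrates the explicit Student-t density by adaptive quadrature.

## Synthetic sessions

The generator emulates, per subject: rest-level rectified EMG (band-limited
5–500 Hz Gaussian noise, exactly rescaled to the published rest RMS of
1.26 µV TA / 1.32 µV SOL); MVC trials (a noise plateau whose 500 ms
center-window RMS equals the subject's MVC level, with a narrow center
boost pinning the recording's maximal sample); stimulus-locked reflex
bursts; and marker traces whose interior ankle angle follows a neutral
150° with ramp-and-hold excursions per event (−1.33° heel, +1.07°
forefoot by default, ramp = plate rise time, 0.1 mm marker jitter).

Reflex occurrence is a Bernoulli draw per event and muscle at the
profile's base probability, multiplied (and clipped to 1) by a
fast-stimulus factor; burst amplitude in %MVC is linear in pressure
through a per-muscle-and-location gain and scaled by the same fast factor.
This encodes the qualitative findings — response grows with pressure and,
much more strongly, with rise speed — without asserting a functional form
the experiments did not measure. Strong fast stimuli (3.5 bar) in
"susceptible" subjects produce double bursts and a ~1° transient
perturbation placed mid-event, clear of the measurement plateau. Every
draw is recorded in per-event ground truth. The 60 ms burst latency is a
placeholder — no latencies were measured for this protocol — and is
labelled as such in ground truth.

Burst construction: a Gaussian-envelope burst whose carrier mixes a
positive pedestal (70 %) with 20–250 Hz noise. The pedestal keeps the
rectified profile supra-threshold through the burst core (as the elevated
envelope of a real motor-unit interference burst does), so a burst whose
amplitude clears the threshold also satisfies the 10 ms duration
criterion; it tapers to zero for bursts above ~100 µV, where noise alone
is tens of times the threshold and the pedestal's low-frequency energy
would otherwise smear rectified ringing into the silent gap between double
bursts. The finished burst is filtered through the same 5–500 Hz + notch
chain the analysis applies and then rescaled, so its peak equals the
target amplitude exactly at generation and survives the analysis
refiltering within a few percent. The 20–250 Hz carrier band is the flat
interior of the analysis pass-band (and the bulk of real surface-EMG
power).

What the generator does **not** emulate: real motor-unit recruitment and
firing statistics, latency variability, fatigue, movement artifact,
electrode noise, cross-talk between muscles, the gastrocnemius
contribution, or 3-D kinematics and soft-tissue artifact. Passing
recovery tests therefore demonstrates that the pipeline is a consistent
estimator of the quantities the generator encodes — not that it would
perform identically on human recordings, in particular where real bursts
dip below threshold mid-burst.

## Problem sizes and numerical choices

Recovery checks use compressed trial spacing (2–4 s instead of 30 s, still
leaving a full 0.8 s baseline before each pulse) and 200 repetitions for
occurrence recovery, judged against 3 binomial standard errors; angle
recovery uses 10 trials per location with a ±0.05° band. Filters are
applied as second-order sections for numerical stability; the arccos
argument in the angle computation is clipped to [−1, 1] with a 1e−9
tolerance; degenerate inputs (coincident markers, zero difference
variance, empty factor lists, out-of-range pressures) raise explicit
errors rather than propagating NaNs.

## Known limitations

* Occurrence estimates inherit the detector's false-positive rate on
  rest-level noise (empirically ≈ 0 at these settings, but not provably
  zero for arbitrary baselines).
* The published occurrence table from the human study depends on
  single-subject recordings and is not reproducible from summaries; only
  its semantics (quarter-resolution percentages) are exercised.
* The trapezoid force profile and the linear pressure→amplitude link are
  modelling choices; the platform's true force output was not recorded.
* The ramp-and-hold perturbation fit assumes the plate movement dominates
  the trace; perturbations overlapping the final 0.2 s plateau would bias
  the plate-change estimate they are judged against.
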