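# Methods

This note documents the models, conventions and design decisions behind
`alarmcast`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Problem framing

Monitor alarms are two-tiered: an advisory (yellow) alarm fires when a vital
sign breaches a first threshold, a critical (red) alarm at a second, more
extreme one, each after a persistence delay (e.g. 10 s) that lets transient
excursions self-correct.  The prediction task is binary classification at
the yellow-alarm instant: will at least one red alarm, of any category,
follow within the post-alarm window?  Specificity is deliberately fixed high
(0.98) because clinicians tolerate missed predictions (the threshold alarm
still fires as usual) far better than false critical alarms.

Episode windows are anchored so the final 1 Hz grid point coincides with the
alarm instant: the pre window is the closed interval
`[t − pre + 1 s, t]` on an integer-second grid, the post window the
half-open `(t, t + post]`.  A red alarm at exactly the anchor instant is not
"following" — prediction must precede the event.

## 2. The synthetic monitor generator

The generator emulates only what the downstream analysis is sensitive to;
it is a study-conditions definition, not a physiological model.

**Vital signs.**  Each signal is `baseline + events + AR(1) noise` sampled
near 1 Hz with uniform timestamp jitter ≤ 0.2 s.  The AR(1) lag-1
coefficient is 0.95 and `*_noise_sd` parameters are *stationary* standard
deviations (innovations are scaled by √(1−φ²)), so configured noise levels
are directly interpretable.  Defaults: HR 150 ± 4 bpm, BR 50 ± 3 /min,
SpO2 96 ± 1 %.

**Desaturation events.**  Arrivals are homogeneous Poisson at
`event_rate_per_h`, restricted to a margin-trimmed window
`[300 s + precursor_lead, duration − 200 s]` so every pre-alarm window and
every event's post window lies inside the record.  Event depths are
lognormal (default median 12 % SpO2, log-sd 0.5); an event is *red-crossing*
when its depth exceeds `baseline − red threshold`.

The dip shape is deliberately **two-phased**:

1. *Common onset phase* (30 s): every event falls exponentially (τ = 5 s)
   to a shared plateau 11 % below baseline — below the yellow threshold but
   above the red one.  Because this phase is identical in distribution for
   mild and severe events, the trajectory observed up to and including the
   yellow alarm carries no information about eventual severity.
2. *Divergent phase*: red-crossing events continue falling (τ = 5 s) to
   their full depth, hold near nadir 15 s and recover (τ = 20 s);
   non-crossing events recover directly.

The only learnable pre-anchor signal is a **precursor drift**: red-crossing
events are preceded by a linear SpO2 (default 4 %) and HR (default 6 bpm)
down-ramp over the final `precursor_lead_s` (default 60 s) before onset,
mirroring the empirical observation that case and control vital signs
diverge only in the last minute before the advisory alarm.  Setting the
drift magnitudes to zero makes the outcome depend solely on post-anchor
event depth, which is the designed negative control: a correct pipeline
must then score near chance.  Deep desaturations co-occur with a bradycardia
dip (HR to 65 bpm, below the red threshold) with probability
`brady_coupling_prob` (default 0.3), starting in the divergent phase.  In
the negative-control condition this coupling is also disabled, because an
HR-low anchor would otherwise reveal the (deep-event) outcome through the
alarm-category feature.

**NN intervals.**  Beats occur where the integrated instantaneous heart
rate crosses whole numbers, giving NN ≈ 60/HR(t); beat-time jitter
(σ = 10 ms) supplies short-term variability, and heart-rate decelerations
around events lengthen NN through the HR dip itself.  Detection artifacts
are injected by replacing a fraction `nn_artifact_rate` of intervals with
values in 1.6–2.5 s (> the 1.5 s cleaning bound).

**Missingness.**  Per-sample dropout (default 1 %) plus Poisson-started
bursts (default rate 5·10⁻⁴/s, length 20 s), independent per signal.

**Alarm logic.**  One alarm per continuous excursion beyond a threshold
lasting at least `delay_s` (default 10 s), timestamped at excursion start +
delay; SpO2 is first smoothed by a trailing 8 s moving average.  Missing
samples break excursions, but gaps ≤ 5 s have already been bridged by the
resampling spline (see §3).  BP and fibrillation alarms are accepted by the
parsers but never emitted; apnea is likewise not simulated (chest-impedance
apnea detection is unreliable and such events surface as
desaturation/bradycardia).

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: motion artifacts correlated across signals,
care-intervention effects (a nurse response that truncates an incipient
event mislabels it), non-stationary baselines, circadian structure,
category-specific physiology behind SpO2-high/BP alarms, and real R-peak
detection error structure.  Synthetic separability is intentionally clean;
absolute AUROC values on synthetic cohorts say nothing about clinical
performance — only the pipeline's correctness properties transfer.

## 3. Preprocessing conventions

* **Resampling**: cubic spline through non-missing samples, evaluated on
  the integer-second grid; no extrapolation beyond the first/last present
  sample; fewer than 4 usable samples → all-missing (not an error).
* **gap_max_s = 5**: the spline bridges gaps ≤ 5 s; grid points strictly
  inside longer gaps stay missing.  Rationale: short telemetry hiccups are
  interpolable, but long holes must remain visible to the sufficiency
  filter rather than being hidden by a smooth interpolant.
* **Sufficiency filter**: a pre-window is discarded if, for any single
  signal, the missing fraction is ≥ 30 % or the longest consecutive missing
  run is ≥ 10 % of the window.  Both boundaries are inclusive, and the rule
  is applied per signal (the stricter of the readings of an ambiguous
  criterion).  The filter is monotone: marking more samples missing can
  only flip keep → discard.
* **NN cleaning**: intervals > 1.5 s are removed before any HRV
  computation.

## 4. Feature registry

The 63-feature inventory is frozen in `features.FEATURE_COLUMNS` (families
meta 3 / category 1 / alarm-counts 2 / HR 13 / BR 13 / SpO2 13 /
correlation 6 / HRV 12).  Specific conventions:

* Population (divide-by-n) standard deviations throughout.
* Per-signal 13: occurring-moment value (last present sample), mean, SD,
  min, max, range, full-window and last-50 s least-squares slopes, last-50 s
  mean, seconds beyond the yellow and red thresholds, number of
  yellow-threshold excursions, and occurrence value minus the first-30 s
  mean.  The 50 s sub-window reflects where case/control trajectories
  visibly diverge.
* Threshold features: BR uses fixed clinical thresholds 30 (yellow) / 25
  (red); HR and SpO2 take the alarm settings in force.  "Beyond" is
  *below* for low-type signals; the anchor category's signal adopts its own
  orientation (an HR-high anchor flips HR to above-200/220), other signals
  default to low-type.  SpO2-high has no red counterpart; its red bound
  saturates at 100 so time-beyond-red is identically zero rather than
  undefined.
* HRV: SDNN/SDDec/meanNN evaluated every 10 s over trailing 30 s windows
  (`(t−30, t]`, ≥ 3 NN samples else missing).  Deceleration runs are
  maximal runs of strictly increasing NN of length ≥ 2 — a declared
  convention, since published definitions vary.  The occurring-moment mean
  NN is computed directly on the final 30 s (defined for any nonempty
  window).  AUC features integrate `max(NN − q10, 0)` trapezoidally in beat
  time, with q10 the 10th percentile of pre-window NN; AUC_Dec restricts
  the integral to deceleration runs.
* The anchor category is encoded as a single integer code over the frozen
  six-level vocabulary, preserving the 1-feature count; trees split on it
  natively.  Pre-window alarm counts exclude the anchor itself.
* Metadata: gestational age at birth; postnatal age at the anchor
  timestamp; postmenstrual age = gestational + postnatal/7.

## 5. Selection, classification, evaluation

* **Split**: episode-level 80/20, stratified by label, irrespective of
  infant — replicating the study design being implemented.  Within-subject
  splitting is optimistically biased relative to leave-infant-out
  generalisation; this is a documented property of the design, not a bug to
  fix here.
* **Selection**: for each of the HR, BR, SpO2, correlation and HRV
  families, all subsets of cardinality 1, 2, … are scored by mean 5-fold CV
  AUROC of a gini tree (depth ≤ 6); the search stops at the first k where
  best(k+1) − best(k) < 0.001 and keeps the best k-subset.  Ties break by
  frozen column order, then smaller subset.  A configurable hard cap
  (default k ≤ 8) guards against pathological non-convergence of the stop
  rule; in practice the rule stops at k ≤ 4.  Metadata, category and
  alarm-count features always enter the pool in full.
* **Missing values** are routed by the tree learners' learned default
  directions (sklearn ≥ 1.3 trees and XGBoost both support this natively);
  no imputation anywhere.
* **Operating point**: the threshold is the smallest score cutoff whose
  empirical specificity reaches the target on *out-of-fold training
  scores* (5-fold, stratified), then applied unchanged to test data.
  Fixing the threshold on training keeps the test set untouched until final
  evaluation; test-set specificity therefore fluctuates around the target.
  Sensitivity at specificity uses no interpolation; with all scores tied
  the point is flagged unattainable (sensitivity 0 at +∞).
* **AUROC** is the rank/concordance definition with ties counted ½.
* **Boosting**: XGBoost, depth ≤ 6, 200 rounds, learning rate 0.1,
  single-thread `hist` for determinism.  Early stopping is available
  through the round count in config but off by default — rounds and rate
  are already fixed configuration, and a held-out stopping fold would
  shrink training data without changing any tested property.
* **Gain**: per-feature total loss reduction summed over all trees
  (`total_gain` in XGBoost); for a single sklearn tree, the analogous
  weighted impurity reduction normalised by the root sample count.
* Seeding: a single master seed; per-infant simulator streams derive from
  `SeedSequence([seed, infant, stream])`; splits, folds, trees and boosters
  reuse the master seed directly and are recorded in the run manifest.

## 6. Burden projection

Pure integer/rational arithmetic.  Count products truncate (floor): with
sensitivity 0.33 and specificity 0.98 this reproduces printed study-scale
results exactly (56,415 × 0.33 → 18,616; 232,823 × 0.02 → 4,656), whereas
round-half-up would not (18,617).  Ratio and percentage-increase round half
up; the auditory-reduction percentage is reported to one decimal.  The
interquartile range of lead times uses linear interpolation between order
statistics.  Degenerate denominators (no baseline reds, no false positives)
flag the affected field rather than raising.

## 7. Problem sizes used by the tests

Chosen as the package's own test conditions: the stochastic
signal-recovery checks run one synthetic cohort of 20 infants × 10 h at 14
events/h (≈ 2,800 events → ≥ 2,000 valid episodes) with pre/post = 120/60 s
— the best-performing window pair — in three conditions (precursor on;
labels shuffled, averaged over three shuffles to keep Monte-Carlo error
well under the tolerance; precursor and coupling off).  End-to-end
reproducibility runs the CLI twice on a 4-infant × 1 h fixture and compares
artifact hashes.  Unit and property tests use windows of tens to hundreds
of samples with brute-force oracles (longhand SD, pairwise concordance,
exhaustive subset search, manual impurity recounts).

## 8. Known limitations

* The synthetic generator's separability is tunable and clean; it validates
  the pipeline, not clinical effect sizes.
* Episode-level splitting shares infants across train and test (see §5).
* Persisted episodes store post-red lead times but not post-red categories;
  rebuilding a feature table from disk is bitwise-exact, but category-level
  post-hoc analyses need the original alarm log.
* Alarm de-duplication, intervention annotation, ventilator alarms, raw ECG
  R-peak detection and waveform features are out of scope.
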