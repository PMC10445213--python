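# Methods

This note documents the models, numerical choices and limitations behind
`trailgaze`.  It is written for a user who wants to know exactly what the
package computes and what its synthetic-data validation does and does not
establish.

## Coordinate systems and geometry

Gaze samples and clicks are stored in pixel space (0-based, origin
top-left, y down) and analyzed in degree space (origin at screen center,
y up).  Conversion is per-axis and exact:
`angle = arctan(offset_cm / viewing_distance_cm)`, invertible to machine
precision.  The default geometry is a 1024×768 px display of 36×27 cm
viewed at 71 cm.

One consequence of the exact (tan-based) mapping: the 5×5 target grid of
4.32° cells spans 21.6°, which slightly exceeds the exact vertical screen
extent (2·arctan(13.5/71) = 21.53°) while fitting the linear small-angle
extent (27 cm · 180/π / 71 = 21.79°).  Layout feasibility is therefore
checked against the linear extent; target centers keep a 0.675° margin to
their cell border, so no target center approaches the ambiguous zone.

## Trial layouts

Targets are 1.35°-diameter circles, one per grid cell, placed uniformly
within the cell minus the 0.675° margin.  Because the margin equals the
circle radius, any two targets in adjacent cells are automatically at
least 1.35° apart center-to-center — the configured minimum separation —
and rejection sampling over the whole layout (retry budget 1000) guards
arbitrary user-supplied separations.  The minimum separation is
interpreted center-to-center, following the letter of the apparatus
description even though two circles at exactly 1.35° touch.

## Event detection

An I-VT-style classifier with the standard clinical-eye-tracking
thresholds: a sample belongs to a saccade when smoothed velocity ≥ 30°/s
or smoothed acceleration ≥ 8000°/s².  Choices the thresholds do not fix:

* **Smoothing** — 5-sample moving average of position before central
  finite differences (exposed as `smooth_window`).  Commercial parsers
  smooth similarly but their internals are proprietary; a plain
  finite-difference velocity at 1000 Hz would amplify sample noise.
* **Boundary refinement** — smoothing smears event edges by up to half a
  window, which would bias fixation durations by 1–3 ms.  Each
  supra-threshold run's boundaries are therefore re-snapped to the
  threshold crossings of the *unsmoothed* derivatives within one window.
  On noise-free traces this recovers planted event boundaries exactly.
* **Blinks** — maximal runs of invalid samples ≥ 10 ms; shorter dropouts
  are linearly interpolated (at 1000 Hz a 1–2 sample dropout is tracker
  noise, not an eyelid).  Fixations and saccades overlapping any blink
  window extended by 50 ms on both sides are removed — note this always
  removes the events bordering a blink, by design.  Blink exclusion runs
  before the analysis filters (fixations ≥ 50 ms, saccades ≥ 0.1°), so a
  short fragment next to a blink never survives via the filter order.
* **Degenerate traces** — no valid samples yields empty event frames and
  a logged warning, not an error; a trace shorter than the smoothing
  window is rejected.

Detection is translation-invariant and, on noise-free rendered traces,
recovers planted fixation counts exactly, durations within one sample and
amplitudes within 0.2° (test-enforced).

## The nine test scores

1. **Completion time** — trial-start click to the *first correct* click
   on the last target, in seconds.  "First click on the last target" is
   read as first correct click (a miss does not land *on* the target);
   a toggle is not provided but the resolver exposes all clicks.
   Undefined (NaN, logged) if the last target is never hit.
2. **Speed–accuracy slope** — per-target click accuracy
   `max(0, 1 − d/r)` is clipped to [0.01, 0.99], logit-transformed and
   regressed on per-target reaction time (OLS); the slope is the score
   (accuracy is the response — "log odd accuracy ~ rt").  Reaction time
   is the inter-correct-click interval; error clicks do not reset the
   clock.  Undefined with < 3 usable targets or zero RT variance;
   exactly 0 when accuracies are constant after clipping.
3. **Median fixation duration** (ms), 7. **median saccade amplitude** (°)
   — sample medians over filtered events; even counts use the central
   midpoint; empty event lists give NaN.
4.–6. **Fixation counts** — a fixation falls on the target nearest its
   centroid if within 3.25° (ties break to the lower sequence index);
   *guiding* if that target is the current (lowest un-hit) target at
   fixation *onset*, *searching* otherwise, *unassigned* beyond 3.25° of
   every target.  `n_fixations` counts all three classes.
8. **Eye–hand span** — per target, the correct click time minus the onset
   of the first fixation on that target since it became current; positive
   = eyes led the hand, and a look that begins just after the click
   yields a negative span.  The trial value is the median across targets
   (the per-trial aggregation is not dictated by the score's definition;
   median was chosen for robustness, and `which="last"` switches to the
   last pre-click look).  Targets without such a fixation are skipped.
9. **Scanpath length** — summed Euclidean distance between consecutive
   fixation centroids, which on filtered streams closely tracks the sum
   of saccade amplitudes.

Undefined scores propagate as NaN.  Condition aggregation averages the
(default 2) trials per subject × session × part × instruction cell and
drops subjects missing a session (listwise, logged); reliability then
requires complete n×2 tables.

## Reliability statistics

**ICC(A,2)** is the two-way, absolute-agreement, average-measures
coefficient.  The 95% CI is the McGraw & Wong F-based interval: the
single-measures bounds on Satterthwaite degrees of freedom, stepped up by
Spearman–Brown — the same construction the standard R and Python
reliability packages use, verified in the tests against an explicit
sums-of-squares oracle (1e-10) and against `pingouin` (to its printed
precision).  A perfect-agreement table returns exactly 1.0 with a
degenerate (point) interval.  Classification bounds overlap in the usual
verbal scheme; boundaries are assigned to the *lower* class, consistent
with "excellent" being strictly > 0.80.

**Bland–Altman**: differences are session 1 − session 2, so positive bias
means larger measures in session one.  The bias CI uses the t reference
distribution; the LOA standard error uses the classical approximation
`sd(d)·√(3/n)`; the proportional-bias slope comes from OLS of d on the
pair mean with its two-sided p (significance 0.05, no multiplicity
adjustment — deliberately, mirroring standard practice for these
descriptive panels).  Constant differences give slope 0 exactly rather
than a 0/0 regression.

## Precision simulation

A population of 100,000 paired scores is drawn from a bivariate normal
with equal means and variances and pair correlation equal to the
predefined "true ICC"; per replicate, n individuals are subsampled
without replacement and the F-based 95% CI of ICC(A,2) computed; bounds
are averaged over replicates (median and percentile-of-estimates
aggregations are provided as alternatives).  Two parameterization facts
worth stating explicitly:

* With k = 2 and equal moments, the population value of the
  *average-measures* coefficient is the Spearman–Brown value
  2ρ/(1+ρ), not ρ.  The simulation deliberately parameterizes by the pair
  correlation ρ — "data whose single-measures reliability is ρ" — which
  is what reproduces the published precision table for this design.
* For *coverage* experiments (does the 95% CI contain the nominal value
  95% of the time?) the nominal value must be the population ICC(A,2)
  itself; the cohort generator's default `icc_scale="average"` therefore
  sets the latent pair correlation to icc/(2−icc).  Under
  `icc_scale="pair"` the configured value is the pair correlation
  directly.  Conflating the two scales makes coverage fail badly at high
  ICC (≈ 64% at 0.8), which is why the switch is explicit.

Default replication is 10,000 (the desk-scale scripts use 1,000–2,000,
where the Monte-Carlo error of a mean bound is already < 0.01).
Degenerate subsamples (non-finite interval) are redrawn with a logged
count.  CI bounds are reported unclipped except for the mathematical
bound at 1.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analysis is validated under.

**Traits.**  Each subject carries latent values per session — fixation
duration mean (Gamma mean 180 ms, between-subject SD 15), searching rate
(Poisson rate 4.5 per target, SD 1), eye–hand lag (1000 ± 250 ms), click
dispersion (0.30 ± 0.06°), movement-speed factor (1 ± 0.15), and a
guide-skip probability (0.35 ± 0.10: the chance a target is clicked
without a final guiding look, which is what makes guiding counts vary
across subjects at realistically low levels, ~16 of 25).  Session pairs
are bivariate normal at the correlation implied by the configured ICC and
scale (above), truncated to physical bounds.  Means and SDs were chosen
once to land trial scores in the ranges healthy adults produce on this
task (completion ≈ 35–65 s, ≈ 130–190 fixations, fixation durations
≈ 180 ms, spans ≈ 1–1.6 s) and are all exposed in `TraitSpec`.

**Trials.**  For each target in sequence: a Poisson number of searching
fixations on other objects (preferring nearby ones, exp(−d/4°)
weighting), one guiding fixation within 0.1° of the current target
(unless skipped), then a click at guiding onset + lag (+ Gaussian noise,
SD 50 ms); the accuracy instruction multiplies the lag by 1.5 and the
click dispersion by 0.5, reproducing the expected direction (higher
accuracy, longer spans).  Clicks that miss are followed by a re-click
150 ms later.  Fixation durations are Gamma (shape 40, floor 80 ms);
saccade gaps follow the main-sequence approximation
duration = 2.2 ms/° × amplitude + 21 ms.

Three construction invariants make planted quantities *exactly*
recoverable by the scorer, and are what the round-trip tests rely on:
a searching fixation's object is never the current target at its onset
(nor the current or upcoming target of its block), consecutive fixations
always sit on different objects (≥ 1.15° apart, hence detectable), and a
guiding fixation's onset always falls after the previous target's click
(dwelling on the previous fixation when needed).  Realized values — not
the input parameters — are recorded as per-trial ground truth, so
Poisson draws and miss-retries do not blur the comparison.

**Raw traces.**  Fixations render as centroid + optional Gaussian jitter
at 1000 Hz; inter-fixation gaps as raised-cosine position ramps (peak
velocity Aπ/2D, above the 30°/s threshold for amplitudes ≥ 0.5° at
main-sequence durations; edge acceleration Aπ²/2D², above 8000°/s² for
amplitudes ≳ 0.9°, which is why boundary recovery is exact for
inter-target saccades); blinks as invalid samples.

**Datasets.**  The full design is subjects × 2 sessions × 2 parts × 2
instructions × `trials_per_condition` (default 2, i.e. 8 scored trials
per session); layouts are random per subject/condition/trial and reused
across the two sessions, as in the emulated procedure.  Training trials
(8 targets) contribute no scores and are not synthesized.  Everything is
keyed by `SeedSequence` tuples, so identical seeds give byte-identical
outputs at every level.

**What passing tests do and do not show.**  The generator validates the
*analysis chain*: detection recovers what was rendered, scores recover
what was planted, reliability statistics recover configured ICCs at
nominal coverage.  It does not emulate real oculomotor data: no
measurement noise spectra, drift or calibration error, no pupil signal,
no main-sequence velocity variability, no error-click strategies beyond
Gaussian dispersion, no subject exclusions or tracking loss.  Empirical
reliability values for human data are therefore outside what these tests
can certify; the package reproduces the reliability *methodology* and the
precision table, not the human results.

## Pipeline and file formats

Data files are comma-separated text with `# key = value` metadata headers
(package version, seed, parameter hash); report tables are tab-separated;
gzip is transparent.  Coordinates rest in pixels; degrees appear once, at
detection.  Readers validate schema (missing columns named) and data
invariants (monotone timestamps per trial, contiguous layout indices).
Stages (`simulate`, `detect`, `score`, `reliability`, `precision`) are
individually re-runnable; `detect` skips itself when no raw samples file
exists, so event-level datasets flow directly to scoring.  Reruns under
the same config are byte-identical (test-enforced).

## Known limitations

* Current-target bookkeeping assumes the trial's click stream is
  complete; a lost click would shift all later labels.
* The guiding/searching taxonomy uses a single 3.25° assignment radius;
  overlapping assignment zones of adjacent targets are resolved by
  nearest-center only.
* ICC machinery is specialized to k = 2 sessions (the design analyzed);
  the CI construction generalizes but is not exposed for k > 2.
* The precision simulation treats the subsampled pairs as exchangeable
  individuals; it does not model condition structure within subjects.
* Sample sizes in the emulated design are ambiguous in the source
  material (30/31 and 33/34 appear); the precision grid follows the
  printed table rows (31, 34) and `n` is a free parameter everywhere.
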