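# Methods

## The task and its coordinate frame

The pursuit stimulus is a ball on a 1366x768 display (14-inch panel,
355.6 mm diagonal, square pixels assumed, 50 cm viewing distance) moving at
250 px/s through five stages over 14 s: 1 s static, 5 s of rectilinear
motion with specular reflection at the screen edges, a 2 s stop, 5 s more
motion resuming the held direction, and a final 1 s stop.  At 60 Hz the
trajectory has exactly N = 840 samples.  The initial direction is drawn
uniformly on [0, 2*pi) from a seeded generator, so every session is
reproducible from one integer.  Coordinates are 0-based pixels, origin
top-left, x rightward, y downward; none of the indices depend on that
orientation choice.

Reflection is resolved inside a frame by folding the overshoot back across
the edge (not by clamping), which preserves the per-frame path length;
corner hits fold both components.  The generator logs each bounce at the
sample index where the sign of the per-step displacement flips, which is the
same convention the detector `find_bounce_points` uses, so detected and
ground-truth bounce sets agree exactly.  Segment boundaries for the
regression direction index are the stage transitions and these bounce
apices; the apex sample itself is excluded from both adjacent segments
because the within-frame fold places it slightly off one of the two lines.

Raw gaze recordings arrive as irregularly timestamped samples (the low-cost
tracker this pipeline targets delivers ~20 Hz effective).  They are brought
onto the uniform 60 Hz clock by strictly linear interpolation between the
bracketing raw samples — no smoothing — with t = 0 at the first raw sample.
The loader makes no nominal-rate assumption; the empirical rate is measured
from the timestamps.  Off-screen samples are kept (the indices tolerate
them); clamping to the screen rectangle is available but off by default.

## The three similarity indices

**Spatiotemporal colocality.**  Both trajectories are snapped to the integer
pixel lattice (round half away from zero) and dressed with closed lattice
balls: radius r1 for the target, r2 for the gaze, radii specified in mm and
converted to pixels as real values.  The index is

    Co = sum_t |B_r1(o(t)) n B_r2(g(t))| / sum_t |B_r2(g(t))|.

Balls are not clipped at screen edges, so the denominator's per-frame
cardinality is center-independent — which is what makes the normalization
an average containment fraction.  With r2 <= r1, Co = 1 iff every gaze ball
sits inside its paired target ball.  The default radius grids are
r1 in {5, 10, 15} mm and r2 in {2, 4, 8} mm.  Implementation: the offsets of
the r2-ball are enumerated once and tested against the r1-ball per frame,
vectorized in chunks; a brute-force lattice scan serves as the test oracle.

**Direction difference.**  Per-step motion angles are theta(t) =
arctan2(dy, dx).  The sample index is 1 - |mean_t exp(i(theta_o - theta_g))|,
i.e. one minus the circular mean resultant length of the per-step angle
differences: 0 for coherent tracking (including any constant angular
offset), approaching 1 for uniformly scattered directions, with range
[0, 2].  The modulus is taken before subtraction so the index is real; only
steps where *both* trajectories move contribute, because a stopped target
has no defined angle (arctan2(0, 0)) — stop phases are therefore excluded.
The regression variant fits a total-least-squares (principal-axis) line to
the gaze points of each straight target segment and averages the acute
orientation difference to the segment, folded to [0, pi/2]: a fitted line
has an orientation, not a direction, and TLS remains defined for vertical
segments where y-on-x regression is not.  Segments with fewer than three
gaze samples or with all points coincident are skipped with a warning.

**Polygon area.**  The trajectory is cut into non-overlapping windows of n
samples (defaults n in {15, 30, 45, 60, 90}, i.e. 250-1500 ms at 60 Hz; a
trailing partial window is dropped), each window's points are closed into a
polygon in temporal order, and the absolute Shoelace area

    A = 1/2 |sum_i (x_i y_{i+1} - y_i x_{i+1})|

is averaged over windows.  The signed Shoelace sum handles self-intersecting
polygons by orientation cancellation, which is the behavior wanted for gaze
loops.  For cohort comparisons the per-subject means are divided by the
cohort-wide maximum for that window length ("normalized units"), a monotone
rescaling into [0, 1].

## The reference cohort table

`spemlab/data/table1_fixture.csv` transcribes the per-subject index values
of the original pilot cohort (nine patients with schizophrenia under
treatment, nine controls); `table1_printed_means.csv` carries the printed
group-mean rows and significance flags.  Recomputing column means from the
per-subject values reproduces every printed mean within +-0.005 except four
columns — Delta-theta-sample SZ (0.642 vs 0.66), colocality (10, 4) SZ
(0.956 vs 0.95), colocality (15, 8) SZ (0.976 vs 0.97), and the 1000 ms
area CNT (0.053 vs 0.06) — which are rounding artifacts of the source table
(its means were evidently computed from unrounded per-subject values).  The
reproduction pipeline reports these as known discrepancies rather than
failures; comparisons against printed values round half away from zero to
two decimals.

## Statistics

With nine subjects per group the analysis is non-parametric throughout.
Normality screening uses the Kolmogorov-Smirnov distance against a normal
with sample-estimated mean and SD; because estimating the parameters shrinks
the distance, the p-value comes from a seeded Monte-Carlo (Lilliefors) null
of 10,000 standard-normal samples re-fitted the same way, with
p = (1 + #{D_null >= D}) / (1 + n_mc).  Group differences use the two-sided
Wilcoxon-Mann-Whitney test: exact-permutation p when the pooled sample is
tie-free and n <= 20, otherwise the normal approximation with midrank tie
correction (with two-decimal table data, ties are guaranteed).  Effect sizes
are Hedges' g — pooled-SD standardized mean difference with the
J = 1 - 3/(4N - 9) small-sample correction, positive when the control group
exceeds the patient group.  Alpha is 0.05, two-sided, with no
multiple-testing correction by default (a Holm step-down is available but
off, matching the reference analysis).

## Classifier evaluation

Subjects are represented by a three-feature vector: colocality at
r1 = 5 mm / r2 = 2 mm, the regression direction index, and the 250 ms
normalized polygon area — the most discriminative column of each index
family in the reference table; the choice is configurable because the
original feature columns were not reported.  No feature scaling is applied;
the indices already live on comparable scales.  The classifier is a
soft-margin SVM with Gaussian kernel k(u, v) = exp(-||u - v||^2 /
(2 sigma^2)) — note sigma is the kernel *width*, converted internally to
scikit-learn's gamma.  The point estimate is leave-one-out cross-validation
accuracy (plus sensitivity = patient recall and specificity = control
recall); hyperparameters come from an exhaustive 50 x 50 grid over
C, sigma in {0.1, ..., 5.0}, ties broken toward the smallest C then the
smallest sigma.  On the bundled reference table this selects C = 0.30 and
reaches 17/18 = 94.4% LOOCV accuracy.

Significance uses a label-permutation null: B = 1000 seeded label shuffles,
re-running the full LOOCV with the hyperparameters selected on the original
labels, and p = (1 + #{acc_b >= acc_obs}) / (1 + B), so the smallest
attainable p is 1/(B + 1).  Holding the hyperparameters fixed rather than
re-searching per permutation is a deliberate trade (re-searching is ~2500x
slower); the alternative is available by calling `grid_search` inside a
custom loop.  Variability uses bootstrap resampling of subjects with
replacement (resamples missing a class are redrawn), recomputing LOOCV per
resample, and reporting the mean and the 2.5/97.5 percentile interval.
Bootstrap LOOCV is optimistic-and-noisy by construction — a held-out
subject can have a duplicate in the training fold — so bootstrap means are
reported for context, not as point estimates.

For the permutation-null *calibration* study (shuffling labels on cohorts
where both groups are simulated from the same profile), the statistic is
computed at fixed default hyperparameters (sigma = 0.1, C = 1) for observed
and permuted data alike: calibrating the machinery requires a statistic
fixed a priori, and with near-degenerate hyperparameters the accuracy
distribution collapses to a point and every p-value ties at 1.  At n = 18
the test is conservative (rejection rate below nominal), which is the safe
direction for a screening tool.

## The synthetic gaze simulator

No recordings of the original cohort are publicly available, so a simulator
generates paired target/gaze trajectories with controllable fidelity.  It is
a minimal behavioral model, not an oculomotor one:

* **Pursuit loop.**  The gaze integrates the target velocity delayed by the
  pursuit latency `lag_ms` and each frame closes a `catchup_gain` fraction
  of the positional error to the current target.  Latency therefore shows up
  as a transient after motion onsets and bounces rather than as a standing
  offset of v x lag (50 px at 250 px/s for a 200 ms latency), which real
  pursuit does not exhibit and which would be incompatible with the high
  colocality the reference controls show.  The same proportional term
  performs the exponential post-lapse catch-up.
* **Jitter.**  Isotropic Gaussian noise of SD `jitter_sd_px`, optionally
  AR(1)-correlated (`jitter_ar1`), added to the *recorded* trace.  It models
  oculomotor tremor plus tracker measurement noise (a 0.5 degree tracker at
  50 cm is ~19 px) and deliberately does not feed back into the pursuit
  loop.
* **Attentional lapses.**  Poisson onsets at `lapse_rate_per_s`, gated to
  target-motion periods (pursuit is what loads attention; a lapse while
  parked on a static target is invisible to every index).  During a lapse
  (exponential duration, mean `lapse_duration_s`) the gaze decouples and
  drifts along a random per-lapse direction at `drift_sd_px` px/frame with
  half-scale walk noise, then re-acquires the target exponentially.

Default profiles: controls use jitter 4 px (white), latency 100 ms, lapse
rate 0.02/s, gain 0.3; the impaired profile uses jitter 8 px with AR(1)
0.7, latency 200 ms, lapse rate 0.25/s, mean lapse 0.9 s, drift 6 px/frame,
gain 0.2.  These constants were calibrated once so that simulated group
means of the three headline indices land within +-0.15 of the reference
cohort's printed group means (achieved: SZ colocality ~0.76 vs 0.87, sample
direction ~0.67 vs 0.66, regression direction ~0.19 vs 0.31; controls ~0.98
vs 0.98, ~0.58 vs 0.56, ~0.04 vs 0.09), and so that the direction of every
group difference matches the reference table essentially always.  The
calibration is a regression-tested property of the simulator, not a claim
about the real cohort.

What the simulator does *not* emulate: saccadic structure (main-sequence
dynamics, catch-up saccade counts), blinks and tracker dropouts, anticipatory
pursuit, velocity-gain deficits, or heavy-tailed subject heterogeneity (the
reference patient group contains one severe outlier; the simulated groups
are homogeneous).  Consequently, passing synthetic tests shows the pipeline
recovers group structure of the modeled kind — it does not validate the
indices against real pathology.  The normalized polygon-area levels in
particular depend strongly on cohort composition (division by the cohort
maximum), so only their group *ordering* is meaningful in simulation.

## Numerical choices and degenerate inputs

* Resampling requires the recording to cover the last requested grid time;
  the error names the uncovered interval.  Gaze CSVs are written with 17
  significant digits and read with round-trip float parsing, so save/load
  is bit-exact.
* Zero-displacement steps carry no angle and are masked; trajectories whose
  joint motion mask is empty raise rather than return a vacuous index.
* `reflect_step` rejects steps longer than both screen dimensions as
  nonphysical; the fold-back loop handles multiple reflections per step.
* Disk offsets are cached per radius; colocality memory is bounded by
  chunking over frames (256 frames x |B_r2| offsets).
* Mean-area normalization refuses all-zero cohorts (no scale).
* Grid search iterates C-major ascending and replaces the incumbent only on
  strictly larger accuracy, which realizes the smallest-C-then-smallest-
  sigma tie-break; the SVM fit itself is deterministic, so LOOCV metrics
  carry no seed.
* All stochastic procedures (simulator, permutation, bootstrap, Monte-Carlo
  nulls) take explicit integer seeds; cohort generation derives per-subject
  seeds from one master seed via a seed sequence.

## Problem sizes used by the test suite

Property tests run the metric oracles at 100-1000 random cases; simulator
calibration and ordering checks average 8-100 seeded cohorts of 9 + 9
subjects with the index grid restricted to one representative column per
family (the full 9-pair colocality grid and five windows are exercised
once per run elsewhere); permutation checks use B = 99 for calibration
sweeps and B = 1000 where the floor 1/(B + 1) is the point.  These sizes
keep the full suite in the minutes range while leaving every statistical
assertion several standard errors away from its threshold.

## Known limitations

* The colocality lattice enumeration is exact but O(|B_r2|) per frame;
  very large r2 on high-DPI displays would want a distance-transform
  implementation.
* The regression direction index weights all segments equally, so short
  segments (bounce-dense seeds) carry disproportionate influence — the
  same property the reference analysis appears to have.
* The Lilliefors Monte-Carlo null is recomputed per call; for batch
  screening at fixed n it could be cached.
* Bootstrap LOOCV inherits the duplicated-subject optimism discussed above;
  interpret its intervals as variability envelopes only.
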