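# Methods

## Data model and preprocessing

A *trial* is one participant × task × sensor recording: T × 3 linear
acceleration (m/s², gravity included — see limitations) and T × 3 angular
velocity (deg/s) at a nominal 128 Hz, with per-trial metadata (full task
duration in seconds and an ordinal perceived-difficulty rating
easy = 1 … impossible = 4; a rating of *impossible* implies the trial was not
completed and carries neither duration nor signals).

Preprocessing is a fixed two-step chain applied in this order:

1. **Edge trimming.** `floor(0.05 · T)` samples are removed from each end,
   eliminating task initiation/termination artefacts. Trimming operates on
   sample counts, which at a fixed sampling rate is equivalent to trimming by
   duration; the floor rule makes the trimmed length deterministic. The
   recorded full-task duration (a feature in its own right) is unaffected.
2. **Low-pass filtering.** 4th-order Butterworth, 6 Hz cut-off, applied
   forward–backward (`sosfiltfilt`) on all six channels. Zero-phase filtering
   was chosen because every downstream feature is an amplitude statistic, and
   a one-pass filter's group delay would bias the trimmed edges; the cost is
   that the effective magnitude response is the squared one-pass response.
   DC gain is exactly 1.

The order matters (filter transients interact with the cut edges), so the
pipeline funnels all preprocessing through a single `preprocess()` entry
point.

Units: trial files may declare accelerations in g or m/s²; everything is
normalized to m/s² (and deg/s) on ingestion. Wrist and thigh sensor files can
be read but are excluded from analysis; only head, trunk, sacrum and the two
feet enter the feature roster.

## Movement features

For each preprocessed trial, with `‖·‖` the per-sample Euclidean norm:

- `NormLinAcc_RMS` = RMS of `‖acc‖` (movement intensity, m/s²);
- `NormAngVel_RMS` = RMS of `‖gyr‖` (rotational intensity, deg/s);
- `JERK_RMS` = RMS of `‖d(acc)/dt‖` (smoothness, m/s³). The scalar jerk
  integral `½∫‖d(acc)/dt‖² dt` is also exposed (`jerk_scalar`); the matrix
  feature is the RMS form, which shares the intensity features' scale
  behaviour (both scale linearly with the signal, the integral quadratically).
  Derivatives are central differences with one-sided ends; integration is
  trapezoidal. These discretizations are second-order accurate and verified
  against closed forms (ramp and sinusoid) in the tests.
- Attenuation coefficients `AC_ij = (1 − RMS_j/RMS_i) × 100` for
  (i, j) ∈ {(TR, HE), (SA, HE), (SA, TR)}, computed from the RMS of the
  *linear-acceleration norm* of each sensor; the lower segment is always the
  denominator, so positive values mean attenuation going up the trunk. Whether
  per-axis RMS or the norm RMS is used is a genuine design choice; the norm
  was picked for rotation invariance and consistency with the intensity
  features.
- The full task duration (s).

One participant × task yields 19 variables named `task|sensor|parameter`,
`task|AC_*`, `task|duration`; 8 selected tasks give a 152-column matrix. (A
published analysis of this design reports 153 variables for 8 tasks; the
roster as stated yields 19 × 8 = 152, and this implementation reproduces the
roster as written.) Tasks rated impossible leave explicitly missing cells,
never zeros.

All features are invariant under a common 3D rotation of the sensor frame and
scale linearly (AC: invariantly) with the signal amplitude; both properties
are enforced by tests.

## Task selection

For every task, duration and difficulty are compared across BV/UV/HS with
Kruskal–Wallis (tie-corrected H, χ² p with 2 df). A task is selected iff both
p-values fall below α = 0.05; clinically essential tasks (default: walking in
the dark) are forced in regardless. Dunn's pairwise z tests on the pooled
ranks follow a significant omnibus test only; the three pairwise p-values are
Holm-adjusted within one task × parameter family (no correction across tasks,
matching per-task reporting). Difficulty ratings are treated as ordinal
samples 1–4; participants who rated a task impossible contribute that rating
but no duration observation. If every observation is identical the test is
undefined and (H = 0, p = 1) is returned by convention. A Shapiro–Wilk
diagnostic is exposed but never gates anything: the analysis path is
nonparametric throughout.

## Component analysis

The feature matrix mixes m/s², deg/s, %, and s, so PCA operates on z-scored
columns (sd with ddof = 1), i.e. on the correlation matrix; covariance PCA
would be unit-dominated. Missing cells are imputed first — default
`group_median` (respects group structure, keeps every participant);
`overall_median` and `complete_case` are available. Loadings are
correlation-scaled (eigenvector × √eigenvalue), so a loading is the
correlation between variable and component score. Each component's sign is
fixed by making its largest-|loading| entry positive, which together with the
SVD makes the fit bit-reproducible. With n participants < p variables the
discarded dimensions carry exactly zero variance, so VAF still sums to 100%.

**Retention.** Two-stage:

1. *Permutation test on VAF* (default 1000 permutations, α = 0.05). Every
   column is permuted independently, destroying correlations while keeping
   marginals; component k is retained while its observed VAF exceeds the
   (1 − α) quantile of the k-th null VAF, stopping at the first failure
   (sequential testing; the marginal variant would ignore the ordering
   constraint). Permuting a z-scored column leaves it z-scored, so no
   re-standardization is needed.
2. *Cumulative-VAF cut*: the smallest k (≤ the permutation count) whose
   cumulative VAF reaches 50%; if the threshold is unreachable, all
   permutation-retained components are kept with a warning.

**Variable selection.** Per retained component, the
`min(ceil(0.10 · p), 10)` highest |loadings|; exact ties at the cut are all
included and logged (the only situation where the cap is exceeded). The
reported threshold is the smallest retained |loading|, and the union across
components (first-appearance order) feeds the discriminant screen.

**Bootstrap stability** (default 1000 draws). Participants are resampled with
replacement *within* groups (stratified, preserving the design), the sample is
re-standardized and refitted, and each original component is matched to the
bootstrap component with the highest |Tucker congruence| — greedily from PC1
down, without replacement, sign-aligned to positive congruence. Procrustes
rotation is deliberately not applied: the metrics are reported per component.
Reported per component, as means over draws: Pearson r between loading
vectors, RMS loading difference, congruence coefficient
CC = Σxy/√(Σx²·Σy²), and Cattell's salient-variable similarity s with
hyperplane cut 0.1 (loadings classified salient-positive/-negative/hyperplane;
s = (agreements − disagreements)/(n − both-hyperplane)). The 0.1 cut follows
the component-stability methodology this module re-implements; it is exposed
as an argument. Resamples that zero a column's variance are redrawn and
counted.

## Discriminant screen

Each selected variable gets a Kruskal–Wallis test; pairwise Dunn–Holm
p-values are computed only when the omnibus test is significant (α = 0.05).
No correction is applied across variables — the screen reports per-variable
evidence, matching the per-variable reporting convention of this analysis
family — and group medians/IQRs accompany every result. Significance stars:
\* p < 0.05, ** p < 0.01, *** p < 0.001.

## Synthetic cohort generator

The generator exists so that every stage is testable end-to-end without
recorded data. It emulates 3 groups × 20 participants × 15 daily-living
tasks × 5 sensors at 128 Hz.

**Signals.** Each acceleration axis is a sum of the first three harmonics of
the participant's step frequency (base 1.8 Hz, lognormal 5% between-subject
spread) with fixed axis/harmonic weight patterns, sensor-specific base
amplitudes (feet 3.0 m/s² ≫ sacrum 1.3 ≫ trunk 1.0 ≫ head 0.8, so attenuation
coefficients are naturally positive), white noise, and a band-limited
(4.2–5.8 Hz, below the filter cut-off) "jitter" component whose amplitude
degrades smoothness and therefore drives the jerk features. Angular velocity
is generated identically on a deg/s scale. Durations are lognormal around
task-specific bases (10–35 s); difficulty comes from a latent-normal
threshold model (cuts at 1.5/2.5/3.5 on the latent scale), and a latent value
beyond the last cut yields an *impossible* rating — metadata without signals.

**Random-effect hierarchy.** Between-subject structure is multiplicative and
hierarchical: a weak global intensity factor (lognormal sd 0.05–0.11, largest
for UV, reflecting that group's heterogeneity), a strong locomotor factor
applied fully to foot sensors during locomotor tasks and attenuated
(exponent 0.3) on the upper body, a weak postural factor on non-locomotor
tasks, a smoothness factor that scales only the jitter (jerk-specific
variance), and per-trial lognormal wobble drawn separately for the
acceleration and gyroscope channels (so the three parameters of one trial
correlate strongly but not degenerately). This hierarchy is what gives the
synthetic correlation matrix a dominant locomotor-foot component, a weaker
upper-body component and jerk-specific components — the structure the
component analysis is designed to find. A flat single intensity factor was
rejected during design because it makes the feature matrix near rank-1.

**Planted effects and ground truth.** Effects are registered explicitly:
multiplicative amplitude effects (→ intensity variables), jitter effects
(→ jerk variables), duration effects (→ duration variables), plus a
group-dependent mean of the locomotor factor (patients' foot-movement
intensity reduced across locomotor tasks). The registry maps deterministically
to feature-matrix variable names with direction and combined effect size; the
recovery analyses measure the fraction of those variables the pipeline flags.
Variables planted on tasks the dual criterion can never select (e.g. plain
walking, which carries no duration/difficulty effect) are excluded from the
recovery denominator, since the analysis design discards them before any
variable-level test.

The default scenario (`default_paper_scenario`) plants: foot amplitude
reductions for BV (×0.70) and UV (×0.85) on uneven ground, the inclined plane
and walking in the dark, on top of locomotor-factor means of 0.80 (BV) and
0.90 (UV); a trunk reduction on the inclined plane; head-jerk (dressing) and
sacrum-jerk (wood beam) elevations ×2.5 (BV)/×1.6 (UV); duration ×1.40
(BV)/×1.15 (UV) and latent difficulty +0.9/+0.45 on the seven
effect-carrying tasks, with a difficulty shift but no duration effect on
walking in the dark (which therefore relies on forced inclusion, as
intended). `null_scenario` removes every effect for calibration.

**What the generator does not emulate.** Signals are gravity-free
abstractions (all features are norm-based and the pipeline never separates
gravity, so adding a constant would only shift acceleration-norm levels);
there is no biomechanical gait model, no sensor drift, no orientation
dynamics, and noise is additive white + band-limited jitter only. Passing
tests therefore demonstrate the statistical machinery recovers planted
effects under realistic correlation structure and sample sizes — not that the
features are clinically valid, which only recorded cohorts can show.

## Seeds and problem sizes

Every stochastic operation takes an explicit seed; the pipeline derives
independent per-stage streams from one master seed via `SeedSequence`, and
every synthetic trial derives its own stream from (seed, group, participant,
task, sensor), so generation is order-independent and bit-reproducible.

The test suite runs the reference scenario at the study's sample size
(n = 20/group) for the 50-seed recovery and null-calibration checks, with
metadata-only simulation wherever signals are not needed; permutation and
bootstrap calibration tests use 60 × 20 matrices with 200–500 resamples,
sizes at which the tested properties are already stable. The acceptance
script runs the full pipeline once at default settings (1000 permutations,
1000 bootstrap draws).

## Known limitations

- Gravity is not removed before the acceleration features; on real data the
  acceleration-norm RMS therefore mixes posture (gravity orientation) with
  movement intensity. The filtering/trimming chain operates on the signals as
  recorded.
- The 50% cumulative-VAF rule and the sequential permutation test interact:
  with a very strong first component the final count can be smaller than the
  permutation count; both are reported.
- No multiplicity control across screened variables or across tasks — a
  deliberate reproduction of the per-variable reporting convention, to be
  kept in mind when interpreting counts of significant variables.
- `complete_case` imputation can discard many participants when impossible
  ratings concentrate in one group; `group_median` is the default for that
  reason.
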