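# Methods

## Problem and model

`actidx` classifies school-age children as hyperactive (ADHD combined or
predominantly hyperactive/impulsive presentation) versus typically active
from wrist accelerometry, conditioned on parent-reported activity context.
The modeling assumption is that hyperactivity manifests as *excess motion
relative to what the context calls for*: during exercise or household
activity the two groups move similarly, while during sitting/quiet time the
hyperactive group's motion is elevated. Consequently whole-day motion
summaries are weakly informative at best, and the pipeline's value lies in
stratifying every feature by the diary context before classification.

## Input model and day filtering

A participant contributes one or more study days; each day is a tri-axial
acceleration stream (units of g, timestamps in seconds from midnight,
strictly increasing), a diary of up to 36 half-hour slots between 06:00 and
24:00 with categories {sleeping, sitting_quiet, household, exercise,
not_worn}, and optional heart-rate/GPS/Bluetooth channels. Diary slots are
half-open intervals `[start, start+30 min)`, so boundary samples are
assigned deterministically to the later slot. For hyperactive-group
children, only unmedicated days are analyzed; control days are never
filtered. Participants left with zero days are retained and become
all-missing rows (imputation, not exclusion). Sleeping, not-worn and
unlabeled time never enters any feature: the "whole-day" context is defined
as the union of the three analysis contexts (sitting_quiet, household,
exercise).

## Feature extraction

Windows of 60/300/600 s tile the 06:00–24:00 grid; every length divides the
30-minute slot, so a window has exactly one context. A window is *valid*
when at least 50% of `length × nominal rate` samples are present; invalid
windows carry no values. Per window and axis (X, Y, Z, and the composite
Euclidean-norm signal):

* shape: population skewness `m₃/m₂^1.5` and kurtosis `m₄/m₂²` (both defined
  as 0 when `m₂ < 10⁻¹²`; at least 3 samples required);
* summary: mean, population variance (ddof 0), median, and mean magnitude —
  mean |value| for single axes, mean Euclidean norm for the composite axis
  (the only reading of "magnitude" that is a per-window summary on the same
  footing as mean/variance/median);
* cumulative motion: total variation `Σ|Δ|` (composite: `Σ‖Δ‖₂`), chosen
  because it measures the total amount of motion while being exactly
  invariant to the static gravity offset; at least 2 samples required.

Participant-level aggregation pools valid windows across all analysis days
and reduces each (statistic, axis, window length, context) cell with the
MEAN and population VARIANCE over windows — producing the
"cumulative mean / cumulative variance / mean / variance" style feature
names. Hour-quantile features take the 25/50/75% quantiles (linear
interpolation) of the 1-minute cumulative-motion values within each
(day, clock-hour) group and average them over hours; calendar hours were
chosen over rolling hours for determinism and simplicity. Context-sensor
features are heart-rate mean/variance and Bluetooth mean/max per context,
plus two day-level GPS mobility summaries (radius of gyration on a local
equirectangular approximation, and the fraction of fixes in the modal
~11 m grid cell). All missing values become the sentinel −1 in the final
matrix; downstream stages treat −1 as an ordinary value.

The higher window moments are computed from day-mean-centered power sums
via cumulative-sum segment reductions — algebraically identical to the
window-by-window definition (verified against it in tests) but one pass per
day; centering by the day mean leaves all reported moments unchanged
(they are shift-invariant) while avoiding cancellation against the ~1 g
gravity offset.

## Stability selection

The selector is stability selection with randomized L1-logistic base
learners: B = 200 stratified subsamples of 75% of participants per class,
an L1-penalized logistic fit per subsample with inverse penalty
`C = 0.25 × jitter`, jitter log-uniform on (0.5, 2); a feature scores the
fraction of subsamples in which its coefficient is nonzero (|β| > 10⁻⁸).
Ranking is by frequency, ties broken by mean |coefficient| and then column
order, making the retained top-20 list fully reproducible. The default
penalty was calibrated so that the selector sits in the classical stability
regime: a perfectly separating column is selected in ≥95% of subsamples and
ranks first, while on pure noise no feature's frequency approaches 1
(measured maximum ≈ 0.6). Standardization (z-score; constant columns → 0)
is computed once on the matrix given to the selector — inside the
cross-validation loop that matrix is the training fold only, so no
held-out statistics leak into selection.

## Classification and evaluation

Evaluation is leave-one-participant-out: one fold per child, ensuring no
within-child leakage. The classifier is a balanced random forest (default
2000 trees, √p feature subsampling at splits, unrestricted depth; a
documented stump mode sets depth 1 — "2000 decision stumps or estimators"
admits both readings and unrestricted depth is the conventional practice).
Each tree trains on a class-stratified bootstrap: an equal number of
participants resampled with replacement from each class. Stratification
matters under LOPO — every training fold is one participant short in the
held-out child's class, and with a plain bootstrap that count difference
alone tilts the vote toward the majority class. The score is the fraction
of trees voting for the hyperactive class; the decision threshold is 0.5
with ties going to control (the conservative call). Training rows are
canonicalized by participant id before fitting, so predictions are
invariant to row order.

Feature selection runs *inside* each training fold by default (statistically
clean); a global "outside" variant — selection once on the full matrix — is
available as a switch. In null experiments the outside variant inflated
LOPO accuracy to 0.67–0.80, a textbook illustration of selection leakage,
which is why it is not the default.

Per configuration the predictions reduce to a 2×2 table (hyperactive =
positive), the five diagnostic ratios (undefined ratios are reported as
missing, never as 0), and the 1-df Pearson chi-square against chance
*without* continuity correction — the convention that exactly reproduces
the published statistics (17.37, 5.25, 0.14) on the reconstructed tables.
`reconstruct_tables` inverts a printed, rounded metric row back to integer
tables by exhaustive enumeration over (TP, TN) at fixed group sizes; at
14+14 each published row determines its table uniquely.

The three feature configurations see column blocks of one shared matrix:
`motion_only` = whole-day motion features; `motion_plus_labels` = motion
features of all contexts; `motion_plus_context` = whole-day motion plus
context-sensor features.

## Synthetic cohort generator

The generator exists so the pipeline is testable without clinical data. It
emulates the study conditions: 15 + 15 children, 2 days each, diaries drawn
from a slot-level Markov chain whose stationary category fractions are
`w_c·d_c / Σ` (weights w, mean dwells d; defaults give roughly 48%
sitting/quiet, 22% household, 16% exercise, 13% sleeping, 3% not-worn).
Motion is a per-slot Gaussian-intensity process: slot intensity
`λ = max(0, N(μ_c, σ_c)) × trait`, per-axis signal = gravity + λ·N(0,1)
per sample, plus short movement bursts (probability 0.1/min, 2 s,
amplitude 3λ). Category intensities are μ = 0.003/0.012/0.05/0.15 g for
sleeping/quiet/household/exercise with σ_c = 0.25 μ_c; `trait` is a
per-child lognormal activity factor (sd 0.15) shared across categories —
an overall "active kid" dial that makes whole-day summaries noisy without
carrying group information. Unmedicated hyperactive-group days multiply λ
by 1.35 during sitting/quiet only — the midpoint of the 24.7%–41.2%
quiet-activity elevations observed between matched children — so the group
contrast is context-conditional by construction. Heart rate is linear in
slot intensity (base 75 ± 5 bpm between children, +350 bpm/g, noise 3 bpm),
GPS a two-state home/away process with ~10 m jitter, Bluetooth counts
Poisson with category-dependent rates. Missingness: each labeled slot loses
its sensor data with probability 0.05 (watch off without a diary update);
each context channel drops entirely for a day with probability 0.10.

By default all study days of hyperactive-group children are unmedicated
(families schedule the wear on weekends or medication holidays); this keeps
the two groups' analysis-day counts identical, so data volume carries no
group label. Mixed medicated/unmedicated records are fully supported — the
medication filter then removes the medicated days (which are generated
without the quiet-context elevation).

All randomness flows from one cohort seed through `numpy.random.SeedSequence`
spawning; the per-participant seed is `SeedSequence(cohort_seed,
spawn_key=(participant_index,))`, stable across runs and platforms. RNG
draws are consumed identically for each generated slot regardless of group,
so two generations differing only in the group flag are draw-aligned — the
quiet-context motion ratio between them equals the configured multiplier
exactly, which the tests exploit.

What the generator does *not* model: gait or limb ballistics, diurnal
intensity rhythms, medication pharmacokinetics, diary misreporting, sensor
drift or spectral structure (the signal is white within a slot). Passing
tests therefore show that the pipeline recovers a context-conditional
intensity difference under realistic schedule variability, missingness and
between-child heterogeneity — not that it would achieve any particular
accuracy on real children.

## Problem sizes and numerical choices

Simulated experiments in the test suite and acceptance script run at
6–8 Hz sampling (the statistics of per-sample Gaussian intensities are
rate-independent), 500 trees and 50–100 stability subsamples — sizes chosen
so a full multi-seed experiment completes in minutes on one core. The
sampling rate of the real instrument is stream metadata (default 50 Hz) and
configurable everywhere. Quantiles use linear interpolation; moments are
population (ddof 0) throughout; near-zero variance (< 10⁻¹²) defines the
constant-signal convention for shape features; prediction ties break toward
control; chi-square requires all four marginals positive and raises a
degenerate-table error otherwise (the experiment driver records such
configurations as having no test statistic).

## Null behavior of LOPO at this sample size

A caution for interpreting chance-level results: with 30 participants,
hundreds of correlated features and feature selection rerun inside every
fold, the null distribution of LOPO accuracy is *not* binomial around 0.5.
Because the cohort's group totals are fixed, the training fold's class
counts reveal the held-out child's label, and the selector and deep trees
fit cohort-level flukes from which the held-out child — excluded by
construction — is systematically displaced. In null simulations
(quiet-context multiplier 1.0) held-out vote scores anti-correlate with the
true label and per-cohort accuracy ranges roughly 0.2–0.6, i.e. below-chance
accuracies arise regularly; this mirrors the below-chance classification
rates documented for small-sample cross-validation generally, and is
consistent with a whole-day-motion configuration landing at 0.46 on real
data. The stratified bootstrap removes the class-count channel but not the
fluke-displacement channel. Practical consequence: single-cohort accuracies
near or below chance should be read against a permutation distribution, not
a binomial band.

## Known limitations

* The feature grammar fixes the aggregator pair (mean, variance) over
  windows; other day-level reductions (max, IQR) are not implemented.
* "Mean motion" and "mean" are treated as one statistic family.
* GPS features are day-level only; per-context mobility is not computed.
* The published headline accuracies are properties of the original private
  cohort; this package reproduces the *procedure* and the printed
  closed-form statistics, and validates the pipeline's behavior on
  synthetic cohorts with a known ground truth.
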