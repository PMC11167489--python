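# Methods

## The model

A participant's averaged day is a 4-part composition
x = (Sleep, SB, LPA, MVPA), x_j > 0, Σx_j = κ (1440 min internally;
reported as %/day, κ = 100). Closure imposes the constant sum:
C(x) = κ·x / Σx. Compositions are analyzed in isometric log-ratio (ILR)
coordinates built from a sequential binary partition that pivots out
MVPA, then SB, then LPA:

- ilr₁ = √(3/4) ln[ MVPA / (SB·LPA·Sleep)^{1/3} ]
- ilr₂ = √(2/3) ln[ SB / (LPA·Sleep)^{1/2} ]
- ilr₃ = √(1/2) ln[ LPA / Sleep ]

Equivalently ilr(x) = Vᵀ ln x with an orthonormal 4×3 contrast matrix
V, which gives scale invariance (closure before or after the transform
is immaterial), an exact inverse, and the identity between the
compositional (geometric) mean and the inverse ILR of the arithmetic
ILR mean. The row normalizing constants √(rs/(r+s)) make V orthonormal.

Latent activity profiles are a K-component Gaussian mixture on the ILR
vectors: z_i ~ Categorical(π), y_i | z_i = k ~ N(μ_k, Σ_k) with
Σ_k diagonal. Two variance structures are supported: one diagonal
covariance shared by all classes (`"equal"`, the default — the simplest
common latent-profile model) and one per class (`"free"`).

## Actigraphy scoring rules

- Awake intensity bands (counts/min): SB ≤ 178.50, MVPA ≥ 562.50, LPA
  between — a total monotone partition of [0, ∞), so epochs that fall in
  the printed gap (178.50, 178.51) resolve to LPA.
- Nightly rest intervals come from paired event-marker presses when the
  gap is a plausible night (3–14 h); otherwise the longest noon-to-noon
  block with lux < 10 and 15-min rolling-median counts below the
  sleep/wake threshold (≥ 3 h). Only the major nightly period counts as
  sleep; secondary rest is treated as napping, which scores as SB.
- Sleep inside the interval: epochs strictly below 20 counts/min.
  Epochs at/above 20 are wake-after-sleep-onset; they are excluded from
  sleep and credited to the awake budget through the intensity bands
  (nearly always SB). This keeps each day's four parts summing exactly
  to its window length, which the source rules leave unspecified.
- Days are half-open bedtime-to-bedtime windows [bed_n, bed_{n+1});
  durations are typically not 1440 min. The recording before the first
  bedtime is dropped. Epoch gaps ≤ 2 min are back-filled as SB; longer
  gaps invalidate the day.
- Participants need ≥ 5 calendar-consecutive valid days (the longest
  run is averaged); otherwise they are excluded with a logged reason.

## Winsorization

Values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are replaced by the 5th /
95th percentile of the original vector, in a single pass, per variable
across participants — first the %/day behaviors (re-closed afterwards so
compositions stay valid), then the ILR coordinates, then cognition.
Quantiles use linear interpolation between order statistics (numpy
default, "type 7").

## Estimation and model selection

EM with a k-means start plus random restarts (default 8); the
log-likelihood is nondecreasing per iteration and convergence is a
relative change < 1e-7 (a looser 1e-5 inside the BLRT, applied
identically to observed and bootstrap fits, since only the LR difference
matters there). Variances are floored at 1e-6 of each coordinate's total
variance; a restart whose class empties is discarded. K = 1 uses the
closed-form MLE. Parameter counts: equal-diagonal 3K + 3 + (K−1);
free-diagonal 6K + (K−1).

Fit statistics: AIC = −2ℓ + 2p; BIC = −2ℓ + p ln n; normalized entropy
1 − Σ −p_ik ln p_ik / (n ln K) (1 for K = 1); smallest modal class. The
BLRT simulates B parametric-bootstrap datasets from the fitted (K−1)
model and reports p = (1 + #{LR_b ≥ LR_obs})/(B + 1); note the smallest
attainable p is 1/(B+1), so B must exceed 1/α − 1 for rejection to be
possible. Selection scans K (default 1–6): eligible K need every modal
class ≥ 25 members (a > 1 %-of-n arm is available by configuration) and,
for K ≥ 2, BLRT p < .05; the lowest BIC among eligible wins, ties to
smaller K. If nothing is eligible the best-BIC fit is returned flagged.
Label switching in recovery checks is handled by Hungarian matching;
ARI is permutation-invariant.

## Inference

One-way ANOVA is computed from group sums of squares and is therefore
identical whether given raw vectors or printed n/mean/SD summaries.
χ² is Pearson's without continuity correction. The cognition ANCOVA is
OLS of outcome on profile + covariates (age, sex, BMI, MoCA, RCT cohort;
a sensitivity switch replaces MoCA with education years), no
interactions (homogeneity of slopes assumed); the profile factor is
tested marginally (extra sum of squares after covariates — Type III in
the no-interaction case). EMMs are mean model predictions with the
factor set to each level and covariates kept at their observed values
(continuous at means, categoricals at observed proportions), with SEs
from the coefficient covariance. Pairwise contrasts are unadjusted by
default, matching an exploratory protocol; standard corrections are
available behind a flag. Pairwise contrasts from the full model use the
pooled residual variance, so they differ slightly from two-group subset
refits (the tests compare them at a loose tolerance).

## Synthetic data: what it emulates, and what it does not

The generator draws, per participant: a latent profile from the
published mixing weights (103/70/54/26 at n = 253); a composition from a
logistic-normal around the profile's published %/day mean (noise is
diagonal Gaussian in ILR space, mapped back by the inverse ILR — every
draw is strictly positive and closed); a day duration
Normal(1343.53, 44.11) truncated to [1100, 1550] min; cognition
Normal(−0.31 + δ_k, 0.62) with all δ_k = 0 by default (the null the
study observed); and demographics from the published cohort marginals.
One root seed spawns a deterministic substream per participant, so any
subset reproduces bit-identically.

Percentage-scale SD targets cannot be inverted exactly to a diagonal
ILR covariance (4 targets, 3 parameters), so a calibration loop
linearizes the inverse-ILR map at the profile mean, solves nonnegative
least squares for the ILR variances, and refines against simulated
%-SDs. The published means are closed to exactly 100 (printed rounding
leaves sums of 100.01). Achieved %-SDs land within roughly 10–40 % of
the targets depending on the part — the diagonal structure is a
deliberate simplification and the residual mismatch is irreducible
within it.

Two consequences matter for interpreting the recovery experiments.
First, with noise at the printed SDs the mixture components overlap
substantially: the Bayes-optimal classifier (using the true generating
parameters) reaches only median ARI ≈ 0.67 against the true labels at
n = 253, so no fitted model can approach perfect recovery — the
smallest-class-size experiment (mean smallest modal class ≈ 26–28
across seeds) is the meaningful recovery check at these conditions.
Second, BIC resolves three versus four profiles only about half the
time seed-to-seed, and the ≥ 25 class-size rule is knife-edge by
construction (the smallest true class has expected size 26, so its
modal count falls below 25 in roughly a third of seeds). Passing or
failing a single selection run therefore says little; the suite checks
the modal selected K across five seeds, and its outcome should be read
alongside these bounds. Real cohorts whose latent classes are separated
more cleanly than the printed within-class SDs suggest would recover
more sharply.

The epoch-series generator places counts inside the cutpoint bands
(sleep U[0,15), SB U[30,170], LPA U[200,540], MVPA U[600,1500]
counts/min), with low lux and marker presses framing each night, so the
scoring chain recovers day targets minute-for-minute. It does not
emulate raw tri-axial accelerations, device noise, naps (unless WASO
minutes are requested), irregular bedtimes, or non-wear.

## Numerical and design notes

- Epochs are minute-based by default; sub-minute epochs must divide
  60 s evenly and counts are always expressed per minute.
- `ilr_inverse` subtracts the row max before exponentiating; closure and
  transforms are vectorized over rows.
- Zero or negative composition parts are a hard error everywhere; the
  generator cannot emit them, and no zero-replacement strategy is
  provided (out of scope).
- MMSE "> 20/30" is implemented as ≥ 21 on integer scores; the MoCA
  education adjustment (+1 for ≤ 12 years, capped at 30) is available
  but off by default since generated MoCA scores are already adjusted.
- Internal κ is 1440 min; reporting converts to %/day (÷ 14.4).
- Simulation sizes in the test suite (e.g. 100-seed class-size runs,
  200-replicate calibration checks at n = 100, B = 99) were chosen to
  keep Monte-Carlo error comfortably inside the asserted tolerances on
  a single CPU.

## Known limitations

- The proprietary rest-interval algorithm of the source device is not
  reimplemented; the marker/heuristic scheme here follows only the
  publicly stated rules.
- No compositional regression of cognition on ILR coordinates,
  isotemporal substitution, covariance-structured mixtures, or
  longitudinal models.
- The within-profile covariance of real cohorts is unidentifiable from
  printed per-behavior SDs; all recovery results are conditional on the
  diagonal logistic-normal emulation described above.
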