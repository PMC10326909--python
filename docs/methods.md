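# Methods

This note documents the models and procedures `sfcquant` implements, the
defaults it ships with, and the choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Response factors from calibration graphs

The response factor of an analyte is the slope (in M⁻¹, with intercept) of
the least-squares line of isotope-corrected signal versus molar
concentration over the linear range. Peak integration is assumed to cover
only the monoisotopic peak, so raw areas are divided by the monoisotopic
fraction of the molecular formula — the probability that every atom is its
lightest isotope, `∏ aᵉˡ^count` with representative IUPAC 2021 abundances
for C, H, N, O, S, P, F, Cl, Br, I. For analytes below ~1000 Da the
monoisotopic peak is the most abundant isotopologue, so this is the
appropriate correction for "main peak only" integration; the unit suite
checks it against a full isotopologue-convolution oracle to 1e-9.

**Linear-range detection.** Manual residual inspection is replaced by a
deterministic rule. Levels whose replicate RSD exceeds 0.3 (the
reproducibility bound used for peak areas) are excluded first. Then the
per-level response ratios `mean corrected area / concentration` are compared
with their median: while the worst relative deviation exceeds 0.2 and more
than three levels remain, the worst level is dropped (highest concentration
preferred on ties) and the median recomputed. A chemical ends with fewer
than three acceptable levels — or three levels that still violate the
tolerance — is flagged "no linear range" and excluded downstream.

*Why ratios rather than residuals of the fitted line:* relative residuals of
an ordinary least-squares calibration line are dominated by the intercept at
the low end of a geometrically spaced concentration series, so any greedy
pruning driven by them discards the low levels and converges onto a
saturated plateau (which is perfectly "linear"). The response ratio is the
quantity that is actually constant in the linear range, weighs all levels
equally, and detects the hard saturation plateau exactly; the rule is also
idempotent. The RF itself is still the OLS slope **with** intercept over the
retained replicate points, so baseline offsets are absorbed rather than
folded into the slope.

## Eluent descriptors

The SFC gradient (default: 2 %B hold for 1 min, ramp to 60 %B within 6 min,
4 min hold, reset within 0.1 min; 1.5 mL/min column flow) is interpolated
piecewise-linearly. At the ESI inlet the column flow (CO₂ + methanol split
by %B) mixes volumetrically with the 200 µL/min water/isopropanol 90/10
makeup flow. By default descriptors are computed on the condensed (CO₂-free,
renormalized) liquid, since CO₂ decompresses before ionization; pass
`include_co2=True` to keep it.

Mixture properties use deliberately simple rules isolated behind a single
function so they can be swapped: volume-fraction-weighted Snyder polarity
index and surface tension, log-linear viscosity mixing
`η = exp(Σ φᵢ ln ηᵢ)`, pure-component constants at 25 °C (water 10.2 /
0.890 mPa·s / 71.99 mN/m; methanol 5.1 / 0.544 / 22.07; isopropanol 3.9 /
2.038 / 20.93). These quantities enter the model only as features, so their
exact functional form is a modeling choice, not a physical claim. pH is
recorded as the aqueous-phase pH (default 7.0 for 20 mmol/L ammonium
acetate) and NH₄⁺ presence is inferred from the additive name.

## Descriptor filters

Two caret-style filters: (1) near-zero-variance — a descriptor is removed
when constant or when its most frequent value is ≥ 19× (95/5) as common as
the second most frequent; (2) pairwise correlation — while any kept pair has
|Pearson r| > 0.75, the most correlated pair is found and the member with
the larger mean absolute correlation against the currently kept set is
removed, recomputing after each removal (ties keep the earlier column).
Greedy removal is used rather than exact minimal removal — exactness is
combinatorial at realistic descriptor counts — but the suite verifies the
greedy result coincides with exhaustive search on small instances, and that
no retained pair exceeds the cutoff. Spearman profiling uses tie-corrected
rank correlation.

## The guided regularized random forest

The model regresses log₁₀ RF (all logs base 10 throughout) on the filtered
descriptors with bootstrap-aggregated regression trees and
variance-reduction split gain. The regularization follows the guided-RRF
scheme: for a candidate feature *j* not yet used anywhere in the
sequentially grown ensemble, the gain is multiplied by

    λⱼ = (1 − coefImp) · coefReg + coefImp · impⱼ′,

where impⱼ′ is the gain importance of *j* in a preliminary unregularized
forest, normalized to maximum 1. Features already used compete unpenalized.
With `coefReg = 1, coefImp = 0` every λⱼ = 1 and the model is an ordinary
random forest. Defaults: 500 trees, `min_node = 5` (nodes at or below this
size become leaves), `mtry` capped at the number of surviving descriptors;
the tuning grid includes the reference optimum (mtry 86, coefReg 1.0,
coefImp 0.5). Tests and the acceptance script use 150 trees — ensemble error
is essentially flat beyond ~100 trees at these problem sizes.

Split near-ties are common because bootstrap duplication lets several
features induce the identical partition of a small node; ties (within 1e-9
relative gain) are broken toward the smallest threshold value, an intrinsic
key that keeps predictions independent of descriptor column order.

Final-model importances are out-of-bag permutation importances (mean MSE
increase, permuting only features actually used per tree).

**Cross-validation** is rank-stratified: chemicals are sorted by the target,
and within each consecutive block of *k* ranks the fold labels are a seeded
permutation of 1..k, so folds are balanced to ±1 in size and each spans the
whole response distribution. Out-of-fold predictions come from the model not
trained on the chemical's fold. Hyperparameter tuning scores each grid point
by mean validation RMSE over 2-fold CV repeated twice ("two-by-two"),
with the same folds and training seeds for every grid point.

## Transfer and error factors

Relative log₁₀ IE predictions are mapped to instrument RFs by
`log₁₀ RF = slope · log₁₀ IE + intercept`, fitted by iteratively reweighted
least squares with Huber weights (tuning constant 1.345, scale = normalized
MAD of the residuals, ≤ 50 iterations, relative tolerance 1e-8) — the
behavior of the classic M-estimator default, cross-checked against
statsmodels' RLM in the suite. The regression direction is RF on IE (it
predicts the instrument quantity). With zero iterations the fit is exactly
OLS, which the outlier tests use as the non-robust reference.

Concentration is the calibration-model inverse `c = corrected area / RF`,
and accuracy is the symmetric fold error
`EF = max(c_pred/c_spiked, c_spiked/c_pred)`; `log₁₀ EF = |Δlog₁₀ c|`, so
over- and underestimation are treated equally and EFs are comparable across
concentration levels. Summaries report the median and mean EF over all
(chemical, level) predictions and the fraction of chemicals with EF < 10 at
*every* level. For multiplicative lognormal errors with σ log-units the
median EF follows the half-normal quantile law `10^(0.6745 σ)`, which the
acceptance suite verifies by simulation.

## Monte Carlo calibrant selection

For each calibrant count k (default 5–20) and each of 200 repetitions, k
chemicals are drawn without replacement, the transfer line is refitted on
them, and all remaining chemicals are quantified at their linear-range
levels. Each sample records the test-set median EF and the calibrants'
retention-time and predicted-IE ranges. Aggregation reports, per k, the mean
and SD of the median EF plus the SD of log₁₀(median EF) ("log-units"), and
the mean median EF over quartile bins of RT range and IE range (bin edges
are data quantiles; the reference study does not state its binning).
Repetitions are per k. Sub-seeds are derived deterministically from
(seed, k, repetition).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
defaults mirroring the study conditions: 127 chemicals; 8 calibration levels
geometrically spaced 12.2→1750 nmol/L in triplicate; true log₁₀ RF spanning
the anchor range 4.06×10¹⁴–2.70×10¹⁸ M⁻¹ (instrument slope 1.3182 and
intercept 12.8948 map the target IE span 1.30–4.20 exactly onto it);
multiplicative instrument noise σ = 0.15 log-units; relative area noise
σ = 0.10 (the replicate-agreement bound of 30 % is treated as a ~3σ upper
bound); saturation above the 75 % level quantile as a hard plateau (the
simplest mechanism that makes linear-range detection nontrivial); retention
times mapped through ranks into the gradient window with a target Spearman
correlation of −0.28 against log RF; random C/H/N/O formulas whose
monoisotopic fraction attenuates the simulated raw areas (so isotope
correction is exercised end to end).

Descriptors follow a correlated factor model — each noise descriptor loads
(0.6–0.95) on one of ~10 latent factors, giving the collinear blocks the
correlation filter exists for. The informative descriptors are mutually
independent columns *outside* those blocks with effect magnitudes
`U(0.8, 1.2) · beta_scale`: they represent distinct chemical property axes,
each carrying its own marginal association with log IE. (Embedding them in
shared factors lets marginal correlations cancel, which would make single-
descriptor profiling meaningless — real descriptor sets contain families
that individually track ionization efficiency.) True log IE is the sparse
linear combination affinely rescaled to the target span.

**What passing on synthetic data does and does not show.** The generator
reproduces dynamic range, collinearity, sparsity, saturation and noise
structure, so it validates the machinery: isotope correction, range
detection, filtering, CV hygiene, transfer algebra, EF statistics and the
Monte Carlo design. It does not reproduce real descriptor semantics,
nonlinear descriptor–IE relationships, matrix effects, adduct chemistry or
detector nonlinearity beyond a hard plateau — so performance numbers on
synthetic data characterize the pipeline under its stated assumptions, not
expected accuracy on any particular instrument.

## Numerical choices and degenerate inputs

- Seeds: every stochastic stage takes an explicit seed; sub-seeds are
  spawned deterministically (SeedSequence or affine derivation, kept below
  2³¹). Identical config + seed reproduces every artifact byte-for-byte.
- Degenerate designs raise: identical predicted IE for all calibrants
  (transfer), mtry exceeding the descriptor count, non-increasing
  concentration levels, a degenerate IE target span, unknown elements or
  eluent components.
- Non-positive calibration slopes and missing linear ranges are flagged per
  chemical and excluded, never silently imputed.
- The pipeline validates table schemas on read and reports file, row and
  column for the first offending cell.

## Problem sizes

Tests and the acceptance script run the full workflow at the default study
scale (127 chemicals, 200 descriptors, 10-fold CV, 16 × 200 Monte Carlo
samples) with 150-tree ensembles; the complete suite and the acceptance
script each finish in a few minutes on a single CPU.

## Known limitations

- The eluent property rules are first-order mixing laws; no CO₂ expansion
  thermodynamics or pressure corrections.
- The RRF penalty is the guided formulation above; other regularized-forest
  variants differ in detail.
- "Two-by-two repeated cross-validation" is interpreted as 2-fold CV × 2
  repeats.
- Adducts are not modeled (positive-mode protonated species assumed), and
  the isotope correction assumes the integrated main peak is the
  monoisotopic peak (safe below ~1000 Da).
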