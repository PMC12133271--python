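# Methods

## The scientific question

Auxiliary variables — variables in the imputation model but not the analysis
model — are routinely added to multiple-imputation (MI) models to reduce
bias and recover precision.  In practice the auxiliaries themselves are
often incomplete.  This package implements a Monte Carlo laboratory for the
question: *how does missing data in an auxiliary variable, under different
missingness mechanisms and proportions, affect the bias and the fraction of
missing information (FMI) of an MI analysis?*

## Data-generating process

Each replicate draws n rows of (Y, X, Z) from a trivariate normal with
means (6, −3, 2) and unit variances; corr(X,Y) = 0.6 (so the true slope of
the analysis regression of Y on X is 0.6), corr(X,Z) = 0, and corr(Y,Z)
varied over {0.1, 0.3, 0.5, 0.7}.  A fully observed proxy for the
auxiliary is constructed as

    W = (0.6 (Z − E[Z]) + e) / sqrt(0.6² + 1),   e ~ N(0, 1),

standardized by its population moments so that E[W] = 0, Var[W] = 1 and
corr(W, Z) = 0.6/√1.36 ≈ 0.514 exactly.  (Sample-moment standardization,
differing by O(n^−1/2), is available via `w_standardize="sample"`.)

### Missingness amputation

Missingness is deterministic given the latent data (an exact CDF cutoff,
not a probit/logit draw).  Writing F for the standard-normal CDF of a
variable standardized by its known population mean and unit SD:

* **Outcome** (proportion `pi_y`, default 0.5):
  mechanism 1 removes Y where **both** F(X) < √pi_y and F(Z) < √pi_y —
  because X ⊥ Z the two marginal conditions multiply, giving overall
  proportion pi_y (the conjunction reading; a bivariate joint-CDF reading
  would not generalize across pi_y).  Mechanism 2 removes Y where
  F(Y) < pi_y (MNAR outcome); mechanism 3 where F(X) < pi_y (exposure-driven,
  so complete records analysis is unbiased).
* **Auxiliary** (proportion `pi_z`, grid 0–0.9):
  mechanism 1 is an independent uniform draw < pi_z (MCAR); mechanism 2
  removes Z where F(Z) < pi_z (MNAR); mechanism 3 where F(W) < pi_z (MAR
  given the proxy).

`cdf_mode="empirical"` replaces F by fractional ranks (rank − 0.5)/n,
which pins exact missing counts (⌊pi·n⌋ ± 1) and is what the exact-count
tests use; the default `"population"` mode is the deterministic threshold
on latent values and converges to the nominal proportion as n grows.  Both
indicators are computed from the complete data, so outcome and auxiliary
missingness commute.

## Imputation engine

Chained equations (fully conditional specification) with normal linear
imputation models throughout.  One draw for a target with k design columns
and n_obs observed rows:

1. OLS fit on the observed rows: β̂, RSS, df = n_obs − k;
2. σ*² = RSS / g with g ~ χ²(df) (scaled inverse chi-square posterior draw);
3. β* ~ N(β̂, σ*² (XᵀX)⁻¹), drawn via the Cholesky factor of the Gram matrix;
4. imputed values = X_mis β* + N(0, σ*²) noise.

This is the classical "proper" normal-linear method (the *regress*/*norm*
family); predictive mean matching is deliberately not implemented because
the study design calls for linear-regression imputation of continuous
variables.  Design choices where the convention was open:

* **Initialization**: missing cells start as draws with replacement from
  the variable's observed values — a common chained-equations default.
* **Chains**: each of the m imputations is an independent chain (own
  substream, own initialization) run for `burnin` cycles (default 10), not
  thinned states of one chain.
* **Visit order**: incomplete variables in model-spec order, default
  (Y, then Z); configurable, and with these linear models order effects are
  within Monte Carlo noise.
* **Passive terms**: powered/product terms (`z^3`, `z^3:edu`) are rebuilt
  from current values at every cycle, so transformed-scale models stay
  coherent with the latest imputations.
* **Rank deficiency is an error**, never silent column dropping — dropping
  would change the conditional model without notice.

With a single incomplete variable the sampler has no cross-dependence, so
burn-in beyond the first cycle leaves the imputation distribution unchanged
and the engine reduces to Bayesian regression imputation; the bivariate
conditional-normal oracle test exploits this.

## Estimators and pooling

The analysis model is the unadjusted OLS regression of Y on X (simple
closed-form fit; statsmodels is used in the tests as an independent
cross-check, not in the engine).  Three estimators per replicate:

* **CRA** — OLS on rows with Y observed.  Z is not in the analysis model,
  so auxiliary missingness never changes the CRA sample.
* **MI excluding the auxiliary** — Y imputed from p(Y|X) only; Z is
  neither imputed nor used (imputing it would only add noise).
* **MI including the auxiliary** — Y from p(Y|X,Z); Z from p(Z|Y,X), or
  p(Z|Y,X,W) under auxiliary mechanism 3 when the proxy is in the model
  (the `include_w` switch covers the sensitivity analysis that omits it).

Rubin's rules: Q̄ = mean of per-imputation slopes, B their m−1-divisor
variance, Ū the mean squared SE, T = Ū + (1 + 1/m)B, r = (1 + 1/m)B/Ū,
ν = (m − 1)(1 + 1/r)², λ = (1 + 1/m)B/T, and the df-adjusted

    FMI = (r + 2/(ν + 3)) / (r + 1),

the variant common MI software reports; λ (its large-m limit) is exposed
alongside because published FMIs do not always say which was printed.
Classical large-sample ν is used throughout; Barnard–Rubin small-sample df
and multi-parameter pooling are out of scope.  Intervals use a t reference
on ν df.  B at or below float noise (identical estimates) collapses to
exactly 0 so that complete data give FMI = 0 rather than ~1e−30.

## Study orchestration and metrics

A grid cell is one combination of (outcome mechanism, auxiliary mechanism,
corr(Y,Z), pi_z) plus sensitivity axes (pi_y, corr(X,Y), include_w).  Seeds
derive from (root seed, cell index, replicate index) via numpy
`SeedSequence`, so any cell or replicate is reproducible in isolation and
parallel execution (joblib) is bit-identical to serial.  Failed replicates
(e.g. singular designs) are recorded with identifiers and excluded from
metrics with their count reported — never silently retried, which would
bias Monte Carlo error.

Metrics per (cell, model): bias = mean(est) − 0.6 with MCSE = empSE/√n_sim;
empirical SE with MCSE = empSE/√(2(n_sim − 1)); mean model SE; mean FMI;
and bias relative to CRA, 100·bias/bias_CRA.  The relative measure is
flagged whenever |bias_CRA| < 2·MCSE(bias_CRA): dividing by a bias that is
itself Monte Carlo noise (the unbiased-CRA mechanism prints a CRA bias of
a few thousandths) produces unstable percentages, and the plots then fall
back to absolute bias.  "MI bias reaches CRA bias" is judged by overlap of
the two bias estimates' Monte Carlo error bars
(|bias_MI − bias_CRA| ≤ 2√(MCSE_MI² + MCSE_CRA²)); the paired-difference
MCSE is much smaller (the estimators share replicates, correlation ≈ 0.98)
and would label even scientifically negligible differences distinguishable.

## Problem sizes

Full scale is 1000 replicates of n = 1000 with m = 100 imputations per
scenario.  The package's own test and acceptance runs use the scaled-down
sizes m = 20, burn-in 10, and 300–1000 replicates depending on the check;
Monte Carlo SEs are carried everywhere so the reduced precision is explicit
(e.g. bias MCSE ≈ 0.003 at 400 replicates versus ≈ 0.002 at 1000).  The
desk-scale grid driver (`analysis/03_run_study_grid.py`) runs 72 of the 360
base-grid cells at n_sim = 150.

## What the generator does and does not emulate

The synthetic data are exactly the study conditions: multivariate normal,
a single auxiliary, deterministic single-cause missingness per variable,
50% missing outcome.  Real cohort data differ in ways the tests therefore
cannot speak to: stochastic and multi-cause missingness, non-normal and
discrete variables, nonlinear outcome–auxiliary relationships (the term
machinery supports them, but the simulation never exercises them),
incomplete exposures or confounders, and several simultaneously incomplete
auxiliaries.  Passing tests demonstrate correctness of the machinery and
reproduction of the qualitative and quantitative pattern *under these
conditions*, not robustness beyond them.

## Known limitations

* Continuous, normal imputation models only — no logistic/polytomous
  imputation, no predictive mean matching, no MNAR delta adjustment.
* Convergence monitoring is limited to what the burn-in default provides;
  no trace diagnostics are computed in the grid runs.
* The FMI estimate is noisy at m = 20 (the reason the full-scale design
  uses m = 100); mean FMI across replicates is reported to average this
  noise out.
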