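# Methods

## Model and estimation

All fits operate on log₁₀-transformed mass and metabolic rate; printed
intercept magnitudes only make sense in base 10, and the package uses
base 10 everywhere. An `AllometricModel` fit returns the intercept
`log10(a)`, the exponent `b`, classical OLS/WLS standard errors with
n − 2 residual degrees of freedom, R², the mean of log₁₀ mass, and the
predictor sum of squares `ssx = Σ(x − x̄)²`. The standard error of the
back-transformed coefficient `a = 10^log10(a)` uses the delta method,
`SE(a) = a · ln(10) · SE(log10 a)`. Deviations of `b` from theoretical
exponents (3/4, 2/3) are two-sided Student t tests on n − 2 df.

### Common slope and size-independent levels

Three common-slope estimators are provided and selectable everywhere a
common slope is consumed:

* the ANCOVA (indicator-variable) estimate from the model with one slope
  and clade-specific intercepts — the pipeline default, since it is the
  maximum-likelihood common slope under the shared-residual model;
* weighted averages of per-clade OLS slopes, weighted by sample size or
  by `ssx` (the latter is inverse-variance weighting when residual
  variance is shared).

At a fixed slope `b₀` the least-squares intercept is
`log10(a) = ȳ − b₀·x̄`; its R² is computed against the fixed-slope line
and can sit below the free fit's. The dimensionless BMR ratio divides
each clade's `a_common` by the reference clade's (largest) value, making
the reference ratio exactly 1. The scaling elevation is
`L = log10(a) + (b − 1)·x_mid`. The "pivotal midpoint" `x_mid` has no
standard definition; the package defaults to the clade's mean log₁₀
mass and offers the midpoint of the clade's log₁₀ mass span as an
alternative (`x_mid_mode="range"`). Neither convention reproduces the
historically printed per-clade L values from their printed `a` and `b`,
so L is treated as an internally consistent metric, not a number to
match externally.

### Nested ANCOVA and model selection

The three models — single line; common slope with per-clade intercepts;
per-clade slopes and intercepts — are fitted by OLS on indicator-coded
design matrices (baseline = first clade in the configured order;
reported intercepts are back-transformed per clade so the coding is
invisible). AIC = 2k − 2lnL̂ and BIC = k·ln n − 2lnL̂ use the Gaussian
likelihood at the ML variance RSS/n with k counting regression
coefficients plus one for σ², matching R's `AIC` for linear models; the
contract is the *ordering* of models, not the absolute values, which
shift under other likelihood conventions. Slope homogeneity is the
F test `F = [(RSS₂ − RSS₃)/(df₂ − df₃)] / [RSS₃/df₃]`. The two-group
comparison reports the interaction-model t for the slope difference and
the common-slope-model t for the intercept difference, each on its own
model's n − k degrees of freedom.

### PGLS and Pagel's λ

The tip covariance `C[i,j]` is the branch length shared from the root to
the most recent common ancestor of tips i and j (diagonal = tip depth),
assembled in one postorder pass. Pagel's transform multiplies the
off-diagonal by λ ∈ [0,1]; values outside the unit interval are
rejected. GLS estimates are computed by Cholesky whitening, and λ is
estimated by maximising the profile log-likelihood

```
ℓ(λ) = −(n/2)·ln(2π σ̂²) − ½·ln|C_λ| − n/2,   σ̂² = RSS_V / n  (ML, not REML)
```

with bounded scalar optimisation (tolerance 1e-6) plus explicit
evaluation of both boundaries, since the optimum frequently sits at
λ = 0 or 1 and boundary estimates are legitimate results, not errors.
Clades with fewer than four tips cannot support profiling; the pipeline
reports λ = 0 for them. The PGLS "R²" is `1 − RSS_V/TSS_V` on
V-whitened data against the V-weighted mean — an approximation of the
convention in comparative-methods R packages, which do not document
theirs precisely; exact reproduction of published PGLS R² cells is not
claimed. Coefficients and λ̂ are invariant to rescaling all branch
lengths (σ² absorbs the scale; verified by test). Within-clade PGLS uses
that clade's subtree only; cross-clade group-level regressions are
OLS/WLS on one observation per clade.

## Synthetic data generator

The generator defines the study conditions: six clades at the published
sample sizes (3, 84, 730, 9, 404, 587), log₁₀ body-mass distributions
Normal at the midpoint of each clade's published span with SD a quarter
of the span, residual SD 0.146 log₁₀ units, and per-clade phylogenetic
signal at the published λ values. Two clade-level values were not
published and are package choices, fixed once: the Passeriformes mass
span (5–1400 g, a typical passerine range) and its λ (0.664, the
all-Aves estimate); the Passeriformes free-fit intercept is back-derived
from its common-slope intercept at the middle of that span.

Trees are pure-birth (Yule): lineages split at unit rate, the process
runs one extra exponential waiting time after the n-th tip appears (so
every terminal branch is positive and `C` is positive-definite at
λ = 1), and all depths are rescaled to 1. Traits follow
`log10(BMR) = log10(a) + b·log10(m) + ε` with
`ε = √λ·(BM on the tree) + √(1−λ)·N(0, σ)`, both components scaled so
the marginal SD is σ. On a unit-depth ultrametric tree this gives tip
covariance `σ²[λ·C_offdiag + diag]` — exactly the λ-transform the PGLS
module assumes, which makes λ-recovery tests well-posed. All randomness
derives from one integer seed via `numpy.random.SeedSequence.spawn`,
two child streams per clade (tree, traits), so per-clade output is
order-independent and reproducible.

What the generator does **not** emulate: empirical log-mass
distributions are not Normal (real compilations are right-skewed and
truncated); BMR curvature (concave-up in large eutherians) is absent, so
mass-threshold re-fits change slope only if curvature is injected
explicitly; FMR is generated as a fixed multiple of BMR rather than with
its own residual structure; and the backbone divergence structure
between clades is a configuration constant, not simulated. Passing
recovery tests therefore demonstrates estimator correctness under the
stated model, not robustness to these real-data features.

## Numerical and design choices

* Mass thresholds are inclusive (`≤`), matching "10 kg or less".
* Weighted (WLS) fits reject non-positive weights rather than dropping
  points silently.
* `refit_intercept_fixed_slope` accepts a single observation (no slope
  is estimated); R² is then undefined and reported as NaN.
* Degenerate designs (constant predictor) raise immediately with a
  named error; singular phylogenetic covariances raise with the
  condition number attached.
* The ANCOVA baseline clade is the first configured label; all reported
  quantities are coding-invariant (tested).
* Group-level trend regressions are unweighted by default, with
  WLS-by-n selectable, because each clade is one observation whose
  "precision" is debatable.
* The slope-vs-level trends exclude clades with n < 5 in the pipeline
  (a slope estimated from three species over a 0.9-decade mass span is
  noise); the exclusion set is logged, and callers of `slope_vs_level`
  control it directly.
* Report tables are written at full precision with rounded companions
  (3 decimals; 2 for α), so tests compare machine numbers while readers
  see conventional roundings.

## Problem sizes used in the checks

Simulation-based tests run at the published clade sizes (1817 species
total) for intercept/slope recovery (50 replicates), n = 200 tips for
λ recovery (50 replicates per boundary), 200 replicates for the
homogeneity test's type-I error, and 100 replicates for power and
null-coverage checks of the two-group comparison. Mean-bias bounds on
the OLS exponent are asserted for clades with n ≥ 50: for the smallest
clades the slope's sampling SD (~0.2) makes a 0.005 mean-bias bound
unverifiable at any feasible replicate count.

## Known limitations

* λ̂ is constrained to [0,1]; models with λ > 1 or alternative
  correlation structures (Ornstein–Uhlenbeck) are out of scope.
* PGLS R² follows the package's own stated convention (above);
  published PGLS R² values may differ.
* FMR analyses take group-level FMR intercepts (at their own common
  slope, 0.6851) as inputs; the underlying field-metabolism literature
  compilation is not reconstructed, and matched-species BMR/FMR ratios
  are out of scope.
* Quadratic/curvilinear scaling models are deliberately not implemented.
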