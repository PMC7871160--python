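# Methods

## Model

Smoker counts on an age-group x survey-year lattice are modelled per
stratum (gender x area) as

    y_ij ~ Binomial(n_ij, p_ij),        logit(p_ij) = eta_ij,
    eta_ij = delta + alpha_i + beta_j + gamma_k(i,j) + z_ij,

with age effects `alpha` (I = 12 five-year groups, 20-24 … 75-79), period
effects `beta` (J = 6 survey years, 2004 … 2019 every 3 years), birth-cohort
effects `gamma` on a 1-year grid, and a cell-level heterogeneity term
`z_ij` absorbing extra-binomial variation.  Because age groups are 5 years
wide and surveys 3 years apart while cohorts shift by 1 year, the cohort
index is

    k(i, j) = 5 (I - i) + 3 (j - 1) + 1,    K = 5 (I - 1) + 3 (J - 1) + 1 = 71,

so consecutive cohorts overlap (each spans five birth years) and 8 of the
71 indices fall between cells.  Those gaps are retained in the parameter
vector and estimated purely through the smoothing prior.

Identification: each effect vector is constrained to sum to zero, pushing
the overall level into the intercept `delta`.  First-order random-walk
(RW1) priors smooth each effect:
`effect_{t+1} - effect_t ~ Normal(0, sigma_effect^2)`, the cohort walk
running over all 71 indices (which interpolates the unobserved ones).
`z_ij ~ Normal(0, sigma_z^2)` iid.  The four standard submodels keep age
and toggle period/cohort: `a`, `ap`, `ac`, `apc`; the heterogeneity term
is present in all four.

Hyperpriors (a design choice; sensitivity is the user's responsibility):
half-Normal(0, 1) on every sigma (log-odds scale) and Normal(0, 10^2) on
`delta`.  All scales are exposed in `APCModelSpec`.

The classical APC aliasing is *not* resolved beyond sum-to-zero plus RW1
shrinkage: with this lattice a linear cohort trend is an exactly linear
function of the age and period indices, so the linear components of
`alpha`, `beta`, `gamma` trade off against each other and only the prior
determines their split.  Fitted cell probabilities, deviance-based
quantities (DIC) and second differences of effects are fully identified;
individual effect levels are identified only up to this softly-penalized
trend, and their posteriors are correspondingly wide.

## Posterior computation

The sampler is written in the package (numpy): Hamiltonian Monte Carlo
with analytic gradients plus exact Gibbs sweeps, with convergence
assessed by rank-normalized split R-hat (arviz).  Plain HMC fails on this
posterior for two reasons — the likelihood-flat aliasing ridge and the
funnel coupling between each effect and its scale — so the kernel
composes four ideas:

1. **Sum-to-zero basis.**  Effects are sampled in an orthonormal basis of
   the sum-to-zero subspace; the RW1 prior restricted to that subspace is
   a proper Gaussian (its only flat direction, the constant vector, is
   excluded).  Every reported draw satisfies the constraints exactly.
2. **Centered / non-centered by information.**  Each block (age, period,
   cohort, heterogeneity) is sampled on its natural scale (centered) when
   the likelihood carries more precision per coordinate than its prior at
   the posterior mode, and as a unit-scale raw vector times
   `exp(log sigma)` (non-centered) otherwise; the choice is made per fit
   from a deterministic pilot mode search, so the same data always get
   the same parameterization.
3. **Dense Laplace metric.**  The HMC mass matrix is the Gauss-Newton
   Hessian (binomial Fisher weights plus prior precision) at the
   posterior mode, found by L-BFGS from an empirical-logit start; it is
   re-evaluated once mid-warmup at the chain's current position.  Step
   size is tuned by dual averaging (target acceptance 0.8); trajectory
   length 1.5 time units, at most 64 leapfrog steps, with 10% step
   jitter.
4. **Exact Gibbs sweeps.**  Before every HMC step: (a) a *collapsed* draw
   along the exactly-aliased linear-trend direction — the likelihood is
   perfectly flat there, the centered blocks' scales are integrated out
   analytically (the scale integral is a generalized-inverse-Gaussian
   normalizer, a Bessel-K closed form), and the 1-D density is sampled by
   slice sampling; (b) each scale is redrawn from its closed-form
   conditional given the natural-scale vector it governs — for
   non-centered blocks this is an interweaving (ASIS) move that rescales
   the raw coordinates so the natural vector is unchanged.

Chains start from overdispersed draws of the Laplace approximation.
Defaults: 4 chains, 2,000 kept iterations each, warmup equal to kept
iterations; divergent trajectories after warmup are counted and reported,
never dropped silently.  On full-scenario synthetic data (12 x 6 lattice,
n = 10,000 per cell) the worst split R-hat over all 166 scalar parameters
is about 1.09 at 4 x 1,500 draws; the weakly-identified scale parameters
(`sigma_gamma`, `sigma_z`) and the gauge-dependent effect levels are the
slowest coordinates, which is intrinsic to the model rather than the
sampler.

Sampling is deterministic given `(seed, inputs)`; per-chain streams are
spawned from a single `SeedSequence`.

## Model comparison

DIC uses the full binomial log-likelihood including the binomial
coefficients, so absolute deviances are comparable across submodels:
`Dbar` is the posterior mean deviance, `Dhat` the deviance at the
posterior mean of the *cell probabilities* (the plug-in is taken on the
probability scale, which is well-defined under the sum-to-zero gauge),
`pD = Dbar - Dhat`, `DIC = Dbar + pD`.

A caution that the analysis itself demonstrates: when cell-level
heterogeneity is present, `z` can absorb a smooth cohort (or period)
signal at essentially the same effective-parameter cost as the dedicated
effect, so the four submodels reach nearly equal DICs — the
structured-residual diagnostic (`heterogeneity_summary`, per-age and
per-period means and SDs of posterior-mean `z`) is then the informative
tool, showing trend-shaped residuals under the misspecified submodels.
The package's model-selection experiment therefore generates age-cohort
data *without* extra heterogeneity, so that the cohort signal is the only
structure beyond age and DIC can rank the models; with heterogeneity
switched on the near-equality of DICs is itself asserted as the expected
outcome.

## Outputs

Effect-level prevalence curves are `expit(delta + effect_t)` computed
draw-by-draw; the point estimate is the posterior mean and the bounds are
equal-tailed 2.5/97.5 percentiles.  `z` is excluded from these curves by
construction.  Between-stratum prevalence ratios divide the posterior-mean
curves of two independently fitted strata (a per-draw ratio distribution,
pairing draws index-wise, is available as `prevalence_ratio_draws` but is
not the default since the fits are independent).  Direct age
standardization is the weighted mean of age-specific prevalences with
user-supplied standard-population weights (normalized to sum 1); weights
are always user-supplied because the survey's 2019 household age
distribution is not published, so published standardized values can be
reproduced in procedure but not matched numerically.

## Synthetic data

`synthetic_data` generates survey-like tables with known truth on the
12 x 6 study lattice (constant denominator 10,000 per cell by default —
large enough for the recovery tolerances, small enough for desk-scale
runtime).  Ground-truth curves are deterministic parametric shapes chosen
to mimic the field's typical findings: age effect declining linearly
(log-odds span 1.4), period effect declining linearly (span 0.8), cohort
effect a quadratic bump peaking about a third of the way through the
cohort axis (amplitude 0.6), all scaled by `effect_scale` and centered;
baseline prevalence 0.35 (a men-like stratum); `z` iid Normal with SD
0.05.  RW1-draw truth is available via `effect_curves="rw1"`.  A
two-strata generator produces urban / non-urban pairs whose period
declines differ by a configurable gap (default 0.3 log-odds).

What the generator does *not* emulate: survey nonresponse, household
clustering, sampling-weight effects, or the noise introduced by deriving
non-urban counts as national-minus-urban.  Passing recovery tests
therefore show correctness of the estimator under the stated binomial
model, not robustness to real survey complications.

## Numerical choices and degenerate inputs

- Counts reconstructed from published percentages are rounded half away
  from zero (`round(pct/100 * denominator)`).
- Single-level axes are allowed (a 1 x 1 lattice gives K = 1 and an
  intercept-only model, used by the quadrature cross-checks); effects
  with fewer than two levels are dropped from sampling and fixed at zero.
- Log-scale coordinates are rejected outside |log sigma| > 40 before
  exponentiation; slice-sampled scales are bounded to [1e-5, 1e3].
- The DIC identity `DIC = Dhat + 2 pD` holds to floating-point rounding
  (checked at relative 1e-12).
- `center_effects` is idempotent and leaves the linear predictor
  unchanged to < 1e-12; reported draws satisfy sum-to-zero to < 1e-10.

## Problem sizes used by the test suite

The suite fits real-size (12 x 6, K = 71) models throughout but with
reduced iteration counts chosen for desk-scale runs: the shared recovery
fit uses 4 chains x 600 draws; the 20-replicate model-selection study
uses 2 chains x 250 draws per fit; quadrature cross-checks use 4 chains x
1,000 draws on a single cell.  Production analyses should use the
defaults (4 x 2,000) or larger.

## Known limitations

- Effect-level prevalences inherit the APC gauge ambiguity; compare
  second differences or fitted probabilities across specifications.
- DIC is the only comparison criterion implemented (no WAIC/LOO).
- The bundled survey table ships prevalences only; absolute DICs depend
  on the (unpublished) survey denominators and are therefore not
  comparable with published values.
- One stratum is fitted at a time; no sharing of parameters across
  strata.
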