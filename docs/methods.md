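# Methods

## Scope and model

`litterevo` implements a three-stage comparative analysis of leaf litter
decomposability as an *effect trait*:

1. **Decay constants.** For each species, litterbag mass-loss series are
   reduced to a single-exponential decay constant *k* (d⁻¹): ordinary least
   squares of ln(percent mass remaining) on time, with *k* the negated
   slope.  Because the initial dry mass is known from the protocol
   (2 ± 0.1 g), the regression by default includes the anchor point
   (t = 0, ln 100); `include_t0=False` drops it.  Replicate bags at a
   harvest enter as separate points, never pre-averaged.

2. **Trait → k regression.** ln(k) is regressed on ln-scale leaf traits
   (base cations BC, carbon TC, nitrogen TN, phosphorus TP, toughness LT,
   specific leaf area SLA, leaf area LA) by exhaustive best-subset OLS:
   all 2ᴷ − 1 non-empty subsets are fit with intercept and scored by the
   Gaussian maximum-likelihood AICc.  The parameter count is
   p = |predictors| + 2, counting the intercept and the residual variance;
   this convention reproduces every published AIC → AICc gap at n = 48.
   Subsets are compared via Δᵢ, Akaike weights
   wᵢ = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2), cumulative weights, evidence ratios
   exp(Δᵢ/2), and the minimal rank-prefix whose cumulative weight reaches
   0.95 (the 95% confidence set).  Weights are normalized over all
   evaluated candidates, and all quantities are computed from unrounded
   scores.

3. **Trait macroevolution.** Each ln-scale trait (including ln k) is fit
   with three Gaussian models of continuous evolution on a rooted
   time-calibrated phylogeny.  Tips are multivariate normal with mean
   z₀·1 and covariance:

   * BM: V_ij = β t_ij,
   * EB: V_ij = β (e^{r t_ij} − 1)/r, r ≤ 0, BM limit at r = 0,
   * OU: V_ij = β/(2α) e^{−α(T_i + T_j − 2 t_ij)} (1 − e^{−2α t_ij}),
     BM limit at α = 0,

   where t_ij is the root-to-MRCA path length of tips i and j and T_i the
   root-to-tip depth (so the OU form is valid for non-ultrametric trees).
   Per-species measurement error enters as se² added to the covariance
   diagonal and held fixed (standard error of the species mean from
   replicate measurements; not estimated).  The phylogenetic half-life is
   t₁/₂ = ln 2 / α, reported as +∞ when α = 0.

### OU parameter count

The OU optimum is constrained equal to the root state z₀, giving parameter
counts p = {BM: 2, EB: 3, OU: 3}.  This is the only convention consistent
with the published AICc arithmetic for this analysis (e.g.
−2·(−18.19) + 6 + 24/35 = 43.07 at n = 39).  A free-optimum convention
(p = 4) is selectable via `FitOptions.free_optimum_params` or
`--free-optimum`; it changes only the information scores, not the fit.

## Fitting

Given the shape parameter θ (r for EB, α for OU; none for BM) and no
measurement error, the likelihood is profiled analytically: with
V = β C(θ),

  ẑ₀ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1),  β̂ = (x − ẑ₀)ᵀC⁻¹(x − ẑ₀)/n,

so only θ is optimized: a seeded multi-start (endpoints, a deterministic
spread — log-spaced for α, linear for r — plus uniform jitter) followed by
bounded Brent polish.  With measurement error V = β C(θ) + diag(se²), β no
longer profiles out; (log β, θ) are optimized by L-BFGS-B from seeded
restarts, warm-started at the no-error solution, with z₀ still profiled.
Likelihoods use a Cholesky factorization; a condition-number estimate from
the Cholesky diagonal above 10¹² raises a singularity error.  Boundary
MLEs are flagged (`bound_hits`), not rejected.

Default bounds: β ∈ [10⁻⁸, 10⁴], α ∈ [0, 50] Myr⁻¹,
r ∈ [−ln 10⁵/depth, 0], all overridable.  The α lower bound is 0, not a
small positive number: the OU covariance at α = 0 is defined as the exact
BM matrix, so the OU search space strictly nests BM and the fitted OU
likelihood can never fall below BM's — with a positive lower bound of
10⁻⁷ the residual gap on a 350-Myr tree is ~10⁻⁵ lnL units, which breaks
the nesting property the model comparison relies on.

## Tree preparation

Newick I/O and random polytomy resolution are delegated to dendropy;
resolution inserts zero-length internal edges with a seeded random stream,
which provably leaves the shared-ancestry matrix — and hence every model
covariance — unchanged.  Age smoothing assigns fixed ages (root from the
table, tips at 0, labeled internal nodes from the table) and interpolates
each chain of undated nodes evenly in age between its nearest dated
ancestor and nearest dated descendant (fewest intervening nodes; ties go
to the older candidate), then sets branch lengths as age differences.
Ordering violations (a dated node not strictly younger than its nearest
dated ancestor) are hard errors.  Ultrametricity is validated at relative
tolerance 10⁻⁶ but not required by the OU covariance.

## Synthetic studies

The raw species data behind the target analysis is not redistributable, so
validation runs on synthetic studies whose defaults are the study
conditions themselves:

* a pure-birth tree of 39 tips rescaled to exactly 350 Myr depth (the
  birth process is continued past the nth birth by one exponential waiting
  time so no terminal edge is zero — the stopped tree would carry a
  singular covariance);
* traits drawn from the exact model MVN at the tips (Cholesky sampling),
  default OU with β = 0.012, α = 0.036 — half-life ≈ 19 Myr, the regime of
  the decomposability trait;
* 5 replicate measurements per species with within-species sd 0.1
  ln-units (a typical ~10% replicate CV; no published value exists), from
  which species means and standard errors are computed;
* ln k = −6 + BC − LT + SLA + TP + noise, unit-magnitude coefficients with
  signs from decomposition biology, noise variance set from the realized
  signal variance so the population R² is 0.51;
* litterbags of 1.9–2.1 g harvested at 90/270/365 d with unit-mean
  lognormal mass noise (cv 0.1).

What the generator does *not* emulate: correlations among traits beyond
shared phylogeny, non-Gaussian trait distributions, harvest-time loss of
bags, moisture-correction error, and topological uncertainty.  Passing
recovery tests therefore demonstrates correctness of the estimators under
their own assumptions, not robustness to real-data violations of them.

All generators are pure functions of (config, seed); per-stage child seeds
are derived with CRC32-keyed `numpy.random.SeedSequence` so runs are
reproducible across processes.

## Problem sizes

The validation suite uses 100 replicate studies for model identification
and subset-selection consistency, 1000 series for decay recovery, and
4 × 10⁴ Monte-Carlo draws for the covariance calibration check — sizes at
which the whole suite completes in well under a minute while Monte-Carlo
error stays several times below every acceptance band.

## Known limitations

* Single-optimum OU only; no multi-regime models, no phylogenetic signal
  statistics, no ancestral-state reconstruction.
* Regressions are non-phylogenetic OLS by design, matching the analysis
  this package supports; a GLS variant is out of scope.
* The ML rate and rubber-band estimates carry the usual finite-sample
  upward bias at n ≈ 39; the recovery tests bound the median within a
  factor of two of truth rather than asserting unbiasedness.
* Exhaustive subset enumeration is exponential in K; it is intended for
  the K ≲ 15 trait panels typical of this literature.
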