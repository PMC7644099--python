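# Methods

## The model

A microbial growth experiment produces log optical-density curves
y(t) indexed by designed treatment factors, by *batch* (one run of the
plate reader) and by *replicate* within batch.  phenom models every
systematic and random component of such data as an unknown smooth
function with a Gaussian-process (GP) prior:

* **Fixed effects.**  A grand mean m(t); for a single treatment factor,
  a deviation δ(t) per non-reference level
  (y_r(t) = m(t) + δ(t) + ε_r(t) under treatment, m(t) + ε_r(t) under
  the control); for a two-factor design, a functional-ANOVA
  decomposition m(t) + α_p(t) + β_c(t) + (αβ)_{p,c}(t) with main effects
  and interaction.  Identifiability uses corner constraints: reference
  levels (the experimental control) carry zero effect.  The reference
  level defaults to the first level in numeric-aware sort order and
  should normally be set explicitly to the control condition.
* **Batch random effects** (model `M_batch`).  Every fixed-effect
  function gains a per-batch random twin — m^(k)(t), δ^(k)(t), … —
  drawn from a zero-mean GP shared within its group, with variance and
  lengthscale distinct from the fixed effect's.  This is what lets the
  model distinguish "the treatment effect" from "what the treatment
  happened to look like in batch k".
* **Replicate random effects** (model `M_full`).  Each curve
  additionally carries its own smooth GP deviation, capturing
  autocorrelated replicate-level variability on top of i.i.d.
  measurement noise σ_y².  `M_null` ⊂ `M_batch` ⊂ `M_full` are nested:
  the richer covariance families contain the simpler ones in the
  zero-variance limit (this is tested).

All kernels are RBF, κ(t, t′) = σ²·exp(−|t − t′|²/ℓ), with the
lengthscale **un-squared** in the denominator.  That convention is
deliberate (it matches the convention this model family is published
with); the field-standard form σ²·exp(−|t − t′|²/(2ℓ²)) is available
via `kernel_dialect="squared_lengthscale"`.

## Likelihood and inference

Because every latent function is Gaussian given its hyperparameters,
all of them are marginalized analytically: the concatenated observation
vector is multivariate normal with covariance
Σ = Σ_g Z_g K_g Z_gᵀ + σ_y² I, where Z_g is the 0/1 incidence of
observations onto the latent functions of effect group g.  The sampler
therefore explores only the hyperparameters — one (σ², ℓ) per effect
group plus σ_y² (9 parameters for a two-condition `M_batch` model,
11 for `M_full`) — which mixes far better than sampling thousands of
latent function values.

Curves never need a shared grid: covariance assembly operates on the
concatenated observation vector.  When replicates of a condition within
a batch do share a grid (the common case), the likelihood uses an exact
exchangeable-replicate reduction: rotating each such cell by an
orthonormal basis whose first vector is the normalized mean splits the
density into a small MVN over scaled cell means plus i.i.d. residual
contrast terms.  This is a sufficient-statistic identity, not an
approximation (dense and collapsed paths agree to ~1e-12 in the tests),
and reduces the per-evaluation Cholesky cost by the cube of the
replicate count.

Sampling is No-U-Turn HMC on log-transformed hyperparameters
(positivity by construction, log-Jacobian included), with analytic
gradients of the marginal likelihood, dual-averaging step-size
adaptation to a 0.8 target acceptance rate, and windowed diagonal
mass-matrix estimation during warmup.  Defaults: 4 chains × 1000
warmup × 1000 sampling iterations; identical seeds give bitwise
identical draws; divergences above 1 % of draws trigger a loud warning.
Convergence is diagnosed with split-R̂ (each chain halved,
between-/within-half variance), *without* rank normalization, matching
the era of the R̂ < 1.1 recommendation the workflow targets; arviz's
split-R̂ is used as an independent cross-check in the tests.

### Priors

| parameter | prior | rationale |
|---|---|---|
| fixed-effect σ² | Gamma(10, 10) (shape–rate) | mean 1 on the log-OD² scale of standardized data |
| random-effect σ² | Gamma(7, 10) | mean 0.7; random effects expected somewhat smaller |
| ℓ (preset `halobacterium`) | inv-Gamma(6, 1), all groups | mean 0.2 on [0, 1]-standardized time |
| ℓ (preset `pseudomonas`) | inv-Gamma(2, 3) fixed / inv-Gamma(10, 1) random | heavier-tailed for fixed effects |
| noise σ_y² | Gamma(1, 10) | weakly informative, mean 0.1; the source convention leaves this prior's parameters open, so this default is our choice, recorded in output metadata and overridable via `priors.noise` |

Time is standardized to [0, 1] before modelling (the lengthscale priors
above are scale-appropriate for that range; in raw hours they would be
far too concentrated); all user-facing output converts back to hours.
Optical density is modelled as its natural log, with no baseline
subtraction — time-zero offsets are absorbed by the batch-effect terms.
Blank-well correction is available as a preprocessing flag, default
off.

## Posterior products

Conditional on each (thinned) hyperparameter draw, any latent function
f evaluated on a grid is Gaussian,
N(K_*ᵀ Σ⁻¹ y, K_** − K_*ᵀ Σ⁻¹ K_*); the reported function posterior is
the mixture over draws (default thinned to ≤ 500), one function draw
per hyperparameter draw.  Derivatives — the instantaneous growth rate
d log OD/dt, reported per hour — use the analytic RBF derivative
kernels, which are exact under the model; a finite-difference
cross-check exists in the test suite.  Credible bands are pointwise
central quantiles (default 95 %); no simultaneous-band or
multiple-testing adjustment is attempted.  "Significant" intervals are
maximal runs of grid points (default 100 over the observed range) whose
band excludes zero, endpoints snapped to the grid.

Variance components are the posterior kernel variances per effect
group.  Batch groups are pooled into a single "batch" component by
summing per-draw variances (the effects are independent and additive,
so variances add); `pool_batch_components=False` keeps them separate.
The replicate component is labelled "biological", σ_y² "noise".

## The synthetic-data generator

`phenom.synthetic` draws every latent function from its GP on a common
grid, sums them through the same incidence structure the likelihood
uses, and adds i.i.d. Gaussian noise — it is the exact generative twin
of the marginal covariance (tested: the empirical covariance of 20,000
forward draws matches the assembled Σ within Monte-Carlo error).

Presets mirror the two study designs the package targets: `halo_like`
(3 stress levels × 9 batches × 12 replicates, 48 h at 30-min steps),
`pa_like` (3 pH × 3 acid concentrations × 2 batches × 3 replicates,
24 h at 15-min steps) and `halo_like_reduced` (2 conditions × 3 batches
× 3 replicates, 25 points over 48 h) for fast experiments.  Default
ground truth puts batch and treatment variances at equal magnitude
(0.4) — the regime where hierarchical modelling matters most — with
replicate variance 0.1 and noise 0.01, i.e. batch effects several-fold
above replicate and measurement noise.  The generator emulates the
covariance structure of plate-reader data, not its mechanistic shape:
latent curves are GP draws, not sigmoids, so passing recovery tests
demonstrates correct inference under the model's own assumptions, not
robustness to model misspecification, instrument drift, or non-Gaussian
noise.

Calibration experiments (`recovery_experiment`) support ground truth
either fixed or drawn from the model priors per replication
(`truth="prior"`); the latter is the standard Bayesian calibration
protocol under which 95 % intervals cover truth at nominal rate when
the sampler is correct, and is what the coverage test uses.

## Numerical choices

* A diagonal jitter of 1e-8·σ_y² is always included in Σ; on Cholesky
  failure it escalates ×10 up to 1e-4 before raising.
* Hyperparameter draws outside e^±40 are treated as zero-probability
  (guards overflow during leapfrog integration).
* Quantiles use linear interpolation of order statistics throughout.
* Posterior CSVs are written at 17 significant digits and read back
  with round-trip float parsing, so serialized draws reproduce
  summaries exactly.
* The logistic baseline uses the grofit parameterization
  y = A / (1 + exp(4·μ_max·(λ − t)/A + 2)), adopted as an external
  convention so μ_max is directly the maximal slope; fits are
  least-squares with data-derived multi-starts (steepest secant for
  μ_max, tangent intercept for λ).  Group comparisons of μ_max use the
  one-sided Welch (unequal-variance) t-test.  KDEs use Gaussian kernels
  with Scott's-rule bandwidth n^(−1/5)·sd.

## Problem sizes in the test suite

The heavy end-to-end checks run at reduced sizes chosen as the smallest
designs that still exercise the scientific claim: the convergence check
runs the full reduced design (450 observations, 4 × (500 + 500)
iterations); variance-component calibration uses 50 replications of a
2 × 2 × 2 × 12 `M_full` design with 2 × (200 + 200) iterations; the
batch-overconfidence comparison uses 10 seeds of a 2 × 6 × 2 × 12
design.  Results at full study scale (9 batches, 97 time points) follow
from the same code paths; only wall-clock time changes.

## Known limitations

* Latent GPs are marginalized, so per-iteration cost is cubic in the
  collapsed observation count; no sparse/inducing-point approximations
  are provided.
* At most two crossed factors (main effects + pairwise interaction);
  no model-comparison criteria (WAIC, Bayes factors).
* Bands are pointwise; simultaneous coverage is not controlled.
* With few batches the treatment effect and the mean of its batch
  effects are weakly identified; credible bands widen accordingly, and
  several batches of replication are needed before a small treatment
  effect can be called significant.
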