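# phenom

Hierarchical Bayesian non-parametric mixed-effects modelling of
microbial population growth curves.

## The problem

High-throughput plate readers measure optical density of hundreds of
microbial cultures over one to two days.  The scientific question is
usually a *functional contrast*: how does growth under a stress,
a pH level, or an acid concentration differ from the control, over
time?  Two things make this hard in practice:

1. **Growth curves under stress are not sigmoids**, so classical
   parametric models (logistic, Gompertz) fit poorly exactly where the
   biology is interesting.
2. **Batch effects** — random variation shared by every culture in one
   plate-reader run — are frequently as large as the treatment effect
   itself.  Analyses that ignore them are overconfident: each batch
   yields a tight, confident, and *mutually contradictory* estimate of
   the same treatment effect.

phenom addresses both with a functional mixed-effects model in which
every component is an unknown smooth function with a Gaussian-process
prior.  For a single treatment at level s in batch k, replicate r:

    y_{k,r}(t) = m(t) + δ_s(t) + m^(k)(t) + δ_s^(k)(t) + ε_{k,r}(t)

with m(t) the mean log-OD curve, δ_s(t) the treatment effect
(zero for the control), m^(k), δ^(k) batch random effects, and
ε replicate-level noise (i.i.d., plus a smooth per-curve GP in the
fullest model).  Two-factor designs use the functional-ANOVA form
m + α_p + β_c + (αβ)_{p,c}.  All kernels are
RBF, κ(t,t′) = σ²·exp(−|t−t′|²/ℓ).  Three nested models — `M_null`
(no random effects), `M_batch` (+batch), `M_full` (+replicate) — let
you measure what ignoring each variance source would cost you.

Latent functions are marginalized analytically; the kernel
hyperparameters (a variance and lengthscale per effect group, plus
noise) are sampled by NUTS with analytic gradients.  Outputs are
posterior credible bands for every effect (and its time derivative,
the instantaneous growth rate), intervals where an effect is credibly
non-zero, and variance components that quantify how much of the data
each source — mean, treatment, batch, biological, noise — explains.
See `docs/methods.md` for the full model, priors, and numerical
details.

## Worked example

Simulate a reduced stress-response design (2 conditions × 3 batches ×
3 replicates, 48 h sampled at 25 points, batch effects comparable to
the treatment effect), then fit the batch-effects model:

```sh
phenom simulate --preset halo_like_reduced --seed 0 --out-dir demo
phenom fit demo/growth.csv --config config.yaml --out-dir demo_fit \
       --seed 0 --chains 4 --iters 250 --warmup 250
phenom report demo_fit
```

with `config.yaml`:

```yaml
model:
  kind: M_batch
  structure: single_treatment
  reference_levels: {stress: standard}
data:
  factors: [stress]
```

The report printed by the commands above:

```
# phenom fit report

## Convergence (split R-hat)

- mean.variance: mean=0.9436 sd=0.297 rhat=0.997 ess=1747
- mean.lengthscale: mean=0.1841 sd=0.0633 rhat=1.003 ess=886
- treatment.variance: mean=0.9643 sd=0.304 rhat=1.002 ess=1389
- treatment.lengthscale: mean=0.2913 sd=0.109 rhat=0.999 ess=1089
- mean_batch.variance: mean=0.5546 sd=0.202 rhat=0.998 ess=1479
- mean_batch.lengthscale: mean=0.1888 sd=0.0476 rhat=0.998 ess=1061
- treatment_batch.variance: mean=0.5479 sd=0.218 rhat=0.999 ess=1256
- treatment_batch.lengthscale: mean=0.3371 sd=0.156 rhat=0.999 ess=1033
- noise.variance: mean=0.01064 sd=0.000765 rhat=0.998 ess=1357

## Variance components

- mean: 0.9436 [0.4395, 1.587]
- treatment: 0.9643 [0.4771, 1.625]
- batch: 1.103 [0.6257, 1.788]
- noise: 0.01064 [0.009261, 0.01225]

## Significant effect intervals

- treatment[low]: 10.7-39.3 h (-)
```

Reading it: every split R̂ is below 1.1, so the four chains agree.  The
variance components say the treatment effect (0.96) and the pooled
batch effects (1.10) are the same order of magnitude — the regime where
per-batch analyses mislead — both far above measurement noise (0.011,
all in log-OD² units).  The treatment band excludes zero from about
10.7 h to 39.3 h with negative sign: the stress credibly *impairs*
growth through mid-experiment, and the interval honestly shrinks to
nothing near t = 0 and at the end, where batch variation swamps the
effect.  `demo_fit/` also contains the posterior draws
(`posterior.csv`), effect bands and growth-rate derivative bands
(`bands.csv`), and a machine-readable manifest.

The same machinery is available as a library —
`phenom.simulate_dataset`, `phenom.build_model`,
`phenom.sample_posterior`, `phenom.latent_function_posterior`,
`phenom.variance_components` — which is what the test suite and the
scripts use.

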