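"""Forward simulation of the hierarchical GP growth model.

Each latent function (mean, treatment effects, per-batch random twins,
per-curve replicate effects) is drawn from its RBF-kernel GP on a
common time grid, summed per the model's incidence structure, and
observed with i.i.d. Gaussian noise.  The simulator is the generative
twin of the marginal likelihood, which makes it the natural tool for
covariance cross-checks, parameter-recovery experiments and posterior
calibration studies.

Two presets mirror the study designs this package targets: ``halo_like``
(one stress factor at 3 levels, 9 batches, 12 replicates per condition
and batch, 48 h sampled every 30 min) and ``pa_like`` (a full-factorial
pH × acid-concentration design, 2 batches, 3 replicates, 24 h every
15 min).  ``halo_like_reduced`` is a small two-condition variant used
throughout the test suite.  Default ground-truth hyperparameters put
batch and treatment variances at comparable magnitude — the regime in
which hierarchical modelling matters most — with batch effects several
times larger than replicate and measurement noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .data import GrowthCurve, GrowthDataset
from .likelihood import LikelihoodStructure
from .model import ModelDef, build_model, param_names, sample_prior
from .kernels import KernelHyperparams, rbf_kernel, jittered_cholesky

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_dataset",
    "recovery_experiment",
    "RecoveryReport",
    "preset",
    "PRESETS",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Design and ground truth for one simulated experiment.

    ``truth`` maps parameter names (``<group>.variance`` etc.) to
    positive reals, or is the string ``"prior"`` to draw ground-truth
    hyperparameters from the model priors (the setting used for
    calibration experiments).
    """

    factors: dict[str, list[str]]
    reference_levels: dict[str, str]
    n_batches: int
    n_replicates: int
    times_hours: np.ndarray
    model_kind: str = "M_full"
    structure: str = "single_treatment"
    truth: dict[str, float] | str = field(default_factory=dict)
    lengthscale_preset: str = "halobacterium"
    kernel_dialect: str = "as_printed"
    seed: int | None = None

    def __post_init__(self):
        self.times_hours = np.asarray(self.times_hours, dtype=float)
        if self.n_batches < 1 or self.n_replicates < 1:
            raise ConfigError("batch and replicate counts must be >= 1")
        if len(np.unique(self.times_hours)) != len(self.times_hours):
            raise ConfigError("duplicated grid points make the kernel singular")
        if isinstance(self.truth, dict):
            bad = {k: v for k, v in self.truth.items() if not v > 0}
            if bad:
                raise ConfigError(f"ground-truth values must be positive: {bad}")
        elif self.truth != "prior":
            raise ConfigError("truth must be a dict or the string 'prior'")


@dataclass
class SimulatedTruth:
    """Realized latent functions and the hyperparameters that produced them."""

    hyperparams: dict[str, float]
    latents: dict[str, dict[tuple, np.ndarray]]  # group -> label -> f on grid
    grid_model: np.ndarray
    grid_hours: np.ndarray

    def effect(self, group: str, label: tuple = ()) -> np.ndarray:
        d = self.latents[group]
        if label in d:
            return d[label]
        if len(d) == 1:
            return next(iter(d.values()))
        raise KeyError(f"label {label!r} not in group {group!r}: {sorted(d)}")


# ---------------------------------------------------------------- presets

def _default_truth(model: ModelDef) -> dict[str, float]:
    """Study-condition ground truth: batch ≈ treatment variance, both
    several-fold above replicate and measurement noise."""
    truth = {}
    for g in model.groups:
        if g.name == "mean":
            truth[f"{g.name}.variance"] = 1.0
            truth[f"{g.name}.lengthscale"] = 0.2
        elif g.curve_indexed:
            truth[f"{g.name}.variance"] = 0.1
            truth[f"{g.name}.lengthscale"] = 0.05
        elif g.batch_indexed:
            truth[f"{g.name}.variance"] = 0.4
            truth[f"{g.name}.lengthscale"] = 0.2
        else:
            truth[f"{g.name}.variance"] = 0.4
            truth[f"{g.name}.lengthscale"] = 0.2
    truth["noise.variance"] = 0.01
    return truth


def preset(name: str, seed: int | None = None, **overrides) -> SimulationConfig:
    """Named simulation presets mirroring the two study designs."""
    if name == "halo_like":
        cfg = SimulationConfig(
            factors={"stress": ["standard", "low", "high"]},
            reference_levels={"stress": "standard"},
            n_batches=9,
            n_replicates=12,
            times_hours=np.linspace(0.0, 48.0, 97),
            model_kind="M_full",
            structure="single_treatment",
            seed=seed,
        )
    elif name == "halo_like_reduced":
        cfg = SimulationConfig(
            factors={"stress": ["standard", "low"]},
            reference_levels={"stress": "standard"},
            n_batches=3,
            n_replicates=3,
            times_hours=np.linspace(0.0, 48.0, 25),
            model_kind="M_batch",
            structure="single_treatment",
            seed=seed,
        )
    elif name == "pa_like":
        cfg = SimulationConfig(
            factors={"pH": ["7", "6", "5"], "acid_mM": ["0", "10", "20"]},
            reference_levels={"pH": "7", "acid_mM": "0"},
            n_batches=2,
            n_replicates=3,
            times_hours=np.linspace(0.0, 24.0, 97),
            model_kind="M_full",
            structure="two_factor_interaction",
            lengthscale_preset="pseudomonas",
            seed=seed,
        )
    else:
        raise ConfigError(f"unknown preset {name!r}; choose halo_like, halo_like_reduced, pa_like")
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ConfigError(f"unknown preset override {k!r}")
        setattr(cfg, k, v)
    cfg.__post_init__()
    return cfg


PRESETS = ("halo_like", "halo_like_reduced", "pa_like")


# ---------------------------------------------------------------- simulate

def _skeleton(cfg: SimulationConfig) -> GrowthDataset:
    """Dataset with the design of cfg and zero observations."""
    t_hours = cfg.times_hours
    span = t_hours[-1] - t_hours[0]
    t_model = (t_hours - t_hours[0]) / span
    zeros = np.zeros_like(t_model)
    names = list(cfg.factors)
    combos = [()]
    for f in names:
        combos = [c + (lv,) for c in combos for lv in cfg.factors[f]]
    curves = []
    for combo in combos:
        for b in range(1, cfg.n_batches + 1):
            for r in range(1, cfg.n_replicates + 1):
                curves.append(
                    GrowthCurve(
                        times=t_model,
                        values=zeros,
                        factors=dict(zip(names, combo)),
                        batch=f"b{b}",
                        replicate=f"{'_'.join(combo)}_r{r}" if combo else f"r{r}",
                    )
                )
    return GrowthDataset(
        curves=curves,
        factor_names=names,
        time_scale=(t_hours[0], 1.0 / span),
        log_transformed=True,
    )


def build_truth_model(cfg: SimulationConfig, dataset: GrowthDataset | None = None) -> ModelDef:
    dataset = dataset if dataset is not None else _skeleton(cfg)
    return build_model(
        cfg.model_kind,
        dataset,
        cfg.structure,
        reference_levels=cfg.reference_levels,
        lengthscale_preset=cfg.lengthscale_preset,
        kernel_dialect=cfg.kernel_dialect,
    )


def simulate_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GrowthDataset, SimulatedTruth]:
    """Draw one dataset from the generative model.

    Returns the dataset on the model scale (log OD, time in [0, 1] with
    the hours map stored in ``time_scale``) together with the realized
    latent functions and hyperparameters.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    skel = _skeleton(cfg)
    model = build_truth_model(cfg, skel)
    names = param_names(model)
    if cfg.truth == "prior":
        truth = sample_prior(model, rng)
    else:
        truth = _default_truth(model)
        unknown = set(cfg.truth) - set(names)
        if unknown:
            raise ConfigError(f"truth for unknown parameters: {sorted(unknown)}")
        truth.update(cfg.truth)
    structure = LikelihoodStructure(skel, model)
    grid = skel.curves[0].times
    n_t = len(grid)

    latents: dict[str, dict[tuple, np.ndarray]] = {}
    contributions = np.zeros((len(skel.curves), n_t))
    for g in model.groups:
        hp = KernelHyperparams(truth[f"{g.name}.variance"], truth[f"{g.name}.lengthscale"])
        k = rbf_kernel(grid, grid, hp, model.kernel_dialect)
        L, _ = jittered_cholesky(k, 1e-10 * hp.variance, 1e-4 * hp.variance)
        latents[g.name] = {}
        for label, mask in structure.latents[g.name]:
            f = L @ rng.standard_normal(n_t)
            latents[g.name][label] = f
            contributions[mask] += f
    noise_sd = np.sqrt(truth["noise.variance"])
    values = contributions + noise_sd * rng.standard_normal(contributions.shape)

    curves = [
        dataclasses.replace(c, values=values[i]) for i, c in enumerate(skel.curves)
    ]
    dataset = GrowthDataset(
        curves=curves,
        factor_names=skel.factor_names,
        time_scale=skel.time_scale,
        log_transformed=True,
    )
    t_hours = dataset.to_hours(grid)
    return dataset, SimulatedTruth(truth, latents, grid, t_hours)


# ---------------------------------------------------------------- recovery

@dataclass
class RecoveryReport:
    """Per-replication draws vs. truth, and aggregated calibration metrics."""

    per_rep: "pandas.DataFrame"
    summary: "pandas.DataFrame"
    n_reps: int
    rhat_pass_fraction: float


def recovery_experiment(
    cfg: SimulationConfig,
    n_reps: int,
    mcmc_cfg=None,
    fit_kind: str | None = None,
    rhat_threshold: float = 1.1,
) -> RecoveryReport:
    """Simulate → fit → compare, replicated.

    For every variance component (kernel variances plus noise) reports
    bias, relative bias, RMSE and 95 % central-interval coverage across
    replications, and the fraction of replications whose parameters all
    converged below the R̂ threshold.  Deterministic given
    ``cfg.seed``/``mcmc_cfg.seed``.
    """
    import pandas as pd

    from .inference import MCMCConfig, sample_posterior, rhat as compute_rhat

    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    mcmc_cfg = mcmc_cfg or MCMCConfig()
    master = np.random.SeedSequence(cfg.seed if cfg.seed is not None else 0)
    rep_seeds = master.spawn(n_reps)
    rows = []
    rhat_pass = 0
    for rep, seq in enumerate(rep_seeds):
        rng = np.random.default_rng(seq)
        dataset, truth = simulate_dataset(cfg, rng)
        model = build_truth_model(cfg, dataset)
        if fit_kind is not None and fit_kind != model.kind:
            from .model import with_kind

            model = with_kind(model, dataset, fit_kind)
        chain_seed = int(rng.integers(2**31 - 1))
        fit_cfg = dataclasses.replace(mcmc_cfg, seed=chain_seed)
        samples = sample_posterior(dataset, model, fit_cfg)
        rhats = compute_rhat(samples)
        ok = bool(np.all(np.asarray(list(rhats.values())) < rhat_threshold))
        rhat_pass += ok
        for name in samples.param_names:
            if not name.endswith(".variance"):
                continue
            draws = samples.draws_for(name).ravel()
            lo, hi = np.quantile(draws, [0.025, 0.975])
            tv = truth.hyperparams.get(name, np.nan)
            rows.append(
                {
                    "rep": rep,
                    "parameter": name,
                    "truth": tv,
                    "posterior_mean": float(np.mean(draws)),
                    "q2.5": float(lo),
                    "q97.5": float(hi),
                    "covered": bool(lo <= tv <= hi),
                    "rhat_ok": ok,
                }
            )
    per_rep = pd.DataFrame(rows)
    grp = per_rep.groupby("parameter")
    summary = pd.DataFrame(
        {
            "bias": grp.apply(lambda d: (d.posterior_mean - d.truth).mean(), include_groups=False),
            "rel_bias": grp.apply(
                lambda d: ((d.posterior_mean - d.truth) / d.truth).mean(), include_groups=False
            ),
            "rmse": grp.apply(
                lambda d: float(np.sqrt(((d.posterior_mean - d.truth) ** 2).mean())),
                include_groups=False,
            ),
            "coverage": grp["covered"].mean(),
        }
    ).reset_index()
    return RecoveryReport(
        per_rep=per_rep,
        summary=summary,
        n_reps=n_reps,
        rhat_pass_fraction=rhat_pass / n_reps,
    )
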