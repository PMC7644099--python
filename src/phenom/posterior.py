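"""Posteriors of latent functions, conditional on hyperparameter draws.

Given hyperparameters, the joint of (latent function values, data) is
Gaussian, so each latent effect has a closed-form conditional
N(K_*ᵀ Σ⁻¹ y, K_** − K_*ᵀ Σ⁻¹ K_*), where K_* couples the effect to the
observations through its incidence.  The function posterior is the
mixture of these conditionals over (thinned) MCMC hyperparameter draws:
one function draw per hyperparameter draw.  Derivatives (instantaneous
growth rate, d log OD/dt per hour) substitute the analytic RBF
derivative kernels — exact under the model, not finite differences of
draws.

Bands are pointwise central credible intervals on the mixture;
"significant" time intervals are maximal grid runs where the band
excludes a reference value (zero for treatment effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .data import GrowthDataset
from .inference import PosteriorSamples
from .kernels import (
    KernelHyperparams,
    jittered_cholesky,
    rbf_derivative_cross,
    rbf_derivative_kernel,
    rbf_kernel,
)
from .likelihood import LikelihoodStructure, _DensePath
from .model import ModelDef

__all__ = [
    "FunctionPosterior",
    "CredibleBand",
    "VarianceComponentTable",
    "SelectionError",
    "latent_function_posterior",
    "latent_conditional_moments",
    "fitted_conditional_moments",
    "fitted_curve_posterior",
    "credible_band",
    "significant_intervals",
    "variance_components",
]


class SelectionError(ValueError):
    """Effect selector does not resolve to exactly one latent function."""


@dataclass
class FunctionPosterior:
    """Draws of one latent function on a time grid.

    ``grid`` is in hours; ``draws`` has shape (n_draws, n_grid) on the
    log-OD scale (or log-OD/hour when ``derivative``).
    """

    grid: np.ndarray
    draws: np.ndarray
    effect: str
    derivative: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.draws.shape[0] < 1 or self.draws.shape[1] != len(self.grid):
            raise ValueError("draws must be (n_draws, n_grid) with n_draws > 0")

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)


@dataclass
class CredibleBand:
    grid: np.ndarray
    lower: np.ndarray
    mean: np.ndarray
    upper: np.ndarray
    level: float
    effect: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": self.effect,
                "time_h": self.grid,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def _default_grid(dataset: GrowthDataset, n: int = 100) -> np.ndarray:
    lo, hi = dataset.time_range
    return dataset.to_hours(np.linspace(lo, hi, n))


def _resolve_latent(structure: LikelihoodStructure, effect: str, level, batch):
    if effect not in structure.latents:
        raise SelectionError(
            f"no effect group {effect!r}; have {list(structure.latents)}"
        )
    latents = structure.latents[effect]
    want_level = None
    if level is not None:
        want_level = (level,) if isinstance(level, str) else tuple(level)
    matches = []
    for j, (label, mask) in enumerate(latents):
        lab = label
        if batch is not None:
            if not lab or lab[-1] != str(batch):
                continue
            lab = lab[:-1]
        if want_level is not None and lab != want_level:
            continue
        matches.append(j)
    if len(matches) != 1:
        raise SelectionError(
            f"selector (effect={effect!r}, level={level!r}, batch={batch!r}) matches "
            f"{len(matches)} latent functions: {[latents[j][0] for j in matches]}"
        )
    return matches[0]


def _single_moments(structure, dense, hp: dict, grid_model, cross_fn):
    """Exact conditional mean/cov of a latent target for one hyperparameter set."""
    from .model import param_names

    theta = np.array([hp[n] for n in param_names(structure.model)])
    sigma = dense.sigma(theta, with_jitter=True)
    L = scipy.linalg.cholesky(sigma, lower=True)
    k_star, k_grid = cross_fn(hp)
    alpha = scipy.linalg.cho_solve((L, True), structure.y_all)
    mean = k_star @ alpha
    v = scipy.linalg.solve_triangular(L, k_star.T, lower=True)
    cov = k_grid - v.T @ v
    return mean, cov


def _conditional_draws(
    structure: LikelihoodStructure,
    samples: PosteriorSamples,
    grid_model: np.ndarray,
    cross_fn,
    max_draws: int,
    seed: int,
):
    """Generic Gaussian conditioning loop over thinned hyperparameter draws.

    ``cross_fn(hp_dict) -> (K_* (n_grid×N), K_** (n_grid×n_grid))``.
    """
    thinned = samples.thinned(max_draws)
    rng = np.random.default_rng(seed)
    dense = _DensePath(structure)
    out = np.empty((len(thinned), len(grid_model)))
    for d, row in enumerate(thinned):
        hp = dict(zip(samples.param_names, row))
        hp.update(samples.fixed)
        mean, cov = _single_moments(structure, dense, hp, grid_model, cross_fn)
        Lc, _ = jittered_cholesky(cov, 1e-10 * max(np.max(np.diag(cov)), 1e-12), 1.0)
        out[d] = mean + Lc @ rng.standard_normal(len(grid_model))
    return out


def _latent_cross_fn(structure, model, effect, j, grid_model, derivative):
    _, curve_mask = structure.latents[effect][j]
    obs_mask = curve_mask[structure.curve_of_obs]
    t_obs = structure.t_all
    dialect = model.kernel_dialect

    def cross_fn(hp):
        hp_k = KernelHyperparams(hp[f"{effect}.variance"], hp[f"{effect}.lengthscale"])
        if derivative:
            k_star = rbf_derivative_cross(grid_model, t_obs, hp_k, dialect)
            k_grid = rbf_derivative_kernel(grid_model, grid_model, hp_k, dialect)
        else:
            k_star = rbf_kernel(grid_model, t_obs, hp_k, dialect)
            k_grid = rbf_kernel(grid_model, grid_model, hp_k, dialect)
        return k_star * obs_mask[None, :], k_grid

    return cross_fn


def _fitted_context(structure, model, factors, batch, replicate_curve):
    context: list[tuple[str, int]] = []
    for g in model.groups:
        for j, (label, mask) in enumerate(structure.latents[g.name]):
            if g.curve_indexed:
                ok = replicate_curve is not None and mask[replicate_curve]
            else:
                lab = label
                if g.batch_indexed:
                    if batch is None or lab[-1] != str(batch):
                        continue
                    lab = lab[:-1]
                ok = all(
                    factors.get(f) == lv for f, lv in zip(g.factors, lab)
                ) and len(lab) == len(g.factors)
            if ok:
                context.append((g.name, j))
    if not context:
        raise SelectionError(f"no latent functions match context {factors!r}")
    return context


def _fitted_cross_fn(structure, model, context, grid_model, derivative):
    t_obs = structure.t_all
    dialect = model.kernel_dialect

    def cross_fn(hp):
        n_g = len(grid_model)
        k_star = np.zeros((n_g, len(t_obs)))
        k_grid = np.zeros((n_g, n_g))
        for gname, j in context:
            hp_k = KernelHyperparams(hp[f"{gname}.variance"], hp[f"{gname}.lengthscale"])
            obs_mask = structure.latents[gname][j][1][structure.curve_of_obs]
            if derivative:
                k_star += rbf_derivative_cross(grid_model, t_obs, hp_k, dialect) * obs_mask[None, :]
                k_grid += rbf_derivative_kernel(grid_model, grid_model, hp_k, dialect)
            else:
                k_star += rbf_kernel(grid_model, t_obs, hp_k, dialect) * obs_mask[None, :]
                k_grid += rbf_kernel(grid_model, grid_model, hp_k, dialect)
        return k_star, k_grid

    return cross_fn


def latent_conditional_moments(
    dataset: GrowthDataset,
    model: ModelDef,
    hp_all: dict[str, float],
    effect: str,
    level=None,
    batch=None,
    grid_hours: np.ndarray | None = None,
    derivative: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional (mean, covariance) of one latent function given y,
    at a single hyperparameter setting.  Grid in hours; derivative output
    is per hour."""
    structure = LikelihoodStructure(dataset, model)
    j = _resolve_latent(structure, effect, level, batch)
    grid_hours = np.asarray(grid_hours, dtype=float) if grid_hours is not None else _default_grid(dataset)
    grid_model = dataset.from_hours(grid_hours)
    cross_fn = _latent_cross_fn(structure, model, effect, j, grid_model, derivative)
    mean, cov = _single_moments(structure, _DensePath(structure), hp_all, grid_model, cross_fn)
    _, scale = dataset.time_scale
    if derivative:
        mean, cov = mean * scale, cov * scale**2
    return mean, cov


def fitted_conditional_moments(
    dataset: GrowthDataset,
    model: ModelDef,
    hp_all: dict[str, float],
    factors: dict[str, str],
    batch: str | None = None,
    replicate_curve: int | None = None,
    grid_hours: np.ndarray | None = None,
    derivative: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional (mean, covariance) of a summed condition curve."""
    structure = LikelihoodStructure(dataset, model)
    context = _fitted_context(structure, model, factors, batch, replicate_curve)
    grid_hours = np.asarray(grid_hours, dtype=float) if grid_hours is not None else _default_grid(dataset)
    grid_model = dataset.from_hours(grid_hours)
    cross_fn = _fitted_cross_fn(structure, model, context, grid_model, derivative)
    mean, cov = _single_moments(structure, _DensePath(structure), hp_all, grid_model, cross_fn)
    _, scale = dataset.time_scale
    if derivative:
        mean, cov = mean * scale, cov * scale**2
    return mean, cov


def latent_function_posterior(
    dataset: GrowthDataset,
    model: ModelDef,
    samples: PosteriorSamples,
    effect: str,
    level=None,
    batch=None,
    grid_hours: np.ndarray | None = None,
    derivative: bool = False,
    max_draws: int = 500,
    seed: int = 0,
) -> FunctionPosterior:
    """Posterior of one latent function (optionally its time derivative).

    ``effect`` names the group (``mean``, ``treatment``,
    ``treatment_batch``, ...); ``level``/``batch`` pick the latent
    function within it (e.g. ``level="low"``, or ``batch="b2"`` for a
    batch twin).  An effect with no incidence on any observation simply
    returns its GP prior (mean zero).
    """
    structure = LikelihoodStructure(dataset, model)
    j = _resolve_latent(structure, effect, level, batch)
    grid_hours = np.asarray(grid_hours, dtype=float) if grid_hours is not None else _default_grid(dataset)
    grid_model = dataset.from_hours(grid_hours)
    _, scale = dataset.time_scale
    cross_fn = _latent_cross_fn(structure, model, effect, j, grid_model, derivative)
    draws = _conditional_draws(structure, samples, grid_model, cross_fn, max_draws, seed)
    if derivative:
        draws = draws * scale  # model-time derivative -> per hour
    label = effect if level is None else f"{effect}[{level}]"
    if batch is not None:
        label += f"@{batch}"
    return FunctionPosterior(grid=grid_hours, draws=draws, effect=label, derivative=derivative)


def fitted_curve_posterior(
    dataset: GrowthDataset,
    model: ModelDef,
    samples: PosteriorSamples,
    factors: dict[str, str],
    batch: str | None = None,
    replicate_curve: int | None = None,
    grid_hours: np.ndarray | None = None,
    derivative: bool = False,
    max_draws: int = 500,
    seed: int = 0,
) -> FunctionPosterior:
    """Posterior of the summed latent curve for one condition context.

    The context is the set of latent functions a hypothetical curve with
    the given factor levels (and optionally batch / curve index for
    random effects) would carry; the fitted curve is their sum.
    """
    structure = LikelihoodStructure(dataset, model)
    context = _fitted_context(structure, model, factors, batch, replicate_curve)
    grid_hours = np.asarray(grid_hours, dtype=float) if grid_hours is not None else _default_grid(dataset)
    grid_model = dataset.from_hours(grid_hours)
    _, scale = dataset.time_scale
    cross_fn = _fitted_cross_fn(structure, model, context, grid_model, derivative)
    draws = _conditional_draws(structure, samples, grid_model, cross_fn, max_draws, seed)
    if derivative:
        draws = draws * scale
    label = "fitted[" + ",".join(f"{k}={v}" for k, v in factors.items()) + "]"
    return FunctionPosterior(grid=grid_hours, draws=draws, effect=label, derivative=derivative)


def credible_band(fp: FunctionPosterior, level: float = 0.95) -> CredibleBand:
    """Pointwise central credible band at the given probability level."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"credible level must be in (0, 1), got {level}")
    a = (1.0 - level) / 2.0
    lower = np.quantile(fp.draws, a, axis=0)
    upper = np.quantile(fp.draws, 1.0 - a, axis=0)
    return CredibleBand(
        grid=fp.grid,
        lower=lower,
        mean=fp.draws.mean(axis=0),
        upper=upper,
        level=level,
        effect=fp.effect,
    )


def significant_intervals(
    band: CredibleBand, reference: float = 0.0
) -> list[tuple[float, float, str]]:
    """Maximal grid runs where the band excludes ``reference``.

    Returns (t_start, t_end, sign) triples in hours; endpoints snap to
    grid points.  Sign is '+' where the whole band lies above the
    reference and '-' where below.
    """
    sign = np.where(band.lower > reference, 1, np.where(band.upper < reference, -1, 0))
    out = []
    start = None
    for i, s in enumerate(sign):
        if s != 0 and (start is None or s != current):
            if start is not None:
                out.append((band.grid[start], band.grid[i - 1], "+" if current > 0 else "-"))
            start, current = i, s
        elif s == 0 and start is not None:
            out.append((band.grid[start], band.grid[i - 1], "+" if current > 0 else "-"))
            start = None
    if start is not None:
        out.append((band.grid[start], band.grid[-1], "+" if current > 0 else "-"))
    return out


@dataclass
class VarianceComponentTable:
    """Posterior draws and summaries of the variance components.

    Components mirror the model's effect grouping: the mean curve, each
    treatment/fixed group, batch effects (pooled by summing kernel
    variances across batch groups, or kept separate), replicate-level
    variability ("biological") and measurement noise.
    """

    draws: dict[str, np.ndarray]
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        rows = []
        for name, d in self.draws.items():
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append(
                {
                    "component": name,
                    "mean": float(np.mean(d)),
                    "q2.5": float(lo),
                    "q97.5": float(hi),
                }
            )
        self.summary = pd.DataFrame(rows)


def variance_components(
    samples: PosteriorSamples, model: ModelDef, pool_batch_components: bool = True
) -> VarianceComponentTable:
    """Kernel-variance posteriors per effect group, plus noise.

    Batch groups are pooled into a single "batch" component by summing
    their per-draw variances (independent additive effects) unless
    ``pool_batch_components`` is False.
    """
    draws: dict[str, np.ndarray] = {}
    batch_sum = None
    for g in model.groups:
        d = samples.draws_for(f"{g.name}.variance").ravel()
        if g.batch_indexed and pool_batch_components:
            batch_sum = d.copy() if batch_sum is None else batch_sum + d
        elif g.curve_indexed:
            draws["biological"] = d
        else:
            draws[g.name] = d
    if batch_sum is not None:
        draws["batch"] = batch_sum
    draws["noise"] = samples.draws_for("noise.variance").ravel()
    return VarianceComponentTable(draws=draws)
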