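"""Posterior sampling of kernel hyperparameters by NUTS.

All latent functions are marginalized analytically, so the sampler only
explores the low-dimensional space of kernel hyperparameters (one
variance and one lengthscale per effect group, plus the noise
variance).  Sampling runs on log-transformed parameters — positivity by
construction, with the log-Jacobian included in the target — using the
No-U-Turn Sampler (slice variant, with dual-averaging step-size
adaptation and windowed diagonal mass-matrix estimation during warmup).

Convergence is diagnosed with the split potential-scale-reduction
statistic R̂ (each chain halved, between- vs. within-half variance),
without rank normalisation.  Identical seeds and configuration produce
bitwise-identical draws.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GrowthDataset, validate_design
from .likelihood import MarginalLikelihood
from .model import ModelDef, param_names, prior_logpdf_grad, sample_prior

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "InferenceError",
    "sample_posterior",
    "rhat",
    "summarize",
]

_ZMAX = 40.0  # |log parameter| bound; beyond this the target is -inf
_DIVERGENCE_DELTA = 1000.0


class InferenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  Defaults: 4 chains × 1000 warmup × 1000 draws."""

    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10
    fixed_params: dict | None = None

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 1 or self.samples < 1:
            raise ValueError("chains, warmup and samples must all be >= 1")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")


@dataclass
class PosteriorSamples:
    """MCMC draws of all sampled hyperparameters, on the natural scale.

    ``draws`` has shape (chains, iterations, parameters) in the order of
    ``param_names``; parameters held fixed during sampling appear in
    ``fixed`` instead.
    """

    draws: np.ndarray
    param_names: list[str]
    divergences: list[int]
    config: MCMCConfig
    fixed: dict[str, float] = field(default_factory=dict)
    stepsizes: list[float] = field(default_factory=list)
    model_kind: str = ""

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def draws_for(self, name: str) -> np.ndarray:
        if name in self.fixed:
            return np.full(self.draws.shape[:2], self.fixed[name])
        return self.draws[:, :, self.param_names.index(name)]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def thinned(self, max_draws: int) -> np.ndarray:
        """Flattened draws, evenly thinned to at most ``max_draws`` rows."""
        flat = self.flat()
        if len(flat) <= max_draws:
            return flat
        idx = np.linspace(0, len(flat) - 1, max_draws).round().astype(int)
        return flat[idx]

    def to_dataframe(self) -> pd.DataFrame:
        chains, iters, _ = self.draws.shape
        rows = {
            "chain": np.repeat(np.arange(chains), iters * len(self.param_names)),
            "iteration": np.tile(np.repeat(np.arange(iters), len(self.param_names)), chains),
            "parameter": np.tile(self.param_names, chains * iters),
            "value": self.draws.reshape(-1),
        }
        return pd.DataFrame(rows)

    def save_csv(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        # %.17g keeps doubles bit-exact through the round trip
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        if metadata_path is not None:
            meta = {
                "param_names": self.param_names,
                "fixed": self.fixed,
                "divergences": self.divergences,
                "stepsizes": self.stepsizes,
                "model_kind": self.model_kind,
                "config": {
                    k: v for k, v in dataclasses.asdict(self.config).items()
                },
            }
            Path(metadata_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load_csv(cls, path: str | Path, metadata_path: str | Path | None = None):
        df = pd.read_csv(path, float_precision="round_trip")
        names = list(df[df.chain == df.chain.min()].parameter.unique())
        chains = df.chain.nunique()
        iters = df.iteration.nunique()
        draws = np.empty((chains, iters, len(names)))
        for ci, (_, sub) in enumerate(df.groupby("chain")):
            piv = sub.pivot(index="iteration", columns="parameter", values="value")
            draws[ci] = piv[names].to_numpy()
        meta = {}
        if metadata_path is not None:
            meta = json.loads(Path(metadata_path).read_text())
        cfg = MCMCConfig(**meta["config"]) if "config" in meta else MCMCConfig(
            chains=chains, warmup=1, samples=iters
        )
        return cls(
            draws=draws,
            param_names=names,
            divergences=meta.get("divergences", [0] * chains),
            config=cfg,
            fixed=meta.get("fixed", {}),
            stepsizes=meta.get("stepsizes", []),
            model_kind=meta.get("model_kind", ""),
        )

    def to_arviz(self):
        import arviz as az

        return az.from_dict(
            posterior={
                n: self.draws[:, :, i] for i, n in enumerate(self.param_names)
            }
        )


# ------------------------------------------------------------------ target

class _LogPosterior:
    """Log posterior and gradient in z = log(theta) for the free parameters."""

    def __init__(self, dataset, model, fixed: dict[str, float]):
        self.ml = MarginalLikelihood(dataset, model)
        self.model = model
        self.names = param_names(model)
        unknown = set(fixed) - set(self.names)
        if unknown:
            raise InferenceError(f"fixed_params refer to unknown parameters {sorted(unknown)}")
        self.free = [i for i, n in enumerate(self.names) if n not in fixed]
        if not self.free:
            raise InferenceError("all parameters fixed; nothing to sample")
        self.template = np.empty(len(self.names))
        for i, n in enumerate(self.names):
            if n in fixed:
                if not fixed[n] > 0:
                    raise InferenceError(f"fixed value for {n} must be positive")
                self.template[i] = fixed[n]
        self.dim = len(self.free)

    def __call__(self, z: np.ndarray) -> tuple[float, np.ndarray | None]:
        if np.any(np.abs(z) > _ZMAX) or not np.all(np.isfinite(z)):
            return -math.inf, None
        theta = self.template.copy()
        theta[self.free] = np.exp(z)
        try:
            ll, gll = self.ml.value_and_grad(theta)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return -math.inf, None
        lp, gp = prior_logpdf_grad(theta, self.model)
        logpost = ll + lp + float(np.sum(z))
        if not np.isfinite(logpost):
            return -math.inf, None
        grad = (gll + gp)[self.free] * theta[self.free] + 1.0
        return logpost, grad


# ------------------------------------------------------------------ NUTS

def _leapfrog(target, z, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    z1 = z + eps * inv_mass * r1
    lp1, grad1 = target(z1)
    if grad1 is None:
        return z1, r1, lp1, None
    r1 = r1 + 0.5 * eps * grad1
    return z1, r1, lp1, grad1


def _joint(lp, r, inv_mass):
    return lp - 0.5 * float(np.sum(inv_mass * r * r))


class _Tree:
    __slots__ = (
        "z_minus", "r_minus", "g_minus", "z_plus", "r_plus", "g_plus",
        "z_prop", "lp_prop", "g_prop", "n_valid", "keep_going", "divergent",
        "alpha", "n_alpha",
    )


def _build_tree(target, rng, z, r, grad, logu, direction, depth, eps, inv_mass, joint0):
    tree = _Tree()
    if depth == 0:
        z1, r1, lp1, g1 = _leapfrog(target, z, r, grad, direction * eps, inv_mass)
        joint = _joint(lp1, r1, inv_mass) if g1 is not None else -math.inf
        tree.z_minus = tree.z_plus = tree.z_prop = z1
        tree.r_minus = tree.r_plus = r1
        tree.g_minus = tree.g_plus = tree.g_prop = g1
        tree.lp_prop = lp1
        tree.n_valid = int(logu <= joint)
        tree.divergent = not (logu < joint + _DIVERGENCE_DELTA)
        tree.keep_going = not tree.divergent
        tree.alpha = min(1.0, math.exp(min(0.0, joint - joint0)))
        tree.n_alpha = 1
        return tree
    first = _build_tree(target, rng, z, r, grad, logu, direction, depth - 1, eps, inv_mass, joint0)
    tree = first
    if first.keep_going:
        if direction == -1:
            second = _build_tree(
                target, rng, first.z_minus, first.r_minus, first.g_minus,
                logu, direction, depth - 1, eps, inv_mass, joint0,
            )
            first.z_minus, first.r_minus, first.g_minus = (
                second.z_minus, second.r_minus, second.g_minus,
            )
        else:
            second = _build_tree(
                target, rng, first.z_plus, first.r_plus, first.g_plus,
                logu, direction, depth - 1, eps, inv_mass, joint0,
            )
            first.z_plus, first.r_plus, first.g_plus = (
                second.z_plus, second.r_plus, second.g_plus,
            )
        total = first.n_valid + second.n_valid
        if total > 0 and rng.random() < second.n_valid / total:
            first.z_prop = second.z_prop
            first.lp_prop = second.lp_prop
            first.g_prop = second.g_prop
        first.alpha += second.alpha
        first.n_alpha += second.n_alpha
        first.n_valid = total
        first.divergent = first.divergent or second.divergent
        first.keep_going = (
            second.keep_going
            and _no_uturn(first.z_minus, first.z_plus, first.r_minus, first.r_plus, inv_mass)
        )
    return first


def _no_uturn(z_minus, z_plus, r_minus, r_plus, inv_mass):
    dz = z_plus - z_minus
    return (float(dz @ (inv_mass * r_minus)) >= 0.0) and (
        float(dz @ (inv_mass * r_plus)) >= 0.0
    )


def _nuts_step(target, rng, z, lp, grad, eps, inv_mass, max_depth):
    r0 = rng.standard_normal(len(z)) / np.sqrt(inv_mass)
    joint0 = _joint(lp, r0, inv_mass)
    logu = joint0 - rng.exponential()
    z_minus = z_plus = z
    r_minus = r_plus = r0
    g_minus = g_plus = grad
    z_new, lp_new, g_new = z, lp, grad
    n_valid = 1
    depth = 0
    divergent = False
    alpha_sum, n_alpha = 0.0, 0
    while depth < max_depth:
        direction = -1 if rng.random() < 0.5 else 1
        if direction == -1:
            tree = _build_tree(
                target, rng, z_minus, r_minus, g_minus, logu, -1, depth, eps, inv_mass, joint0
            )
            z_minus, r_minus, g_minus = tree.z_minus, tree.r_minus, tree.g_minus
        else:
            tree = _build_tree(
                target, rng, z_plus, r_plus, g_plus, logu, 1, depth, eps, inv_mass, joint0
            )
            z_plus, r_plus, g_plus = tree.z_plus, tree.r_plus, tree.g_plus
        alpha_sum += tree.alpha
        n_alpha += tree.n_alpha
        if not tree.keep_going:
            divergent = tree.divergent
            break
        if tree.n_valid > 0 and rng.random() < min(1.0, tree.n_valid / n_valid):
            z_new, lp_new, g_new = tree.z_prop, tree.lp_prop, tree.g_prop
        n_valid += tree.n_valid
        if not _no_uturn(z_minus, z_plus, r_minus, r_plus, inv_mass):
            break
        depth += 1
    accept_stat = alpha_sum / max(n_alpha, 1)
    return z_new, lp_new, g_new, accept_stat, divergent


def _find_initial_stepsize(target, rng, z, lp, grad, inv_mass):
    eps = 1.0
    r0 = rng.standard_normal(len(z)) / np.sqrt(inv_mass)
    joint0 = _joint(lp, r0, inv_mass)
    z1, r1, lp1, g1 = _leapfrog(target, z, r0, grad, eps, inv_mass)
    joint1 = _joint(lp1, r1, inv_mass) if g1 is not None else -math.inf
    direction = 1 if joint1 - joint0 > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        z1, r1, lp1, g1 = _leapfrog(target, z, r0, grad, eps, inv_mass)
        joint1 = _joint(lp1, r1, inv_mass) if g1 is not None else -math.inf
        if direction == 1 and joint1 - joint0 <= math.log(0.5):
            break
        if direction == -1 and joint1 - joint0 > math.log(0.5):
            break
    return max(eps, 1e-6)


def _adaptation_schedule(warmup):
    """Stan-style windows: fast start, expanding metric windows, fast end."""
    init_buffer, term_buffer, base_window = 75, 50, 25
    if warmup < init_buffer + term_buffer + base_window:
        init_buffer = max(1, int(0.15 * warmup))
        term_buffer = max(1, int(0.10 * warmup))
        base_window = max(1, warmup - init_buffer - term_buffer)
    boundaries = []
    start = init_buffer
    window = base_window
    while start + window < warmup - term_buffer:
        next_window = window * 2
        if start + window + next_window >= warmup - term_buffer:
            window = warmup - term_buffer - start
        boundaries.append(start + window)
        start += window
        window *= 2
    if start < warmup - term_buffer:
        boundaries.append(warmup - term_buffer)
    return init_buffer, boundaries


def _run_chain(target, cfg, rng):
    # initialize from the prior (seed-controlled), retry on non-finite target
    z = lp = grad = None
    for _ in range(100):
        hp0 = sample_prior(target.model, rng)
        theta0 = np.array([hp0[n] for n in target.names])
        z0 = np.log(theta0[target.free])
        lp0, g0 = target(z0)
        if np.isfinite(lp0):
            z, lp, grad = z0, lp0, g0
            break
    if z is None:
        raise InferenceError("non-finite posterior at initialization after 100 retries")

    inv_mass = np.ones(target.dim)
    eps = _find_initial_stepsize(target, rng, z, lp, grad, inv_mass)

    # dual averaging state
    def reset_da(eps0):
        return {"mu": math.log(10.0 * eps0), "log_eps_bar": 0.0, "h_bar": 0.0, "count": 0}

    da = reset_da(eps)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    delta = cfg.target_accept

    init_buffer, boundaries = _adaptation_schedule(cfg.warmup)
    window_draws = []
    divergences = 0
    draws = np.empty((cfg.samples, target.dim))

    for it in range(cfg.warmup + cfg.samples):
        warm = it < cfg.warmup
        z, lp, grad, accept, div = _nuts_step(
            target, rng, z, lp, grad, eps, inv_mass, cfg.max_treedepth
        )
        if warm:
            da["count"] += 1
            frac = 1.0 / (da["count"] + t0)
            da["h_bar"] = (1 - frac) * da["h_bar"] + frac * (delta - accept)
            log_eps = da["mu"] - math.sqrt(da["count"]) / gamma * da["h_bar"]
            w = da["count"] ** -kappa
            da["log_eps_bar"] = w * log_eps + (1 - w) * da["log_eps_bar"]
            eps = math.exp(log_eps)
            if it >= init_buffer:
                window_draws.append(z.copy())
            if (it + 1) in boundaries and len(window_draws) > 1:
                arr = np.asarray(window_draws)
                n = len(arr)
                var = arr.var(axis=0, ddof=1)
                inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                window_draws = []
                eps = _find_initial_stepsize(target, rng, z, lp, grad, inv_mass)
                da = reset_da(eps)
            if it == cfg.warmup - 1:
                eps = math.exp(da["log_eps_bar"])
        else:
            if div:
                divergences += 1
            draws[it - cfg.warmup] = z
    return np.exp(draws), divergences, eps


def sample_posterior(
    dataset: GrowthDataset, model: ModelDef, cfg: MCMCConfig | None = None
) -> PosteriorSamples:
    """Draw from the hyperparameter posterior ∝ prior × marginal likelihood.

    Runs ``cfg.chains`` independent NUTS chains (sequentially; identical
    seed and config give identical draws) and reports divergence counts.
    A loud warning is emitted if divergences exceed 1 % of draws or the
    design validation reports errors.
    """
    cfg = cfg or MCMCConfig()
    report = validate_design(dataset, model.kind)
    if not report.ok:
        raise InferenceError("design validation failed: " + "; ".join(report.errors))
    fixed = dict(cfg.fixed_params or {})
    target = _LogPosterior(dataset, model, fixed)
    free_names = [target.names[i] for i in target.free]

    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    all_draws = np.empty((cfg.chains, cfg.samples, target.dim))
    divergences, stepsizes = [], []
    for ci, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        chain_draws, ndiv, eps = _run_chain(target, cfg, rng)
        all_draws[ci] = chain_draws
        divergences.append(ndiv)
        stepsizes.append(eps)
    total_div = sum(divergences)
    if total_div > 0.01 * cfg.chains * cfg.samples:
        warnings.warn(
            f"{total_div} divergent transitions "
            f"({100 * total_div / (cfg.chains * cfg.samples):.1f}% of draws); "
            "posterior geometry may be poorly explored",
            stacklevel=2,
        )
    return PosteriorSamples(
        draws=all_draws,
        param_names=free_names,
        divergences=divergences,
        config=cfg,
        fixed=fixed,
        stepsizes=stepsizes,
        model_kind=model.kind,
    )


# ------------------------------------------------------------- diagnostics

def _split_rhat(chains_by_iters: np.ndarray) -> float:
    m, n = chains_by_iters.shape
    half = n // 2
    if half < 2:
        raise InferenceError("split R-hat needs >= 4 iterations per chain")
    halves = np.concatenate(
        [chains_by_iters[:, :half], chains_by_iters[:, half : 2 * half]], axis=0
    )
    within = halves.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0:
        warnings.warn("zero within-chain variance; R-hat undefined", stacklevel=3)
        return math.nan
    b_over_n = halves.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b_over_n
    return float(math.sqrt(var_plus / w))


def rhat(samples: PosteriorSamples) -> dict[str, float]:
    """Split potential-scale-reduction per parameter (no rank normalisation)."""
    if samples.n_chains < 2:
        raise InferenceError("R-hat requires >= 2 chains")
    return {
        name: _split_rhat(samples.draws[:, :, i])
        for i, name in enumerate(samples.param_names)
    }


def summarize(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean, sd, central 95% interval, R̂ and effective sample size."""
    import arviz as az

    rh = rhat(samples)
    idata = samples.to_arviz()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(idata)
    rows = []
    for i, name in enumerate(samples.param_names):
        d = samples.draws[:, :, i].ravel()
        lo, hi = np.quantile(d, [0.025, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
                "q2.5": float(lo),
                "q97.5": float(hi),
                "rhat": rh[name],
                "ess": float(ess[name].values),
            }
        )
    return pd.DataFrame(rows)
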