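"""Model definitions for the hierarchical GP mixed-effects growth model.

Three nested models are supported.  M_null contains only fixed
functional effects: a grand mean m(t) plus, depending on the design,
either per-level treatment deltas δ(t) (``single_treatment``) or a
functional-ANOVA decomposition m + α_p + β_c + (αβ)_{p,c}
(``two_factor_interaction``).  M_batch adds, for every fixed-effect
group, a batch-indexed random twin drawn from its own GP (one latent
function per fixed-effect function per batch).  M_full additionally
adds a replicate-level GP per curve, capturing smooth replicate-specific
deviations on top of white measurement noise.

All latent functions in a group share one RBF kernel (σ², ℓ).  Kernel
variances carry Gamma priors — Gamma(10, 10) for fixed effects and
Gamma(7, 10) for random effects (shape–rate) — and lengthscales carry
inverse-Gamma priors with organism presets.  Identifiability uses corner
constraints: reference levels carry zero effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data import GrowthDataset
from .kernels import DIALECTS

__all__ = [
    "PriorSpec",
    "EffectGroup",
    "ModelDef",
    "DesignError",
    "build_model",
    "prior_logpdf",
    "marginal_loglik",
    "param_names",
    "pack_params",
    "unpack_params",
    "LENGTHSCALE_PRESETS",
]

MODEL_KINDS = ("M_null", "M_batch", "M_full")
STRUCTURES = ("single_treatment", "two_factor_interaction")

# lengthscale prior presets: (fixed-effect spec, random-effect spec)
LENGTHSCALE_PRESETS = {
    "halobacterium": (("inverse_gamma", 6.0, 1.0), ("inverse_gamma", 6.0, 1.0)),
    "pseudomonas": (("inverse_gamma", 2.0, 3.0), ("inverse_gamma", 10.0, 1.0)),
}

DEFAULT_FIXED_VARIANCE = ("gamma", 10.0, 10.0)
DEFAULT_RANDOM_VARIANCE = ("gamma", 7.0, 10.0)
DEFAULT_NOISE = ("gamma", 1.0, 10.0)


class DesignError(ValueError):
    """Dataset design incompatible with the requested model structure."""


@dataclass(frozen=True)
class PriorSpec:
    """A Gamma or inverse-Gamma prior, shape–rate/scale parameterized.

    ``gamma``: p(x) ∝ x^(α−1) e^(−βx) (β is a rate, Stan convention).
    ``inverse_gamma``: p(x) ∝ x^(−α−1) e^(−β/x) (β is a scale).
    """

    family: str
    shape: float
    rate: float

    def __post_init__(self):
        if self.family not in ("gamma", "inverse_gamma"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError("prior shape and rate must be positive")

    def logpdf(self, x: float) -> float:
        if x <= 0 or not np.isfinite(x):
            return -math.inf
        a, b = self.shape, self.rate
        if self.family == "gamma":
            return a * math.log(b) - math.lgamma(a) + (a - 1) * math.log(x) - b * x
        return a * math.log(b) - math.lgamma(a) - (a + 1) * math.log(x) - b / x

    def dlogpdf(self, x: float) -> float:
        a, b = self.shape, self.rate
        if self.family == "gamma":
            return (a - 1) / x - b
        return -(a + 1) / x + b / x**2

    def mean(self) -> float:
        if self.family == "gamma":
            return self.shape / self.rate
        if self.shape <= 1:
            return math.inf
        return self.rate / (self.shape - 1)

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "gamma":
            return float(rng.gamma(self.shape, 1.0 / self.rate))
        return float(self.rate / rng.gamma(self.shape, 1.0))

    @classmethod
    def from_tuple(cls, spec) -> "PriorSpec":
        if isinstance(spec, PriorSpec):
            return spec
        if len(spec) == 2:  # (shape, rate) shorthand for gamma
            return cls("gamma", float(spec[0]), float(spec[1]))
        return cls(str(spec[0]), float(spec[1]), float(spec[2]))


@dataclass(frozen=True)
class EffectGroup:
    """One family of latent functions sharing a kernel and its priors.

    ``factors`` names the factor subset indexing distinct latent
    functions within the group (empty for the grand mean);
    ``batch_indexed`` marks batch random twins; ``curve_indexed`` marks
    the M_full replicate group (one latent per curve).
    """

    name: str
    kind: str  # fixed | random
    factors: tuple[str, ...]
    batch_indexed: bool = False
    curve_indexed: bool = False
    variance_prior: PriorSpec = field(
        default_factory=lambda: PriorSpec.from_tuple(DEFAULT_FIXED_VARIANCE)
    )
    lengthscale_prior: PriorSpec = field(
        default_factory=lambda: PriorSpec.from_tuple(("inverse_gamma", 6.0, 1.0))
    )

    def __post_init__(self):
        if self.kind not in ("fixed", "random"):
            raise ValueError(f"effect kind must be fixed/random, got {self.kind!r}")
        if self.kind == "fixed" and self.batch_indexed:
            raise ValueError("fixed groups are never batch indexed")


@dataclass(frozen=True)
class ModelDef:
    """A full model: ordered effect groups + noise specification."""

    kind: str
    structure: str
    groups: tuple[EffectGroup, ...]
    noise_prior: PriorSpec
    reference_levels: dict[str, str]
    factor_levels: dict[str, list[str]]
    kernel_dialect: str = "as_printed"

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"model kind must be one of {MODEL_KINDS}")
        if self.kernel_dialect not in DIALECTS:
            raise ValueError(f"unknown kernel dialect {self.kernel_dialect!r}")
        names = [g.name for g in self.groups]
        if names.count("mean") != 1:
            raise ValueError("a model has exactly one 'mean' group")
        if ("replicate" in names) != (self.kind == "M_full"):
            raise ValueError("replicate group exists iff model is M_full")

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    def group(self, name: str) -> EffectGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"no effect group named {name!r}; have {self.group_names}")

    def nonreference_levels(self, factor: str) -> list[str]:
        ref = self.reference_levels[factor]
        return [lv for lv in self.factor_levels[factor] if lv != ref]


def _resolve_priors(priors: dict | None, preset: str):
    priors = dict(priors or {})
    fixed_var = PriorSpec.from_tuple(priors.get("fixed_variance", DEFAULT_FIXED_VARIANCE))
    random_var = PriorSpec.from_tuple(priors.get("random_variance", DEFAULT_RANDOM_VARIANCE))
    noise = PriorSpec.from_tuple(priors.get("noise", DEFAULT_NOISE))
    preset = priors.get("lengthscale_preset", preset)
    if preset not in LENGTHSCALE_PRESETS:
        raise DesignError(
            f"unknown lengthscale preset {preset!r}; choose from {sorted(LENGTHSCALE_PRESETS)}"
        )
    ls_fixed, ls_random = (PriorSpec.from_tuple(s) for s in LENGTHSCALE_PRESETS[preset])
    ls_overrides = {
        k: PriorSpec.from_tuple(v) for k, v in priors.get("lengthscale", {}).items()
    }
    return fixed_var, random_var, noise, ls_fixed, ls_random, ls_overrides


def build_model(
    kind: str,
    dataset: GrowthDataset,
    structure: str,
    priors: dict | None = None,
    reference_levels: dict[str, str] | None = None,
    lengthscale_preset: str = "halobacterium",
    kernel_dialect: str = "as_printed",
) -> ModelDef:
    """Construct an M_null/M_batch/M_full definition from a dataset design.

    ``single_treatment`` expects one factor (groups: mean + treatment);
    ``two_factor_interaction`` expects two (groups: mean, per-factor
    main effects, interaction).  M_batch adds a batch-indexed random
    twin ``<name>_batch`` of every fixed group; M_full additionally adds
    the per-curve ``replicate`` group.
    """
    if kind not in MODEL_KINDS:
        raise DesignError(f"model kind must be one of {MODEL_KINDS}, got {kind!r}")
    if structure not in STRUCTURES:
        raise DesignError(f"structure must be one of {STRUCTURES}, got {structure!r}")
    nf = len(dataset.factor_names)
    want = 1 if structure == "single_treatment" else 2
    if nf != want:
        raise DesignError(
            f"{structure} needs {want} factor(s); dataset has {nf} ({dataset.factor_names})"
        )
    factor_levels = {f: dataset.factor_levels(f) for f in dataset.factor_names}
    refs = {f: factor_levels[f][0] for f in dataset.factor_names}
    if reference_levels:
        for f, lv in reference_levels.items():
            if f not in factor_levels:
                raise DesignError(f"reference level for unknown factor {f!r}")
            if lv not in factor_levels[f]:
                raise DesignError(f"reference level {lv!r} not observed for factor {f!r}")
            refs[f] = lv

    fixed_var, random_var, noise, ls_fixed, ls_random, ls_over = _resolve_priors(
        priors, lengthscale_preset
    )

    def _ls(name, default):
        return ls_over.get(name, default)

    groups: list[EffectGroup] = [
        EffectGroup(
            "mean", "fixed", (), variance_prior=fixed_var,
            lengthscale_prior=_ls("mean", ls_fixed),
        )
    ]
    if structure == "single_treatment":
        f = dataset.factor_names[0]
        groups.append(
            EffectGroup(
                "treatment", "fixed", (f,), variance_prior=fixed_var,
                lengthscale_prior=_ls("treatment", ls_fixed),
            )
        )
    else:
        f1, f2 = dataset.factor_names
        for name, facs in [
            (f"{f1}_main", (f1,)),
            (f"{f2}_main", (f2,)),
            ("interaction", (f1, f2)),
        ]:
            groups.append(
                EffectGroup(
                    name, "fixed", facs, variance_prior=fixed_var,
                    lengthscale_prior=_ls(name, ls_fixed),
                )
            )
    if kind in ("M_batch", "M_full"):
        for g in list(groups):
            name = f"{g.name}_batch"
            groups.append(
                EffectGroup(
                    name, "random", g.factors, batch_indexed=True,
                    variance_prior=random_var, lengthscale_prior=_ls(name, ls_random),
                )
            )
    if kind == "M_full":
        groups.append(
            EffectGroup(
                "replicate", "random", (), curve_indexed=True,
                variance_prior=random_var, lengthscale_prior=_ls("replicate", ls_random),
            )
        )
    return ModelDef(
        kind=kind,
        structure=structure,
        groups=tuple(groups),
        noise_prior=noise,
        reference_levels=refs,
        factor_levels=factor_levels,
        kernel_dialect=kernel_dialect,
    )


# ---------------------------------------------------------------- parameters

def param_names(model: ModelDef) -> list[str]:
    """Canonical parameter order: per group (variance, lengthscale), then noise."""
    names = []
    for g in model.groups:
        names.append(f"{g.name}.variance")
        names.append(f"{g.name}.lengthscale")
    names.append("noise.variance")
    return names


def pack_params(hp_all: dict[str, float], model: ModelDef) -> np.ndarray:
    names = param_names(model)
    missing = [n for n in names if n not in hp_all]
    if missing:
        raise KeyError(f"missing hyperparameters: {missing}")
    return np.array([hp_all[n] for n in names], dtype=float)


def unpack_params(theta: np.ndarray, model: ModelDef) -> dict[str, float]:
    names = param_names(model)
    if len(theta) != len(names):
        raise ValueError(f"expected {len(names)} parameters, got {len(theta)}")
    return {n: float(v) for n, v in zip(names, theta)}


def _param_priors(model: ModelDef) -> list[PriorSpec]:
    priors = []
    for g in model.groups:
        priors.append(g.variance_prior)
        priors.append(g.lengthscale_prior)
    priors.append(model.noise_prior)
    return priors


def prior_logpdf(hp_all: dict[str, float], model: ModelDef) -> float:
    """Sum of log prior densities over all groups' (σ², ℓ) and noise σ_y².

    Returns −inf for any non-positive hyperparameter.
    """
    theta = pack_params(hp_all, model)
    if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
        return -math.inf
    return float(sum(p.logpdf(x) for p, x in zip(_param_priors(model), theta)))


def prior_logpdf_grad(theta: np.ndarray, model: ModelDef) -> float | tuple:
    """(logpdf, gradient wrt natural-scale parameter vector)."""
    priors = _param_priors(model)
    lp = sum(p.logpdf(x) for p, x in zip(priors, theta))
    grad = np.array([p.dlogpdf(x) for p, x in zip(priors, theta)])
    return float(lp), grad


def sample_prior(model: ModelDef, rng: np.random.Generator) -> dict[str, float]:
    priors = _param_priors(model)
    return dict(zip(param_names(model), (p.sample(rng) for p in priors)))


def marginal_loglik(dataset: GrowthDataset, model: ModelDef, hp_all: dict[str, float]) -> float:
    """Log-density of the observations with all latent GPs integrated out.

    The concatenated observation vector is multivariate normal with mean
    zero (the GP prior means are zero) and covariance assembled from the
    model's effect groups; see :mod:`phenom.likelihood`.
    """
    from .likelihood import MarginalLikelihood

    return MarginalLikelihood(dataset, model).value(pack_params(hp_all, model))


def with_kind(model: ModelDef, dataset: GrowthDataset, kind: str) -> ModelDef:
    """Rebuild the same model family with a different kind (nesting helper)."""
    return build_model(
        kind,
        dataset,
        model.structure,
        reference_levels=model.reference_levels,
        kernel_dialect=model.kernel_dialect,
    )
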