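"""RBF covariance functions and their derivative cross-covariances.

The kernel is κ(t, t′) = σ²·exp(−|t − t′|²/ℓ) with the lengthscale ℓ
appearing *un-squared* in the denominator (dialect ``as_printed``, the
package default).  The more common convention
κ = σ²·exp(−|t − t′|²/(2ℓ²)) is available as dialect
``squared_lengthscale``.  Differentiating a GP is a linear operation, so
the instantaneous growth rate d log OD/dt of any latent function is
itself a GP whose covariances with the function are the analytic kernel
derivatives implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "KernelHyperparams",
    "NoiseParams",
    "DIALECTS",
    "rbf_kernel",
    "rbf_derivative_cross",
    "rbf_derivative_kernel",
    "jittered_cholesky",
    "assemble_covariance",
]

DIALECTS = ("as_printed", "squared_lengthscale")


class ParameterError(ValueError):
    """Kernel hyperparameters outside their support."""


@dataclass(frozen=True)
class KernelHyperparams:
    """RBF kernel hyperparameters on the model scale.

    variance : σ², magnitude of function fluctuations (log-OD² units).
    lengthscale : ℓ, smoothness scale in model-time units.
    """

    variance: float
    lengthscale: float

    def __post_init__(self):
        if not (self.variance > 0 and self.lengthscale > 0):
            raise ParameterError(
                f"variance and lengthscale must be positive, got "
                f"({self.variance}, {self.lengthscale})"
            )


@dataclass(frozen=True)
class NoiseParams:
    """White observation-noise variance σ_y²."""

    noise_variance: float

    def __post_init__(self):
        if not self.noise_variance > 0:
            raise ParameterError(f"noise_variance must be positive, got {self.noise_variance}")


def _check(hp: KernelHyperparams, dialect: str):
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown kernel dialect {dialect!r}; choose from {DIALECTS}")


def _sqdist(t1, t2):
    t1 = np.asarray(t1, dtype=float).ravel()
    t2 = np.asarray(t2, dtype=float).ravel()
    if not (np.all(np.isfinite(t1)) and np.all(np.isfinite(t2))):
        raise ParameterError("time vectors must be finite")
    d = t1[:, None] - t2[None, :]
    return d, d * d


def rbf_kernel(t1, t2, hp: KernelHyperparams, dialect: str = "as_printed") -> np.ndarray:
    """Covariance matrix K[i, j] = κ(t1[i], t2[j])."""
    _check(hp, dialect)
    _, d2 = _sqdist(t1, t2)
    if dialect == "as_printed":
        return hp.variance * np.exp(-d2 / hp.lengthscale)
    return hp.variance * np.exp(-d2 / (2.0 * hp.lengthscale**2))


def rbf_derivative_cross(
    t_deriv, t_obs, hp: KernelHyperparams, dialect: str = "as_printed"
) -> np.ndarray:
    """Cross-covariance Cov(f′(t_deriv), f(t_obs)) = ∂κ/∂t evaluated analytically."""
    _check(hp, dialect)
    d, _ = _sqdist(t_deriv, t_obs)
    k = rbf_kernel(t_deriv, t_obs, hp, dialect)
    if dialect == "as_printed":
        return -(2.0 * d / hp.lengthscale) * k
    return -(d / hp.lengthscale**2) * k


def rbf_derivative_kernel(
    t1, t2, hp: KernelHyperparams, dialect: str = "as_printed"
) -> np.ndarray:
    """Covariance of the derivative process, ∂²κ/∂t∂t′."""
    _check(hp, dialect)
    d, d2 = _sqdist(t1, t2)
    k = rbf_kernel(t1, t2, hp, dialect)
    if dialect == "as_printed":
        return (2.0 / hp.lengthscale - 4.0 * d2 / hp.lengthscale**2) * k
    return (1.0 / hp.lengthscale**2 - d2 / hp.lengthscale**4) * k


class FactorizationError(np.linalg.LinAlgError):
    """Covariance not factorizable even after jitter escalation."""


def jittered_cholesky(
    sigma: np.ndarray, base_jitter: float, max_jitter: float | None = None
) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor with escalating diagonal jitter.

    Starts at ``base_jitter`` and escalates ×10 up to ``max_jitter``
    (default 1e4 × base) before raising :class:`FactorizationError`.
    Returns (L, jitter_used).
    """
    if max_jitter is None:
        max_jitter = base_jitter * 1e4
    n = sigma.shape[0]
    jitter = base_jitter
    eye = np.eye(n)
    while True:
        try:
            L = scipy.linalg.cholesky(sigma + jitter * eye, lower=True)
            return L, jitter
        except scipy.linalg.LinAlgError:
            jitter *= 10.0
            if jitter > max_jitter * (1.0 + 1e-12):
                raise FactorizationError(
                    f"covariance not positive definite at jitter {max_jitter:g}"
                ) from None


def assemble_covariance(dataset, model, hp_all) -> np.ndarray:
    """Marginal covariance of the concatenated observation vector.

    Σ = Σ_g Z_g K_g Z_gᵀ + σ_y² I, where Z_g is the 0/1 incidence of
    observations onto the latent functions of effect group g (fixed
    effects: one function per level combination; batch effects: one per
    level × batch; the M_full replicate effect: one per curve).  The
    heavy lifting lives in :mod:`phenom.likelihood`; this is the public
    entry point.
    """
    from .likelihood import LikelihoodStructure

    return LikelihoodStructure(dataset, model).covariance(hp_all)
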