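"""Parametric comparison pipeline: logistic fits, μ_max, KDE, t-tests.

The logistic growth model serves as the conventional baseline against
which the non-parametric analysis is judged.  We adopt the grofit
parameterization

    y(t) = A / (1 + exp(4·μ_max·(λ − t)/A + 2)),

in which A is the carrying capacity (in the units of y), μ_max the
maximum instantaneous growth rate (units of y per hour; it equals the
maximal slope of the curve by construction) and λ the lag time (hours,
the intercept of the tangent at the inflexion with the time axis).
This follows the external convention of the grofit R package; only the
model form and least-squares objective are reproduced, not grofit's
internal multi-start heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .data import GrowthCurve, GrowthDataset

__all__ = [
    "LogisticFit",
    "FitError",
    "logistic_curve",
    "fit_logistic",
    "fit_mse_by_condition",
    "kde",
    "compare_mu_max",
]


class FitError(RuntimeError):
    pass


class KDEError(ValueError):
    pass


@dataclass(frozen=True)
class LogisticFit:
    A: float
    mu_max: float
    lam: float
    mse: float
    converged: bool = True

    def __post_init__(self):
        if self.mse < 0:
            raise ValueError("mse must be non-negative")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return logistic_curve(np.asarray(t, dtype=float), self.A, self.mu_max, self.lam)


def logistic_curve(t, A, mu_max, lam):
    z = 4.0 * mu_max * (lam - t) / A + 2.0
    return A / (1.0 + np.exp(np.clip(z, -500, 500)))


def _initial_guesses(t, y):
    """Data-derived starts: capacity from max y, slope from the steepest
    secant, lag from the tangent intercept; plus jittered variants."""
    a0 = max(float(np.max(y)), 1e-6)
    dy = np.diff(y) / np.diff(t)
    i = int(np.argmax(dy))
    mu0 = max(float(dy[i]), 1e-6)
    t_i = 0.5 * (t[i] + t[i + 1])
    y_i = 0.5 * (y[i] + y[i + 1])
    lam0 = t_i - y_i / mu0
    starts = [(a0, mu0, lam0)]
    for fa, fm, dl in [(1.2, 0.5, 0.0), (0.8, 2.0, 0.0), (1.0, 1.0, -0.5 * abs(lam0) - 1.0)]:
        starts.append((a0 * fa, mu0 * fm, lam0 + dl))
    return starts


def fit_logistic(curve: GrowthCurve | tuple) -> LogisticFit:
    """Nonlinear least-squares logistic fit of one curve.

    Accepts a :class:`GrowthCurve` or a (times, values) pair of arrays;
    multi-starts from data-derived initial guesses and returns the best
    fit by MSE.  Raises :class:`FitError` only if every start fails to
    produce finite parameters.
    """
    if isinstance(curve, GrowthCurve):
        t, y = curve.times, curve.values
    else:
        t, y = (np.asarray(a, dtype=float) for a in curve)
    if len(t) < 4:
        raise FitError(f"need >= 4 points for a 3-parameter fit, got {len(t)}")

    best = None
    errors = []
    for start in _initial_guesses(t, y):
        try:
            res = scipy.optimize.least_squares(
                lambda p: logistic_curve(t, *p) - y,
                x0=start,
                bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                method="trf",
                max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failures
            errors.append(str(exc))
            continue
        if not np.all(np.isfinite(res.x)):
            errors.append("non-finite parameters")
            continue
        mse = float(np.mean(res.fun**2))
        if best is None or mse < best[0]:
            best = (mse, res.x, bool(res.success))
    if best is None:
        raise FitError("logistic fit failed from all starts: " + "; ".join(errors))
    mse, (a, mu, lam), success = best
    return LogisticFit(A=float(a), mu_max=float(mu), lam=float(lam), mse=mse, converged=success)


def fit_mse_by_condition(dataset: GrowthDataset) -> pd.DataFrame:
    """Per-curve logistic MSE grouped by condition, with quartile summaries.

    Returns a long table (condition, batch, replicate, mse, A, mu_max,
    lam, converged); quartiles are available via ``groupby('condition')
    .mse.quantile``.
    """
    rows = []
    for c in dataset.curves:
        cond = "/".join(c.factors[f] for f in dataset.factor_names) or "(none)"
        fit = fit_logistic((dataset.times_hours(c), c.values))
        rows.append(
            {
                "condition": cond,
                "batch": c.batch,
                "replicate": c.replicate,
                "mse": fit.mse,
                "A": fit.A,
                "mu_max": fit.mu_max,
                "lam": fit.lam,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def kde(values, grid=None, n_grid: int = 512):
    """Gaussian KDE with Scott's-rule bandwidth (n^(−1/5) · sd).

    Returns (grid, density); the density integrates to 1 on a wide grid.
    """
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise KDEError("KDE needs at least 2 distinct values")
    k = scipy.stats.gaussian_kde(values)  # default bw_method is Scott's rule
    if grid is None:
        sd = values.std(ddof=1)
        grid = np.linspace(values.min() - 4 * sd, values.max() + 4 * sd, n_grid)
    return grid, k(grid)


def compare_mu_max(group_a, group_b, alternative: str = "greater"):
    """One-sided Welch t-test of μ_max between two groups.

    ``alternative='greater'`` tests mean(a) > mean(b).  Returns
    (t statistic, p-value).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    res = scipy.stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
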