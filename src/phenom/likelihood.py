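"""Marginal likelihood of the growth model with latent GPs integrated out.

Given kernel hyperparameters, every latent function is Gaussian, so the
concatenated observation vector y is multivariate normal with mean zero
and covariance

    Σ = Σ_g Z_g K_g Z_gᵀ + σ_y² I,

where Z_g is the 0/1 incidence of observations onto the latent
functions of effect group g and K_g is the group's RBF kernel evaluated
at the observation times.  Sampling therefore only has to explore the
small hyperparameter space.

Two evaluation paths compute identical values:

* a dense path over the full N×N covariance, valid for arbitrary
  (unequal) time grids; and
* an exchangeable-replicate collapse.  Curves that share a time grid
  and the same latent-function assignment in every non-curve-specific
  group (i.e. replicates of one condition within one batch) are
  exchangeable: rotating each cell by an orthonormal basis whose first
  vector is the normalized mean splits the likelihood into a small MVN
  over scaled cell means plus i.i.d. residual contrast terms.  This is
  an exact sufficient-statistic reduction, not an approximation, and
  cuts the Cholesky cost by the cube of the replicate count.

A diagonal jitter of 1e-8·σ_y² is always included for numerical
stability (escalated ×10 on factorization failure, up to 1e-4).
"""

from __future__ import annotations

import math

import numpy as np
import scipy.linalg

from .data import GrowthDataset, DesignIndex
from .kernels import jittered_cholesky
from .model import ModelDef, param_names

__all__ = ["LikelihoodStructure", "MarginalLikelihood"]

BASE_JITTER_REL = 1e-8
MAX_JITTER = 1e-4
LOG2PI = math.log(2.0 * math.pi)


class StructureError(ValueError):
    """Dataset and model are structurally incompatible."""


def _kernel_mats(d2, variance, lengthscale, dialect):
    """K and ∂K/∂ℓ for a squared-distance matrix."""
    if dialect == "as_printed":
        k = variance * np.exp(-d2 / lengthscale)
        dk_dl = k * d2 / lengthscale**2
    else:
        k = variance * np.exp(-d2 / (2.0 * lengthscale**2))
        dk_dl = k * d2 / lengthscale**3
    return k, dk_dl


class LikelihoodStructure:
    """Incidence bookkeeping between observations and latent functions."""

    def __init__(self, dataset: GrowthDataset, model: ModelDef):
        for f in model.factor_levels:
            if f not in dataset.factor_names:
                raise StructureError(f"model factor {f!r} not present in dataset")
        self.dataset = dataset
        self.model = model
        self.design = DesignIndex.from_dataset(dataset)
        self.curves = dataset.curves
        n_curves = len(self.curves)
        self.t_all = np.concatenate([c.times for c in self.curves])
        self.y_all = np.concatenate([c.values for c in self.curves])
        self.n_obs = len(self.t_all)
        self.curve_of_obs = np.concatenate(
            [np.full(c.n_obs, i, dtype=int) for i, c in enumerate(self.curves)]
        )
        self.obs_slices = []
        start = 0
        for c in self.curves:
            self.obs_slices.append(slice(start, start + c.n_obs))
            start += c.n_obs

        batches = dataset.batches
        # latent functions per group: (label tuple, boolean curve mask)
        self.latents: dict[str, list[tuple[tuple, np.ndarray]]] = {}
        # per curve, index of the latent it carries in each group (-1: none)
        self.curve_latent_id: dict[str, np.ndarray] = {}
        for g in model.groups:
            if g.curve_indexed:
                lat = [
                    ((f"curve{i}",), np.arange(n_curves) == i) for i in range(n_curves)
                ]
            else:
                base = self._base_latents(g)
                if g.batch_indexed:
                    lat = []
                    for lab, mask in base:
                        for b in batches:
                            bmask = np.array([c.batch == b for c in self.curves])
                            lat.append((lab + (b,), mask & bmask))
                else:
                    lat = base
            self.latents[g.name] = lat
            ids = np.full(n_curves, -1, dtype=int)
            for j, (_, mask) in enumerate(lat):
                if np.any(ids[mask] >= 0):
                    raise StructureError(
                        f"group {g.name!r}: a curve maps to two latent functions"
                    )
                ids[mask] = j
            self.curve_latent_id[g.name] = ids

    def _base_latents(self, g):
        model = self.model
        n_curves = len(self.curves)
        if not g.factors:
            return [((), np.ones(n_curves, dtype=bool))]
        if len(g.factors) == 1:
            f = g.factors[0]
            return [
                ((lv,), np.array([c.factors[f] == lv for c in self.curves]))
                for lv in model.nonreference_levels(f)
            ]
        f1, f2 = g.factors
        out = []
        for lv1 in model.nonreference_levels(f1):
            for lv2 in model.nonreference_levels(f2):
                mask = np.array(
                    [c.factors[f1] == lv1 and c.factors[f2] == lv2 for c in self.curves]
                )
                out.append(((lv1, lv2), mask))
        return out

    def curve_share_matrix(self, group_name: str) -> np.ndarray:
        """Boolean C×C matrix: curves i, j share a latent function of the group."""
        ids = self.curve_latent_id[group_name]
        share = (ids[:, None] == ids[None, :]) & (ids[:, None] >= 0)
        return share

    def covariance(self, hp_all, with_jitter: bool = False) -> np.ndarray:
        """Dense Σ over the concatenated observation vector."""
        theta = self._as_theta(hp_all)
        return _DensePath(self).sigma(theta, with_jitter=with_jitter)

    def _as_theta(self, hp_all) -> np.ndarray:
        if isinstance(hp_all, dict):
            from .model import pack_params

            return pack_params(hp_all, self.model)
        return np.asarray(hp_all, dtype=float)


class _DensePath:
    def __init__(self, structure: LikelihoodStructure):
        s = self.s = structure
        d = s.t_all[:, None] - s.t_all[None, :]
        self.d2 = d * d
        self.masks = []
        for g in s.model.groups:
            share = s.curve_share_matrix(g.name)
            self.masks.append(share[s.curve_of_obs][:, s.curve_of_obs])
        self.eye = np.eye(s.n_obs)

    def sigma(self, theta, with_jitter=True):
        s = self.s
        noise = theta[-1]
        sigma = np.zeros((s.n_obs, s.n_obs))
        for gi in range(len(s.model.groups)):
            k, _ = _kernel_mats(
                self.d2, theta[2 * gi], theta[2 * gi + 1], s.model.kernel_dialect
            )
            sigma += self.masks[gi] * k
        eff = noise * (1.0 + BASE_JITTER_REL) if with_jitter else noise
        sigma[np.diag_indices_from(sigma)] += eff
        return sigma

    def value_and_grad(self, theta, want_grad=True):
        s = self.s
        sigma = self.sigma(theta)
        try:
            L = scipy.linalg.cholesky(sigma, lower=True)
        except scipy.linalg.LinAlgError:
            L, _ = jittered_cholesky(sigma, BASE_JITTER_REL * theta[-1], MAX_JITTER)
        alpha = scipy.linalg.cho_solve((L, True), s.y_all)
        ll = (
            -0.5 * float(s.y_all @ alpha)
            - float(np.sum(np.log(np.diag(L))))
            - 0.5 * s.n_obs * LOG2PI
        )
        if not want_grad:
            return ll, None
        sigma_inv = scipy.linalg.cho_solve((L, True), np.eye(s.n_obs))
        a_mat = sigma_inv - np.outer(alpha, alpha)
        grad = np.zeros_like(theta)
        for gi in range(len(s.model.groups)):
            var, ls = theta[2 * gi], theta[2 * gi + 1]
            k, dk_dl = _kernel_mats(self.d2, var, ls, s.model.kernel_dialect)
            mk = self.masks[gi] * k
            grad[2 * gi] = -0.5 * float(np.sum(a_mat * mk)) / var
            grad[2 * gi + 1] = -0.5 * float(np.sum(a_mat * (self.masks[gi] * dk_dl)))
        grad[-1] = -0.5 * float(np.trace(a_mat)) * (1.0 + BASE_JITTER_REL)
        return ll, grad


class _CollapsedPath:
    """Cell-means MVN plus within-cell residual contrast terms."""

    def __init__(self, structure: LikelihoodStructure):
        s = self.s = structure
        model = s.model
        self.shared_idx = [
            gi for gi, g in enumerate(model.groups) if not g.curve_indexed
        ]
        self.replicate_idx = [
            gi for gi, g in enumerate(model.groups) if g.curve_indexed
        ]

        # cells: curves with identical grids and identical shared-latent ids
        cells: dict[tuple, list[int]] = {}
        for i, c in enumerate(s.curves):
            key = (
                c.times.tobytes(),
                tuple(s.curve_latent_id[model.groups[gi].name][i] for gi in self.shared_idx),
            )
            cells.setdefault(key, []).append(i)
        self.cells = sorted(cells.values(), key=lambda idx: idx[0])

        t_parts, u_parts, slices = [], [], []
        self.cell_J, self.cell_rep = [], []
        # residual sufficient statistics grouped by time grid
        self.resid: dict[bytes, dict] = {}
        start = 0
        for idx in self.cells:
            c0 = s.curves[idx[0]]
            J = len(idx)
            ys = np.stack([s.curves[i].values for i in idx])
            ybar = ys.mean(axis=0)
            t_parts.append(c0.times)
            u_parts.append(math.sqrt(J) * ybar)
            slices.append(slice(start, start + c0.n_obs))
            start += c0.n_obs
            self.cell_J.append(J)
            self.cell_rep.append(idx[0])
            if J > 1:
                r = ys - ybar
                w = r.T @ r
                key = c0.times.tobytes()
                entry = self.resid.setdefault(
                    key, {"times": c0.times, "w": np.zeros((c0.n_obs, c0.n_obs)), "m": 0}
                )
                entry["w"] += w
                entry["m"] += J - 1
        self.t_mean = np.concatenate(t_parts)
        self.u = np.concatenate(u_parts)
        self.slices = slices
        self.n_mean = len(self.u)

        d = self.t_mean[:, None] - self.t_mean[None, :]
        self.d2 = d * d
        # shared-group masks at cell level, lifted to the mean observation vector
        cell_of = np.concatenate(
            [np.full(sl.stop - sl.start, a, dtype=int) for a, sl in enumerate(slices)]
        )
        reps = np.array(self.cell_rep)
        self.masks = {}
        for gi in self.shared_idx:
            share = s.curve_share_matrix(s.model.groups[gi].name)[reps][:, reps]
            self.masks[gi] = share[cell_of][:, cell_of]
        js = np.array(self.cell_J, dtype=float)
        scale_cells = np.sqrt(js[:, None] * js[None, :])
        self.scale = scale_cells[cell_of][:, cell_of]
        # per-grid squared distances for the within-cell covariance C
        self.grid_d2 = {}
        for sl, idx in zip(slices, self.cells):
            t = s.curves[idx[0]].times
            key = t.tobytes()
            if key not in self.grid_d2:
                dd = t[:, None] - t[None, :]
                self.grid_d2[key] = dd * dd
        self.cell_grid_key = [s.curves[idx[0]].times.tobytes() for idx in self.cells]

    def _within_cov(self, theta, key):
        """C = replicate GP kernel (M_full) + effective white noise, per grid."""
        s = self.s
        d2 = self.grid_d2[key]
        noise_eff = theta[-1] * (1.0 + BASE_JITTER_REL)
        c = np.zeros_like(d2)
        parts = {}
        for gi in self.replicate_idx:
            k, dk_dl = _kernel_mats(
                d2, theta[2 * gi], theta[2 * gi + 1], s.model.kernel_dialect
            )
            c = c + k
            parts[gi] = (k, dk_dl)
        c = c + noise_eff * np.eye(d2.shape[0])
        return c, parts

    def value_and_grad(self, theta, want_grad=True):
        s = self.s
        dialect = s.model.kernel_dialect
        n_groups = len(s.model.groups)
        grad = np.zeros_like(theta) if want_grad else None

        # ---- mean part: Σ_u = scale ∘ Σ_shared + blockdiag(C_A)
        sigma = np.zeros((self.n_mean, self.n_mean))
        kcache = {}
        for gi in self.shared_idx:
            k, dk_dl = _kernel_mats(self.d2, theta[2 * gi], theta[2 * gi + 1], dialect)
            kcache[gi] = (k, dk_dl)
            sigma += self.masks[gi] * k
        sigma *= self.scale
        cmats = {key: self._within_cov(theta, key) for key in self.grid_d2}
        for sl, key in zip(self.slices, self.cell_grid_key):
            sigma[sl, sl] += cmats[key][0]
        try:
            L = scipy.linalg.cholesky(sigma, lower=True)
        except scipy.linalg.LinAlgError:
            L, _ = jittered_cholesky(sigma, BASE_JITTER_REL * theta[-1], MAX_JITTER)
        alpha = scipy.linalg.cho_solve((L, True), self.u)
        ll = (
            -0.5 * float(self.u @ alpha)
            - float(np.sum(np.log(np.diag(L))))
            - 0.5 * self.n_mean * LOG2PI
        )
        if want_grad:
            sigma_inv = scipy.linalg.cho_solve((L, True), np.eye(self.n_mean))
            a_mat = sigma_inv - np.outer(alpha, alpha)
            for gi in self.shared_idx:
                var = theta[2 * gi]
                k, dk_dl = kcache[gi]
                sm = a_mat * (self.scale * self.masks[gi])
                grad[2 * gi] += -0.5 * float(np.sum(sm * k)) / var
                grad[2 * gi + 1] += -0.5 * float(np.sum(sm * dk_dl))
            for sl, key in zip(self.slices, self.cell_grid_key):
                ablock = a_mat[sl, sl]
                _, parts = cmats[key]
                for gi in self.replicate_idx:
                    k, dk_dl = parts[gi]
                    grad[2 * gi] += -0.5 * float(np.sum(ablock * k)) / theta[2 * gi]
                    grad[2 * gi + 1] += -0.5 * float(np.sum(ablock * dk_dl))
                grad[-1] += -0.5 * float(np.trace(ablock)) * (1.0 + BASE_JITTER_REL)

        # ---- residual part: per grid, M i.i.d. contrasts ~ N(0, C)
        for key, entry in self.resid.items():
            c, parts = cmats[key]
            m = entry["m"]
            w = entry["w"]
            tdim = c.shape[0]
            try:
                Lc = scipy.linalg.cholesky(c, lower=True)
            except scipy.linalg.LinAlgError:
                Lc, _ = jittered_cholesky(c, BASE_JITTER_REL * theta[-1], MAX_JITTER)
            cinv = scipy.linalg.cho_solve((Lc, True), np.eye(tdim))
            ll += (
                -0.5 * m * (tdim * LOG2PI + 2.0 * float(np.sum(np.log(np.diag(Lc)))))
                - 0.5 * float(np.sum(cinv * w))
            )
            if want_grad:
                gmat = cinv @ w @ cinv
                b_mat = m * cinv - gmat
                for gi in self.replicate_idx:
                    k, dk_dl = parts[gi]
                    grad[2 * gi] += -0.5 * float(np.sum(b_mat * k)) / theta[2 * gi]
                    grad[2 * gi + 1] += -0.5 * float(np.sum(b_mat * dk_dl))
                grad[-1] += -0.5 * float(np.trace(b_mat)) * (1.0 + BASE_JITTER_REL)
        return ll, grad


class MarginalLikelihood:
    """Callable marginal log-likelihood with analytic gradients.

    ``collapse='auto'`` uses the exchangeable-replicate reduction when
    any cell holds more than one curve; ``True``/``False`` force a path
    (used by the parity tests).
    """

    def __init__(self, dataset: GrowthDataset, model: ModelDef, collapse="auto"):
        self.structure = LikelihoodStructure(dataset, model)
        self.model = model
        self.names = param_names(model)
        self.n_params = len(self.names)
        if collapse == "auto":
            probe = _CollapsedPath(self.structure)
            self._path = probe if max(probe.cell_J) > 1 else _DensePath(self.structure)
        elif collapse:
            self._path = _CollapsedPath(self.structure)
        else:
            self._path = _DensePath(self.structure)

    def value(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        self._validate(theta)
        ll, _ = self._path.value_and_grad(theta, want_grad=False)
        return ll

    def value_and_grad(self, theta) -> tuple[float, np.ndarray]:
        """Returns (log-likelihood, gradient wrt natural-scale parameters)."""
        theta = np.asarray(theta, dtype=float)
        self._validate(theta)
        return self._path.value_and_grad(theta)

    def _validate(self, theta):
        if len(theta) != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters {self.names}")
        if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
            raise ValueError("hyperparameters must be positive and finite")
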