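"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — explicit
loops over observations and latent-function assignments, scipy's MVN
density — and shares no covariance-assembly code with the package.
"""

import math

import numpy as np
import scipy.stats

JITTER_REL = 1e-8


def curve_latent_keys(curve, curve_index, model):
    """Which latent functions a curve carries, enumerated independently."""
    refs = model.reference_levels
    keys = [("mean", ())]
    facs = [f for f in model.factor_levels]
    if model.structure == "single_treatment":
        f = facs[0]
        lv = curve.factors[f]
        if lv != refs[f]:
            keys.append(("treatment", (lv,)))
    else:
        f1, f2 = facs
        lv1, lv2 = curve.factors[f1], curve.factors[f2]
        if lv1 != refs[f1]:
            keys.append((f"{f1}_main", (lv1,)))
        if lv2 != refs[f2]:
            keys.append((f"{f2}_main", (lv2,)))
        if lv1 != refs[f1] and lv2 != refs[f2]:
            keys.append(("interaction", (lv1, lv2)))
    if model.kind in ("M_batch", "M_full"):
        for name, label in list(keys):
            keys.append((f"{name}_batch", label + (curve.batch,)))
    if model.kind == "M_full":
        keys.append(("replicate", (curve_index,)))
    return set(keys)


def oracle_covariance(dataset, model, hp, jitter=True):
    """Dense Σ by explicit per-observation-pair summation."""
    obs = []
    for ci, c in enumerate(dataset.curves):
        latents = curve_latent_keys(c, ci, model)
        for t in c.times:
            obs.append((t, latents))
    n = len(obs)
    sigma = np.zeros((n, n))
    noise = hp["noise.variance"] * (1.0 + JITTER_REL) if jitter else hp["noise.variance"]
    for i in range(n):
        for j in range(n):
            ti, li = obs[i]
            tj, lj = obs[j]
            total = 0.0
            for name, _ in li & lj:
                v = hp[f"{name}.variance"]
                l = hp[f"{name}.lengthscale"]
                if model.kernel_dialect == "as_printed":
                    total += v * math.exp(-((ti - tj) ** 2) / l)
                else:
                    total += v * math.exp(-((ti - tj) ** 2) / (2 * l * l))
            sigma[i, j] = total
        sigma[i, i] += noise
    return sigma


def oracle_loglik(dataset, model, hp):
    y = np.concatenate([c.values for c in dataset.curves])
    sigma = oracle_covariance(dataset, model, hp)
    return float(scipy.stats.multivariate_normal.logpdf(y, mean=np.zeros(len(y)), cov=sigma))


def oracle_conditional(joint_mean, joint_cov, n_target, y):
    """Condition the first n_target coordinates of a joint Gaussian on the rest."""
    mu_a = joint_mean[:n_target]
    mu_b = joint_mean[n_target:]
    s_aa = joint_cov[:n_target, :n_target]
    s_ab = joint_cov[:n_target, n_target:]
    s_bb = joint_cov[n_target:, n_target:]
    sol = np.linalg.solve(s_bb, (y - mu_b))
    mean = mu_a + s_ab @ sol
    cov = s_aa - s_ab @ np.linalg.solve(s_bb, s_ab.T)
    return mean, cov
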