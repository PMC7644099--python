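import math

import numpy as np
import pytest
import scipy.integrate
import scipy.optimize

from phenom.data import GrowthDataset
from phenom.likelihood import MarginalLikelihood
from phenom.model import (
    DesignError,
    PriorSpec,
    build_model,
    marginal_loglik,
    pack_params,
    param_names,
    prior_logpdf,
    prior_logpdf_grad,
)
from phenom.synthetic import simulate_dataset

from conftest import make_dataset, small_config
from oracles import oracle_loglik


def _dataset(n_levels=3, **kw):
    cfg = small_config(n_levels=n_levels, **kw)
    ds, truth = simulate_dataset(cfg)
    return ds, truth


class TestBuildModel:
    def test_null_single_treatment_census(self):
        ds, _ = _dataset(n_levels=3, seed=1)
        m = build_model("M_null", ds, "single_treatment")
        assert m.group_names == ["mean", "treatment"]
        # 3 stress levels -> one mean function + one delta per non-reference level
        from phenom.likelihood import LikelihoodStructure

        s = LikelihoodStructure(ds, m)
        assert len(s.latents["mean"]) == 1
        assert len(s.latents["treatment"]) == 2

    def test_batch_two_factor_census(self):
        cfg = small_config(seed=2)
        cfg.factors = {"pH": ["7", "6", "5"], "acid": ["0", "10", "20"]}
        cfg.reference_levels = {"pH": "7", "acid": "0"}
        cfg.structure = "two_factor_interaction"
        cfg.model_kind = "M_batch"
        cfg.n_replicates = 1
        ds, _ = simulate_dataset(cfg)
        m = build_model("M_batch", ds, "two_factor_interaction",
                        reference_levels={"pH": "7", "acid": "0"})
        fixed = [g.name for g in m.groups if g.kind == "fixed"]
        random = [g.name for g in m.groups if g.kind == "random"]
        assert fixed == ["mean", "pH_main", "acid_main", "interaction"]
        assert random == [f"{n}_batch" for n in fixed]
        m_full = build_model("M_full", ds, "two_factor_interaction",
                             reference_levels={"pH": "7", "acid": "0"})
        assert len(m_full.groups) == 9
        assert m_full.groups[-1].name == "replicate"

    def test_structure_factor_mismatch(self):
        ds, _ = _dataset(seed=3)
        with pytest.raises(DesignError):
            build_model("M_null", ds, "two_factor_interaction")

    def test_default_priors_match_conventions(self):
        ds, _ = _dataset(seed=4, model_kind="M_full")
        m = build_model("M_full", ds, "single_treatment")
        # shape-rate Gamma: fixed effects mean 1.0, random effects mean 0.7
        assert m.group("mean").variance_prior.mean() == pytest.approx(1.0)
        assert m.group("mean_batch").variance_prior.mean() == pytest.approx(0.7)
        assert m.group("replicate").variance_prior.shape == 7
        ls = m.group("mean").lengthscale_prior
        assert (ls.family, ls.shape, ls.rate) == ("inverse_gamma", 6.0, 1.0)
        mp = build_model("M_batch", ds, "single_treatment",
                         lengthscale_preset="pseudomonas")
        assert mp.group("mean").lengthscale_prior.shape == 2.0
        assert mp.group("mean_batch").lengthscale_prior.shape == 10.0


class TestPriorLogpdf:
    def test_gamma_closed_form_at_one(self):
        p = PriorSpec("gamma", 10.0, 10.0)
        expected = 10 * math.log(10) + 9 * math.log(1) - 10 - math.lgamma(10)
        assert p.logpdf(1.0) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_gives_neg_inf(self):
        ds, _ = _dataset(seed=5)
        m = build_model("M_batch", ds, "single_treatment")
        hp = {n: 1.0 for n in param_names(m)}
        hp["noise.variance"] = 0.0
        assert prior_logpdf(hp, m) == -math.inf

    @pytest.mark.parametrize(
        "spec",
        [PriorSpec("gamma", 10, 10), PriorSpec("gamma", 1, 10),
         PriorSpec("inverse_gamma", 6, 1), PriorSpec("inverse_gamma", 2, 3)],
        ids=lambda s: f"{s.family}({s.shape},{s.rate})",
    )
    def test_each_prior_integrates_to_one(self, spec):
        val, err = scipy.integrate.quad(
            lambda x: math.exp(spec.logpdf(x)), 0, np.inf, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_gradient_matches_finite_differences(self):
        ds, _ = _dataset(seed=6, model_kind="M_full")
        m = build_model("M_full", ds, "single_treatment")
        theta = np.linspace(0.3, 1.5, len(param_names(m)))
        lp, grad = prior_logpdf_grad(theta, m)
        eps = 1e-7
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (prior_logpdf_grad(tp, m)[0] - prior_logpdf_grad(tm, m)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5)


class TestMarginalLoglik:
    def test_two_point_closed_form(self):
        # mean-only-like model: treatment variance pinned to ~0
        t = np.array([0.0, 10.0])
        y = np.array([0.4, -0.2])
        ds = make_dataset([(t, y, {"stress": "s"}, "b1", "r1")])
        m = build_model("M_null", ds, "single_treatment")
        hp = {
            "mean.variance": 0.8, "mean.lengthscale": 0.5,
            "treatment.variance": 1e-300, "treatment.lengthscale": 1.0,
            "noise.variance": 0.3,
        }
        # |dt|=10 makes the off-diagonal mean-kernel term vanish numerically:
        # two independent N(0, sigma_m^2 + sigma_y^2) observations
        var = 0.8 + 0.3 * (1 + 1e-8)
        expected = sum(
            -0.5 * (math.log(2 * math.pi * var) + yy**2 / var) for yy in y
        )
        assert marginal_loglik(ds, m, hp) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("kind", ["M_null", "M_batch", "M_full"])
    def test_matches_independent_mvn_oracle(self, kind):
        for seed in (0, 1, 2):
            cfg = small_config(
                seed=seed, model_kind=kind, n_batches=2, n_replicates=1, n_times=2
            )
            ds, truth = simulate_dataset(cfg)
            m = build_model(kind, ds, "single_treatment")
            ours = marginal_loglik(ds, m, truth.hyperparams)
            assert ours == pytest.approx(oracle_loglik(ds, m, truth.hyperparams), abs=1e-9)

    def test_collapsed_and_dense_paths_agree(self):
        cfg = small_config(seed=8, model_kind="M_full", n_replicates=3, n_times=5)
        ds, truth = simulate_dataset(cfg)
        m = build_model("M_full", ds, "single_treatment")
        theta = pack_params(truth.hyperparams, m)
        c = MarginalLikelihood(ds, m, collapse=True)
        d = MarginalLikelihood(ds, m, collapse=False)
        vc, gc = c.value_and_grad(theta)
        vd, gd = d.value_and_grad(theta)
        assert vc == pytest.approx(vd, abs=1e-8)
        np.testing.assert_allclose(gc, gd, rtol=1e-6, atol=1e-8)

    def test_collapse_handles_unequal_cells_and_singletons(self):
        # one cell of 3 replicates, one of 1; collapse must still be exact
        t = np.linspace(0, 1, 4)
        rng = np.random.default_rng(0)
        curves = [
            (t, rng.normal(size=4), {"stress": "standard"}, "b1", f"r{i}") for i in range(3)
        ] + [(t, rng.normal(size=4), {"stress": "low"}, "b1", "r9")]
        ds = make_dataset(curves)
        m = build_model("M_null", ds, "single_treatment",
                        reference_levels={"stress": "standard"})
        hp = {
            "mean.variance": 1.0, "mean.lengthscale": 0.3,
            "treatment.variance": 0.5, "treatment.lengthscale": 0.2,
            "noise.variance": 0.1,
        }
        theta = pack_params(hp, m)
        assert MarginalLikelihood(ds, m, collapse=True).value(theta) == pytest.approx(
            MarginalLikelihood(ds, m, collapse=False).value(theta), abs=1e-9
        )

    def test_gradient_matches_finite_differences(self):
        cfg = small_config(seed=9, model_kind="M_batch", n_times=4)
        ds, truth = simulate_dataset(cfg)
        m = build_model("M_batch", ds, "single_treatment")
        ml = MarginalLikelihood(ds, m)
        theta = pack_params(truth.hyperparams, m)
        _, grad = ml.value_and_grad(theta)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (ml.value(tp) - ml.value(tm)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=2e-4, abs=1e-6)

    def test_noise_monotonicity_about_data_variance(self):
        # with a near-degenerate mean effect the model is y ~ N(0, s I):
        # increasing s raises the likelihood iff the empirical second moment
        # exceeds the model variance
        t = np.linspace(0, 1, 20)
        rng = np.random.default_rng(3)
        y = rng.normal(scale=1.0, size=20)
        y = y / np.sqrt(np.mean(y**2))  # second moment exactly 1
        ds = make_dataset([(t, y, {"stress": "s"}, "b1", "r1")])
        m = build_model("M_null", ds, "single_treatment")

        def ll(noise):
            return marginal_loglik(ds, m, {
                "mean.variance": 1e-12, "mean.lengthscale": 0.3,
                "treatment.variance": 1e-12, "treatment.lengthscale": 0.3,
                "noise.variance": noise,
            })

        assert ll(0.6) > ll(0.5)  # below data variance: increasing helps
        assert ll(2.4) < ll(2.2)  # above data variance: increasing hurts

    def test_nesting_of_maximized_likelihood(self):
        cfg = small_config(seed=10, model_kind="M_batch", n_times=4)
        ds, truth = simulate_dataset(cfg)
        kinds = ["M_null", "M_batch", "M_full"]
        best = []
        best_hp: dict[str, float] = {}
        for kind in kinds:
            m = build_model(kind, ds, "single_treatment")
            ml = MarginalLikelihood(ds, m)
            names = param_names(m)
            # warm start: embed the simpler optimum with new variances ~ 0
            z0 = np.array([
                math.log(best_hp.get(n, 1e-8 if n.endswith("variance") else 0.3))
                for n in names
            ]) if best_hp else np.full(len(names), -1.0)

            def neg(z):
                return -ml.value(np.exp(np.clip(z, -40, 10)))

            res = scipy.optimize.minimize(neg, z0, method="Nelder-Mead",
                                          options={"maxiter": 6000, "xatol": 1e-6, "fatol": 1e-8})
            best.append(-res.fun)
            best_hp = dict(zip(names, np.exp(res.x)))
        # richer covariance families contain the simpler ones in the
        # zero-variance limit, so maximized likelihoods are ordered
        assert best[0] <= best[1] + 1e-3
        assert best[1] <= best[2] + 1e-3
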