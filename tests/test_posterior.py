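import numpy as np
import pytest

from phenom.data import GrowthCurve, GrowthDataset
from phenom.kernels import rbf_kernel, KernelHyperparams
from phenom.model import build_model
from phenom.posterior import (
    CredibleBand,
    FunctionPosterior,
    SelectionError,
    credible_band,
    fitted_conditional_moments,
    fitted_curve_posterior,
    latent_conditional_moments,
    latent_function_posterior,
    significant_intervals,
    variance_components,
)
from phenom.synthetic import simulate_dataset

from conftest import make_dataset, samples_from_rows, small_config
from oracles import oracle_covariance, oracle_conditional, curve_latent_keys


def _hp_null(**kw):
    hp = {
        "mean.variance": 0.8, "mean.lengthscale": 0.3,
        "treatment.variance": 0.5, "treatment.lengthscale": 0.25,
        "noise.variance": 0.1,
    }
    hp.update(kw)
    return hp


class TestConditioning:
    def test_tiny_dataset_matches_bruteforce_conditioning(self):
        """Conditional mean/cov of delta(t) equal independent Gaussian
        conditioning on a 4-point dataset."""
        t = np.array([0.0, 0.3, 0.7, 1.0])
        rng = np.random.default_rng(8)
        ds = make_dataset(
            [
                (t[:2], rng.normal(size=2), {"stress": "standard"}, "b1", "r1"),
                (t[2:], rng.normal(size=2), {"stress": "low"}, "b1", "r2"),
            ]
        )
        m = build_model("M_null", ds, "single_treatment",
                        reference_levels={"stress": "standard"})
        hp = _hp_null()
        grid_model = np.array([0.1, 0.5, 0.9])
        grid_hours = grid_model  # identity time scale
        mean, cov = latent_conditional_moments(ds, m, hp, "treatment", level="low",
                                               grid_hours=grid_hours)
        # oracle: joint Gaussian of (delta(grid), y), conditioned by formula
        y = np.concatenate([c.values for c in ds.curves])
        t_obs = np.concatenate([c.times for c in ds.curves])
        k_delta = KernelHyperparams(hp["treatment.variance"], hp["treatment.lengthscale"])
        s_aa = rbf_kernel(grid_model, grid_model, k_delta)
        carries = np.array([False, False, True, True])  # obs of the stressed curve
        s_ab = rbf_kernel(grid_model, t_obs, k_delta) * carries[None, :]
        s_bb = oracle_covariance(ds, m, hp)
        joint_mean = np.zeros(3 + 4)
        joint_cov = np.block([[s_aa, s_ab], [s_ab.T, s_bb]])
        o_mean, o_cov = oracle_conditional(joint_mean, joint_cov, 3, y)
        np.testing.assert_allclose(mean, o_mean, atol=1e-9)
        np.testing.assert_allclose(cov, o_cov, atol=1e-9)

    def test_additivity_of_effect_means(self):
        """Sum of the conditional means of all effects carried by a
        condition equals the fitted-curve conditional mean."""
        cfg = small_config(seed=21, model_kind="M_batch", n_times=5)
        ds, truth = simulate_dataset(cfg)
        m = build_model("M_batch", ds, "single_treatment",
                        reference_levels={"stress": "standard"})
        grid = ds.to_hours(np.linspace(0, 1, 9))
        hp = truth.hyperparams
        total = np.zeros(9)
        for effect, kw in [
            ("mean", {}),
            ("treatment", {"level": "low"}),
            ("mean_batch", {"batch": "b1"}),
            ("treatment_batch", {"level": "low", "batch": "b1"}),
        ]:
            mean, _ = latent_conditional_moments(ds, m, hp, effect, grid_hours=grid, **kw)
            total += mean
        fitted, _ = fitted_conditional_moments(
            ds, m, hp, {"stress": "low"}, batch="b1", grid_hours=grid
        )
        np.testing.assert_allclose(total, fitted, atol=1e-8)

    def test_unobserved_latent_returns_prior(self):
        # "low" occurs only in batch b1, so the (low, b2) batch twin has
        # no incidence: its posterior is its GP prior, mean zero
        t = np.linspace(0, 1, 4)
        rng = np.random.default_rng(1)
        ds = make_dataset(
            [
                (t, rng.normal(size=4), {"stress": "standard"}, "b1", "r1"),
                (t, rng.normal(size=4), {"stress": "low"}, "b1", "r2"),
                (t, rng.normal(size=4), {"stress": "standard"}, "b2", "r1"),
            ]
        )
        m = build_model("M_batch", ds, "single_treatment",
                        reference_levels={"stress": "standard"})
        hp = _hp_null()
        hp.update({
            "mean_batch.variance": 0.3, "mean_batch.lengthscale": 0.3,
            "treatment_batch.variance": 0.4, "treatment_batch.lengthscale": 0.3,
        })
        grid = np.linspace(0, 1, 5)
        mean, cov = latent_conditional_moments(
            ds, m, hp, "treatment_batch", level="low", batch="b2", grid_hours=grid
        )
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)
        prior_k = rbf_kernel(grid, grid, KernelHyperparams(0.4, 0.3))
        np.testing.assert_allclose(cov, prior_k, atol=1e-9)

    def test_noise_to_zero_interpolates_observations(self):
        t = np.linspace(0, 1, 8)
        rng = np.random.default_rng(2)
        y = np.sin(2 * t) + 0.1 * rng.normal(size=8)
        ds = make_dataset([(t, y, {"stress": "s"}, "b1", "r1")])
        m = build_model("M_null", ds, "single_treatment")
        # short lengthscale keeps the kernel well conditioned, so the
        # zero-noise limit genuinely interpolates
        hp = _hp_null(**{"noise.variance": 1e-8, "treatment.variance": 1e-12,
                         "mean.lengthscale": 0.05})
        mean, _ = fitted_conditional_moments(ds, m, hp, {"stress": "s"}, grid_hours=t)
        assert np.max(np.abs(mean - y)) < 1e-4

    def test_ambiguous_selector_rejected(self, small_sim):
        ds, truth, m = small_sim
        samples = samples_from_rows(
            [[truth.hyperparams[n] for n in
              __import__("phenom.model", fromlist=["param_names"]).param_names(m)]],
            __import__("phenom.model", fromlist=["param_names"]).param_names(m),
        )
        with pytest.raises(SelectionError):
            latent_function_posterior(ds, m, samples, "mean_batch")  # several batches

    def test_derivative_band_consistent_with_finite_difference_of_mean(self, small_sim):
        """Analytic derivative conditional mean ~ finite differences of the
        function conditional mean (cross-check mode)."""
        ds, truth, m = small_sim
        hp = truth.hyperparams
        grid = ds.to_hours(np.linspace(0.1, 0.9, 21))
        dmean, _ = latent_conditional_moments(ds, m, hp, "mean", grid_hours=grid,
                                              derivative=True)
        h = 1e-3
        up, _ = latent_conditional_moments(ds, m, hp, "mean", grid_hours=grid + h)
        dn, _ = latent_conditional_moments(ds, m, hp, "mean", grid_hours=grid - h)
        np.testing.assert_allclose(dmean, (up - dn) / (2 * h), rtol=1e-4, atol=1e-6)


class TestCredibleBand:
    def test_constant_draws_degenerate_band(self):
        fp = FunctionPosterior(grid=np.arange(4.0), draws=np.full((50, 4), 2.5), effect="e")
        band = credible_band(fp)
        for arr in (band.lower, band.mean, band.upper):
            np.testing.assert_array_equal(arr, 2.5)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_level_outside_unit_interval_rejected(self, bad):
        fp = FunctionPosterior(grid=np.arange(3.0), draws=np.zeros((5, 3)), effect="e")
        with pytest.raises(ValueError):
            credible_band(fp, level=bad)

    def test_normal_draws_match_normal_quantiles(self, rng):
        draws = rng.normal(size=(10_000, 3))
        band = credible_band(FunctionPosterior(grid=np.arange(3.0), draws=draws, effect="e"))
        np.testing.assert_allclose(band.lower, -1.96, atol=0.05)
        np.testing.assert_allclose(band.mean, 0.0, atol=0.05)
        np.testing.assert_allclose(band.upper, 1.96, atol=0.05)


def _band(lower, upper, grid=None):
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    g = np.arange(len(lower), dtype=float) if grid is None else grid
    return CredibleBand(grid=g, lower=lower, mean=(lower + upper) / 2,
                        upper=upper, level=0.95)


class TestSignificantIntervals:
    def test_band_containing_zero_everywhere(self):
        assert significant_intervals(_band([-1, -1, -1], [1, 1, 1])) == []

    def test_all_positive_band_single_run(self):
        got = significant_intervals(_band([1, 1, 1], [3, 3, 3]))
        assert got == [(0.0, 2.0, "+")]

    def test_alternating_pattern_matches_scan_oracle(self, rng):
        for _ in range(20):
            lower = rng.normal(size=6)
            upper = lower + np.abs(rng.normal(size=6))
            band = _band(lower, upper)
            got = significant_intervals(band)
            # independent linear scan
            expected = []
            run = None
            for i in range(6):
                s = "+" if lower[i] > 0 else ("-" if upper[i] < 0 else None)
                if s is None or (run and s != run[2]):
                    if run:
                        expected.append(tuple(run))
                    run = None
                if s is not None and run is None:
                    run = [float(i), float(i), s]
                elif s is not None:
                    run[1] = float(i)
            if run:
                expected.append(tuple(run))
            assert got == expected

    def test_stricter_level_intervals_are_nested(self, rng):
        draws = rng.normal(size=(4000, 30)) + np.linspace(-2, 2, 30)
        fp = FunctionPosterior(grid=np.arange(30.0), draws=draws, effect="e")
        pts95 = {
            g for a, b, _ in significant_intervals(credible_band(fp, 0.95))
            for g in np.arange(a, b + 1)
        }
        pts99 = {
            g for a, b, _ in significant_intervals(credible_band(fp, 0.99))
            for g in np.arange(a, b + 1)
        }
        assert pts99 <= pts95


class TestVarianceComponents:
    def test_null_model_census(self, rng):
        cfg = small_config(seed=30, model_kind="M_null", n_batches=1, n_replicates=2)
        ds, _ = simulate_dataset(cfg)
        m = build_model("M_null", ds, "single_treatment")
        from phenom.model import param_names

        names = param_names(m)
        draws = np.abs(rng.normal(size=(2, 50, len(names)))) + 0.01
        s = samples_from_rows(draws, names)
        table = variance_components(s, m)
        assert set(table.draws) == {"mean", "treatment", "noise"}

    def test_batch_pooling_sums_variances(self, small_sim, rng):
        ds, truth, m = small_sim
        from phenom.model import param_names

        names = param_names(m)
        draws = np.abs(rng.normal(size=(1, 40, len(names)))) + 0.01
        s = samples_from_rows(draws, names)
        pooled = variance_components(s, m, pool_batch_components=True)
        split = variance_components(s, m, pool_batch_components=False)
        np.testing.assert_allclose(
            pooled.draws["batch"],
            split.draws["mean_batch"] + split.draws["treatment_batch"],
        )

    def test_summaries_recomputable_from_serialized_draws(self, tmp_path, small_sim, rng):
        ds, truth, m = small_sim
        from phenom.inference import PosteriorSamples
        from phenom.model import param_names

        names = param_names(m)
        draws = np.abs(rng.normal(size=(2, 30, len(names)))) + 0.01
        s = samples_from_rows(draws, names)
        s.save_csv(tmp_path / "d.csv", tmp_path / "m.json")
        back = PosteriorSamples.load_csv(tmp_path / "d.csv", tmp_path / "m.json")
        t1 = variance_components(s, m).summary
        t2 = variance_components(back, m).summary
        assert t1.equals(t2)
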