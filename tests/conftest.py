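import numpy as np
import pytest

from phenom.data import GrowthCurve, GrowthDataset
from phenom.inference import MCMCConfig, PosteriorSamples
from phenom.synthetic import SimulationConfig, simulate_dataset, build_truth_model


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def small_config(
    n_levels=2,
    n_batches=2,
    n_replicates=2,
    n_times=6,
    hours=12.0,
    model_kind="M_batch",
    seed=0,
    **kw,
):
    levels = ["standard", "low", "high"][:n_levels]
    times = kw.pop("times_hours", np.linspace(0.0, hours, n_times))
    return SimulationConfig(
        factors={"stress": levels},
        reference_levels={"stress": "standard"},
        n_batches=n_batches,
        n_replicates=n_replicates,
        times_hours=times,
        model_kind=model_kind,
        structure="single_treatment",
        seed=seed,
        **kw,
    )


@pytest.fixture
def small_sim():
    """(dataset, truth, model) for a small M_batch design."""
    cfg = small_config(seed=7)
    ds, truth = simulate_dataset(cfg)
    return ds, truth, build_truth_model(cfg, ds)


def make_dataset(curve_specs, factor_names=("stress",), **kw):
    """Hand-built dataset: curve_specs = [(times, values, factors, batch, rep)]."""
    curves = [
        GrowthCurve(times=t, values=v, factors=f, batch=b, replicate=r)
        for t, v, f, b, r in curve_specs
    ]
    return GrowthDataset(curves=curves, factor_names=list(factor_names), **kw)


def samples_from_rows(rows, names, chains=1, fixed=None):
    """PosteriorSamples wrapping explicit hyperparameter draws (testing aid)."""
    arr = np.asarray(rows, dtype=float)
    if arr.ndim == 2:
        arr = arr.reshape(chains, -1, arr.shape[-1])
    return PosteriorSamples(
        draws=arr,
        param_names=list(names),
        divergences=[0] * arr.shape[0],
        config=MCMCConfig(chains=max(arr.shape[0], 1), warmup=1, samples=arr.shape[1]),
        fixed=dict(fixed or {}),
    )
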