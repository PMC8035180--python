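import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from c3pco2 import (
    ProxyParams,
    SamplingPlan,
    StackedCurve,
    fit_stack,
    forward_model_plant_d13c,
    generate_true_history,
    mc_reconstruct,
    sample_sections,
)

PLANT_SUBSTRATES = ("plant_cuticle", "plant_wood")


@pytest.fixture(scope="session")
def truth():
    return generate_true_history()


@pytest.fixture(scope="session")
def plant_true(truth):
    return forward_model_plant_d13c(truth)


@pytest.fixture(scope="session")
def noisefree_samples(truth, plant_true):
    plan = SamplingPlan(noise_sd_plant=0.0, noise_sd_carb=0.0, noise_sd_sst=0.0, seed=3)
    return sample_sections(truth, plant_true, plan)


@pytest.fixture(scope="session")
def noisy_samples(truth, plant_true):
    return sample_sections(truth, plant_true, SamplingPlan(seed=0))


@pytest.fixture(scope="session")
def truth_stacks(truth, plant_true):
    """Exact stacks on the true curves with zero standard error."""
    g = truth.age_grid
    ones = np.ones(len(g), dtype=int)
    zeros = np.zeros(len(g))
    return (
        StackedCurve(g, plant_true, zeros, ones, 0.1),
        StackedCurve(g, truth.d13c_carb_true, zeros, ones, 0.1),
        StackedCurve(g, truth.sst_true, zeros, ones, 0.1),
    )


@pytest.fixture(scope="session")
def noisy_stacks(truth, noisy_samples):
    out = {}
    for name, subs in (
        ("plant", PLANT_SUBSTRATES),
        ("carb", ("carbonate",)),
        ("sst", ("sst",)),
    ):
        df = noisy_samples[noisy_samples["substrate"].isin(subs)]
        out[name] = fit_stack(df, truth.age_grid)
    return out


@pytest.fixture(scope="session")
def default_recon(noisy_stacks):
    """Default-conditions reconstruction shared across statistical tests."""
    return mc_reconstruct(
        noisy_stacks["plant"],
        noisy_stacks["carb"],
        noisy_stacks["sst"],
        ProxyParams(),
        n_draws=4000,
        seed=0,
    )
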