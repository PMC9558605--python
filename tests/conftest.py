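import warnings

import numpy as np
import pytest

import thzchem as tc


@pytest.fixture(scope="session")
def grid():
    return tc.default_grid()


@pytest.fixture(scope="session")
def qext(grid):
    return tc.mie_extinction_efficiency(tc.MieParams(), grid)


@pytest.fixture(scope="session")
def mask(grid):
    return tc.valid_frequency_mask(grid)


def clean_config(**overrides):
    """Noiseless, linear, baseline-free world (clean-room defaults)."""
    base = dict(noise_sd=0.0, thickness_jitter=0.0, water_amplitude=0.0,
                baseline_xi_range=(0.0, 0.0), nonlinearity_strength=0.0, seed=0)
    base.update(overrides)
    return tc.SimulationConfig(**base)


@pytest.fixture(scope="session")
def clean_dataset():
    return tc.simulate_dataset(config=clean_config())


@pytest.fixture(scope="session")
def default_dataset():
    """The stated measurement world: noise, jitter, baseline, water lines."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tc.simulate_dataset(config=tc.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 4-sample, 2-replicate dataset on a short grid for unit tests."""
    g = tc.default_grid(0.3, 3.0, 0.05)
    comps = [
        tc.Composition(1.0, 0.0, 0.0),
        tc.Composition(0.0, 0.5, 0.5),
        tc.Composition(0.4, 0.3, 0.3),
        tc.Composition(0.2, 0.5, 0.3),
    ]
    cfg = clean_config(replicates=2)
    return tc.simulate_dataset(compositions=comps, config=cfg, grid=g)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
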