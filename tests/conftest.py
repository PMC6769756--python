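import numpy as np
import pytest

from paleoload import simdata


def small_params(seed=0, **overrides):
    """A scaled-down scenario for fast tests: same structure as the
    default horse-like scenario, fewer sites and samples."""
    params = simdata.ScenarioParams(
        seed=seed,
        n_sites=800,
        ancient_strata=[
            (50.0, 250.0, 8),
            (250.0, 750.0, 4),
            (750.0, 1750.0, 8),
            (1750.0, 2750.0, 8),
            (2750.0, 3700.0, 8),
        ],
        breeds=[
            simdata.BreedSpec("inbred", "working", 12, 0.3, 12.0),
            simdata.BreedSpec("outbred", "other", 12, 0.02, 12.0),
        ],
    )
    for key, value in overrides.items():
        setattr(params, key, value)
    return params


@pytest.fixture(scope="session")
def small_dataset():
    return simdata.simulate_dataset(small_params())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
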