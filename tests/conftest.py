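import numpy as np
import pytest

from cidms import synthetic, thermo, workflow
from cidms.synthetic import DopedLibrarySpec, ExperimentSpec, SortSpec


@pytest.fixture(scope="session")
def params():
    """Default model constants with expression self-consistently calibrated."""
    return workflow.default_params()


@pytest.fixture(scope="session")
def small_sim(params):
    """A small but complete synthetic experiment shared across tests."""
    spec = ExperimentSpec(
        library=DopedLibrarySpec(seed=11, n_molecules=30_000),
        sort=SortSpec(depth=300_000, seed=12),
        ddg_seed=13,
    )
    sim = synthetic.simulate_experiment(spec, params)
    sim["spec"] = spec
    return sim


@pytest.fixture
def rng():
    return np.random.default_rng(0)
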