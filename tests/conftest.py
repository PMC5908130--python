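import numpy as np
import pytest

from plasmir.simulate import SimulationConfig, build_reference_bundle, sample_truth


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: 60 miRNAs, two small clusters, shallow depth."""
    return SimulationConfig(n_cases=4, n_controls=4, n_mirna=60,
                            cluster_sizes=(5, 4), read_depth=20000, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return build_reference_bundle(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_bundle):
    return sample_truth(small_config, small_bundle)


@pytest.fixture(scope="session")
def default_bundle():
    """Study-scale references (52 + 50 precursor clusters, 600 matures)."""
    return build_reference_bundle(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
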