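import numpy as np
import pytest

import helpmeth as hm


@pytest.fixture(scope="session")
def deep_config():
    """Deep-coverage, low-dispersion cohort: assay noise is negligible so
    score-scale properties of the planted signal are testable directly."""
    return hm.SimulationConfig(
        n_sites=3000,
        seed=101,
        mean_depth=5000,
        hpaii_dispersion=1e-4,
        batch_shift_loc=0.0,
    )


@pytest.fixture(scope="session")
def deep_cohort(deep_config):
    return hm.simulate_cohort(deep_config)


@pytest.fixture(scope="session")
def deep_meth(deep_cohort):
    return hm.quantify(deep_cohort.hpaii, deep_cohort.mspi).dropna()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
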