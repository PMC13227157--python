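import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from elocodon import (
    SimulationConfig,
    compute_profiles_batch,
    simulate_cds_set,
    simulate_expression,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

# the study conditions of the shipped regression simulations: a two-organ
# design with an upregulating codon-load effect in the hypocotyl and a
# stronger downregulating one in the cotyledon
STUDY_CONFIG = SimulationConfig(
    n_genes=5000,
    beta_effect=(0.2, -0.5),
    sigma_noise=0.5,
    organs=2,
    seed=11,
)


@pytest.fixture(scope="session")
def study_cds():
    return simulate_cds_set(STUDY_CONFIG)


@pytest.fixture(scope="session")
def study_profiles(study_cds):
    return compute_profiles_batch(study_cds)


@pytest.fixture(scope="session")
def expr_hyp(study_profiles):
    return simulate_expression(study_profiles, STUDY_CONFIG, organ_index=0)


@pytest.fixture(scope="session")
def expr_cot(study_profiles):
    return simulate_expression(study_profiles, STUDY_CONFIG, organ_index=1)


@pytest.fixture(scope="session")
def expr_null(study_profiles):
    from elocodon.simulate import null_config

    return simulate_expression(study_profiles, null_config(STUDY_CONFIG), organ_index=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
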