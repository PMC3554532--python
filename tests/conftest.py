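import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import epibias as eb

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null_scenario():
    """A medium uniform scenario with its proteome and ground truth."""
    config = eb.scenario_null(seed=11, n_peptides=8000)
    antigens = eb.generate_proteome(config)
    records, truth = eb.generate_assay_peptides(antigens, config)
    return config, antigens, records, truth


@pytest.fixture(scope="session")
def central_scenario():
    config = eb.scenario_central_bias(seed=13, n_peptides=10_000)
    antigens = eb.generate_proteome(config)
    records, truth = eb.generate_assay_peptides(antigens, config)
    return config, antigens, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
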