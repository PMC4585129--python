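import pytest

from aomlab.simulate import SimParams, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (seed 0), shared across tests."""
    return generate_study(SimParams(seed=0))


@pytest.fixture(scope="session")
def noiseless_study():
    """Fully deterministic study: no measurement, Cq or replicate noise."""
    params = SimParams(seed=0, noise_sd=0.0, cq_noise_sd=0.0, bottle_rate_sd=0.0)
    return generate_study(params)
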