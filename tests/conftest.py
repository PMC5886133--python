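import pytest

from fgaps.panel import RunConfig
from fgaps.synthetic import SyntheticSpec, generate_panel, generate_subaccounts


@pytest.fixture(scope="session")
def spec30():
    return SyntheticSpec(n_countries=30, seed=7)


@pytest.fixture(scope="session")
def panel_truth(spec30):
    return generate_panel(spec30)


@pytest.fixture(scope="session")
def panel(panel_truth):
    return panel_truth[0]


@pytest.fixture(scope="session")
def truth(panel_truth):
    return panel_truth[1]


@pytest.fixture(scope="session")
def subaccounts(panel_truth):
    return generate_subaccounts(*panel_truth)


@pytest.fixture()
def config():
    return RunConfig(alpha=0.1, beta=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_panel_truth():
    """Zero-noise panel whose mortality follows the linear predictor exactly."""
    spec = SyntheticSpec(
        n_countries=40, seed=11, mortality_noise_sd=0.0, fraction_noise_sd=0.0
    )
    return generate_panel(spec)
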