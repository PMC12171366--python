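import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from espccd import ESPData, SyntheticConfig, fit_esp, generate_population

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_model_data(table, config: SyntheticConfig) -> ESPData:
    """ESPData from a model-mode population, using the true covariate set."""
    covariates = [k for k in config.beta1 if k != "const"]
    return ESPData.from_frame(
        table,
        outcome="balanced",
        treatment="work",
        covariates=covariates,
        instrument="iv",
        cluster="village_id",
    )


@pytest.fixture(scope="session")
def model_population():
    """Mid-sized model-mode population shared by estimation tests."""
    config = SyntheticConfig(
        n_villages=250, village_size_range=(15, 25), mode="model", seed=3
    )
    table, truth = generate_population(config)
    return config, table, truth


@pytest.fixture(scope="session")
def model_fit(model_population):
    """One full FIML fit on the shared population (expensive; reused)."""
    config, table, truth = model_population
    data = make_model_data(table, config)
    est = fit_esp(data)
    return config, table, truth, data, est
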