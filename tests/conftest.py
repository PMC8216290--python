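import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ipass.model import IpassModel, N_FEATURES, Scaler, train_model
from ipass.synth import gen_training_table, random_planted_model


@pytest.fixture(scope="session")
def planted():
    return random_planted_model(seed=11, noise_sd=0.1)


@pytest.fixture(scope="session")
def training_data(planted):
    """500 planted-signal training rows: (contexts, y, truth)."""
    return gen_training_table(planted, n=500, seed=11)


@pytest.fixture(scope="session")
def fitted_model(training_data):
    contexts, y, _ = training_data
    return train_model(contexts, y)


def make_manual_model(weights: dict[str, float], intercept: float = 0.0) -> IpassModel:
    """Model with hand-set weights on an identity scaler (raw features)."""
    from ipass.model import feature_names

    names = feature_names()
    w = np.zeros(N_FEATURES)
    for name, v in weights.items():
        w[names.index(name)] = v
    scaler = Scaler(
        center=np.zeros(N_FEATURES),
        scale=np.ones(N_FEATURES),
        constant=np.zeros(N_FEATURES, bool),
    )
    return IpassModel(scaler=scaler, w=w, intercept=intercept, k=1.0)


@pytest.fixture
def manual_model_factory():
    return make_manual_model
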