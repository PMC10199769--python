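import numpy as np
import pytest

from flan import FLAN, TrainConfig
from flan.synthetic import (
    SyntheticImageSpec,
    SyntheticSequenceSpec,
    SyntheticTabularSpec,
    gen_images,
    gen_sequences,
    gen_tabular,
)

TINY_TABULAR = SyntheticTabularSpec(
    n_samples=300,
    n_features=6,
    informative=(0, 1),
    effects=("quadratic", "identity"),
    weight_scale=2.0,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_tabular_task():
    return gen_tabular(TINY_TABULAR)


@pytest.fixture(scope="session")
def tiny_tabular_ds(tiny_tabular_task):
    return tiny_tabular_task.encoded()


@pytest.fixture(scope="session")
def untrained_results(tiny_tabular_ds):
    """A freshly initialized (not trained) tabular model."""
    model = FLAN(tiny_tabular_ds, latent_dim=5, encoder_hidden=(8,), predictor_hidden=(8,))
    return model.as_results()


@pytest.fixture(scope="session")
def trained_results(tiny_tabular_ds):
    model = FLAN(tiny_tabular_ds, latent_dim=5, encoder_hidden=(8, 8), predictor_hidden=(8,))
    return model.fit(TrainConfig(epochs=25, batch_size=32, seed=7, patience=0))


@pytest.fixture(scope="session")
def tiny_sequence_task():
    return gen_sequences(SyntheticSequenceSpec(n_samples=120, seed=5))


@pytest.fixture(scope="session")
def sequence_results(tiny_sequence_task):
    ds = tiny_sequence_task.encoded()
    model = FLAN(ds, latent_dim=6, encoder_hidden=(16,), predictor_hidden=(8,), embed_dim=4)
    return model.fit(TrainConfig(epochs=10, batch_size=32, seed=5, patience=0))


@pytest.fixture(scope="session")
def tiny_image_task():
    return gen_images(SyntheticImageSpec(n_samples=60, seed=3))


@pytest.fixture(scope="session")
def image_results(tiny_image_task):
    ds = tiny_image_task.encoded()
    model = FLAN(ds, latent_dim=6, encoder_hidden=(16,), predictor_hidden=(8,))
    return model.fit(TrainConfig(epochs=8, batch_size=32, seed=3, patience=0))
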