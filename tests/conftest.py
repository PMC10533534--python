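import numpy as np
import pytest

from octood import DatasetConfig, TrainConfig, build_model, generate_dataset
from octood.train import train


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, fast dataset shared by integration tests (32 px images)."""
    return generate_dataset(DatasetConfig(images_per_class=30, side=32, seed=7))


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A briefly trained softmax model on the tiny dataset."""
    model = build_model("softmax", K=4, side=32, seed=0)
    cfg = TrainConfig.desk_scale(seed=5, max_epochs=8,
                                 early_stop_patience=8)
    model, _ = train(model, tiny_dataset.train, tiny_dataset.val, cfg)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
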