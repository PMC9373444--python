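import numpy as np
import pytest

import circsplice as cs


def tiny_config(**overrides):
    """A deliberately small architecture for fast unit tests."""
    base = dict(
        conv1_kernels=8,
        conv1_size=6,
        conv2_kernels=4,
        conv2_size=8,
        dropout1=0.1,
        dropout2=0.1,
        batch_size=64,
        learning_rate=2e-3,
        max_epochs=30,
        early_stopping_patience=8,
        seed=11,
    )
    base.update(overrides)
    return cs.ModelConfig(**base)


def small_fixture(n=120, seed=5, plant_probability=0.95):
    """A small planted dataset separable by a width-6 model."""
    cfg = cs.SimConfig(
        n_pos=n,
        n_neg=n,
        plants=(
            cs.PlantSpec(
                pwm=np.eye(4)[[3, 2, 1, 0, 3, 2]],  # consensus UGCAUG
                target_input="SA",
                side="intron",
                plant_probability=plant_probability,
                offsets=(15,),
            ),
        ),
        seed=seed,
    )
    return cs.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_dataset():
    pairs, log = small_fixture()
    return pairs, log


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    """One small model trained on the small planted dataset."""
    pairs, _ = tiny_dataset
    model = cs.build_model(tiny_config())
    cs.train(model, pairs)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
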