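import numpy as np
import pytest

from aldele.config import ModelConfig
from aldele.synthetic import SyntheticSpec, build_dataset
from aldele.train import train_model


@pytest.fixture(scope="session")
def small_spec():
    """A reduced planted-signal study for fast plumbing tests."""
    return SyntheticSpec(n_pairs=60, n_proteins=10, n_compounds=10,
                         seq_length=(30, 40), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    dataset, truth = build_dataset(small_spec)
    return dataset, truth


@pytest.fixture(scope="session")
def trained_small(small_dataset):
    """An M1 checkpoint trained briefly on the reduced study."""
    dataset, truth = small_dataset
    config = ModelConfig.from_preset("M1", epochs=5, seed=7)
    ckpt, report = train_model(config, dataset)
    return ckpt, report, dataset, truth
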