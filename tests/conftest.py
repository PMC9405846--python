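import numpy as np
import pytest

from aptaselex.library import LibraryConfig, generate_library
from aptaselex.model import ModelConfig
from aptaselex.synthdata import SynthSpec, generate_binding_dataset


@pytest.fixture(scope="session")
def small_library():
    return generate_library(LibraryConfig(n_candidates=200, length=27, seed=7))


@pytest.fixture(scope="session")
def tiny_model_config():
    """A scaled-down model for fast unit tests (same architecture family)."""
    return ModelConfig(
        conv_filters=(4, 6, 8),
        kernel_sizes=(3, 3, 3),
        fc_sizes=(16, 16, 8),
        epochs=4,
        batch_size=16,
        pad_length=40,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_synth_df():
    """80-row planted-rule dataset with short sequences (fits pad length 40)."""
    spec = SynthSpec(n_pos=40, n_neg=40, seq_length_range=(20, 40), seed=5)
    return generate_binding_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
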