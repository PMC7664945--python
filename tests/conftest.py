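import numpy as np
import pytest

from saepso import SparseAEConfig, SynthSpec, make_classification_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_ae_config():
    return SparseAEConfig(
        hidden_size=3, max_epochs=60, l2_coeff=1e-3,
        sparsity_coeff=0.5, sparsity_proportion=0.2, seed=0,
    )


@pytest.fixture
def separable_binary():
    """Small, well-separated two-class dataset for pipeline tests."""
    spec = SynthSpec(
        n_samples=80, n_features=10, n_classes=2,
        separation=6.0, noise_sd=1.0, seed=3,
    )
    return make_classification_dataset(spec)
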