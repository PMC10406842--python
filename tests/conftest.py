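import numpy as np
import pytest

from edice.data_io import GenomicBinning, SignalTensor
from edice.model import ModelConfig, ModelParams


@pytest.fixture
def tiny_config() -> ModelConfig:
    return ModelConfig(embed_dim=8, n_heads=2, attn_hidden=6, attn_out=8,
                       decoder_hidden=10, decoder_layers=2, dropout_rate=0.0)


@pytest.fixture
def tiny_params(tiny_config) -> ModelParams:
    return ModelParams.initialize(3, 4, tiny_config, seed=42)


@pytest.fixture
def small_binning() -> GenomicBinning:
    return GenomicBinning("chrT", 25 * 200, 25)


@pytest.fixture
def small_tensor(small_binning) -> SignalTensor:
    """4 cells x 3 assays x 200 bins, two unobserved tracks."""
    rng = np.random.default_rng(5)
    values = np.arcsinh(np.abs(rng.normal(1.0, 0.5, size=(4, 3, 200))))
    observed = np.ones((4, 3), dtype=bool)
    observed[1, 2] = False
    observed[3, 0] = False
    values[~observed, :] = 0
    return SignalTensor(values, observed, small_binning,
                        [f"C{i}" for i in range(4)], [f"A{j}" for j in range(3)])
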