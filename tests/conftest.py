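import numpy as np
import pytest

from gcap.model import ModelConfig
from gcap.pipeline import build_context
from gcap.synthetic import generate_block_benchmark

TINY_CONFIG = ModelConfig(
    hidden_width=16,
    mga_layers=1,
    supernode_layers=1,
    cnn_layers=1,
    fusion_heads=2,
    mlp_hidden=16,
    seed=11,
)


@pytest.fixture(scope="session")
def block_context():
    """Featurized 8-drug x 6-ADR block benchmark, shared across tests."""
    dataset, smiles, hierarchy = generate_block_benchmark(n_drugs=8, n_adrs=6, seed=3)
    return build_context(dataset, smiles, hierarchy)


@pytest.fixture(scope="session")
def tiny_model(block_context):
    return block_context.make_model(TINY_CONFIG)


@pytest.fixture(scope="session")
def tiny_features(block_context):
    return block_context.features_for(np.arange(block_context.n_pairs))
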