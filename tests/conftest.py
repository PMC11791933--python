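import numpy as np
import pytest

from seqstruct import (EncoderConfig, SequenceEncoder, StructureEncoder,
                       SynthConfig, generate)

# Small-but-nontrivial profile used across tests; 2 layers keep training and
# gradient flows realistic (residuals, adapters in a "top-K" subset).
TEST_CONFIG = EncoderConfig(n_layers=2, embed_dim=16, ffn_dim=32, n_heads=2,
                            max_len=64, patch_size=8, input_side=32)


@pytest.fixture(scope="session")
def small_corpus():
    """3 families x 4 proteins, short sequences: fast paired corpus."""
    cfg = SynthConfig(n_families=3, proteins_per_family=4,
                      length_range=(24, 60), motif_length=6, seed=7)
    return generate(cfg)


@pytest.fixture()
def seq_encoder():
    return SequenceEncoder(TEST_CONFIG, seed=3)


@pytest.fixture()
def str_encoder():
    return StructureEncoder(TEST_CONFIG, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
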