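import numpy as np
import pytest

from seqstruct import load_checkpoint, mean_pool, save_checkpoint, tokenize
from seqstruct.autodiff import Tensor
from seqstruct.encoders import Projector, project
from seqstruct.pretrain import attach_structure_aware_modules
from seqstruct.seqio import ProteinRecord, pad_batch


# -- pooling -----------------------------------------------------------------


def test_mean_pool_simple_rows():
    rows = np.array([[1.0, 3.0], [3.0, 5.0]])
    np.testing.assert_allclose(mean_pool(rows, [True, True]).data, [2.0, 4.0])


def test_mean_pool_single_valid_row():
    rows = np.array([[1.0, 2.0], [9.0, 9.0]])
    np.testing.assert_allclose(mean_pool(rows, [True, False]).data, [1.0, 2.0])


def test_mean_pool_excludes_masked_rows():
    rows = np.array([[1.0, 1.0], [1e6, 1e6], [3.0, 3.0]])
    np.testing.assert_allclose(mean_pool(rows, [True, False, True]).data, [2.0, 2.0])


def test_mean_pool_empty_mask_errors():
    with pytest.raises(ValueError):
        mean_pool(np.ones((2, 2)), [False, False])


def test_pooling_insensitive_to_pad_content(seq_encoder):
    """Altering embeddings at mask-false positions never changes the pool."""
    rng = np.random.default_rng(5)
    x = rng.normal(size=(1, 6, 16))
    mask = np.array([[False, True, True, True, False, False]])
    base = mean_pool(x, mask).data
    x2 = x.copy()
    x2[0, ~mask[0]] = 1e9
    np.testing.assert_array_equal(mean_pool(x2, mask).data, base)


# -- projector ---------------------------------------------------------------


def test_projector_identity_initialisation():
    proj = Projector(4, np.random.default_rng(0), np.float64, d_out=4)
    proj.fc1.W.data = np.eye(4)
    proj.fc1.b.data = np.zeros(4)
    proj.fc2.W.data = np.eye(4)
    proj.fc2.b.data = np.zeros(4)
    x = np.array([0.5, 1.0, 2.0, 0.1])  # nonnegative passes ReLU unchanged
    np.testing.assert_allclose(proj(Tensor(x)).data, x)


def test_projector_zero_weights_give_zero():
    proj = Projector(4, np.random.default_rng(0), np.float64, d_out=4)
    proj.fc2.W.data = np.zeros((4, 4))
    proj.fc2.b.data = np.zeros(4)
    out = proj(Tensor(np.ones(4))).data
    np.testing.assert_array_equal(out, np.zeros(4))


def test_projector_fixed_2x2_hand_computed():
    proj = Projector(2, np.random.default_rng(0), np.float64, d_out=2)
    proj.fc1.W.data = np.array([[1.0, -1.0], [2.0, 0.5]])
    proj.fc1.b.data = np.array([0.1, 0.2])
    proj.fc2.W.data = np.eye(2)
    proj.fc2.b.data = np.array([1.0, 1.0])
    # x = (1, 0): fc1 -> (1.1, -0.8); ReLU -> (1.1, 0); fc2 -> (2.1, 1.0)
    np.testing.assert_allclose(proj(Tensor(np.array([1.0, 0.0]))).data, [2.1, 1.0])


def test_project_checks_dimension(seq_encoder):
    with pytest.raises(ValueError, match="dimension"):
        project(seq_encoder, np.ones(7))


# -- sequence encoder --------------------------------------------------------


def test_encode_single_residue(seq_encoder):
    b = seq_encoder.encode(tokenize(ProteinRecord("p", "A"), max_len=64))
    assert b.residue_embeddings.shape == (1, 16)
    assert b.projected.shape == (256,)
    assert b.modality == "sequence"


def test_pooled_equals_mean_of_residue_embeddings(seq_encoder):
    b = seq_encoder.encode(tokenize(ProteinRecord("p", "ACDEFG"), max_len=64))
    np.testing.assert_allclose(b.protein_embedding,
                               b.residue_embeddings.mean(axis=0), atol=1e-12)


def test_truncation_makes_long_tails_irrelevant(seq_encoder):
    base = "ACDEFGHIKL" * 7  # 70 residues, max_len 64
    a = seq_encoder.encode(tokenize(ProteinRecord("a", base), max_len=64))
    b = seq_encoder.encode(tokenize(ProteinRecord("b", base[:64] + "WWWWWW"), max_len=64))
    np.testing.assert_array_equal(a.projected, b.projected)


def test_out_of_vocabulary_token_rejected(seq_encoder):
    ids = np.array([[99, 0, 1]])
    mask = np.array([[False, True, True]])
    with pytest.raises(ValueError, match="vocabulary"):
        seq_encoder.forward_batch(ids, mask)


def test_batch_and_single_paths_agree(seq_encoder):
    recs = [ProteinRecord("a", "ACDEF"), ProteinRecord("b", "WYW")]
    toks = [tokenize(r, max_len=64) for r in recs]
    ids, mask = pad_batch(toks)
    _, pooled, proj = seq_encoder.forward_batch(ids, mask)
    for i, t in enumerate(toks):
        single = seq_encoder.encode(t)
        np.testing.assert_allclose(single.protein_embedding, pooled.data[i], atol=1e-10)


def test_zero_init_adapters_are_exact_identity(seq_encoder):
    tok = tokenize(ProteinRecord("p", "ACDEFGHIKL"), max_len=64)
    before = seq_encoder.encode(tok)
    attach_structure_aware_modules(seq_encoder, seed=0)
    with_adapters = seq_encoder.encode(tok, adapters_enabled=True)
    np.testing.assert_array_equal(before.projected, with_adapters.projected)
    np.testing.assert_array_equal(before.residue_embeddings,
                                  with_adapters.residue_embeddings)


# -- structure encoder -------------------------------------------------------


def _map_and_mask(rng, L=16):
    vals = rng.uniform(size=(3, L, L))
    vals = (vals + vals.transpose(0, 2, 1)) / 2
    from seqstruct.structmap import ContactMapTensor, resize_for_encoder
    cm = ContactMapTensor(vals, (22.0,) * 3)
    return resize_for_encoder(cm, side=32, patch_size=8)


def test_identical_maps_identical_bundles(str_encoder, rng):
    arr, mask = _map_and_mask(rng)
    b1 = str_encoder.encode(arr, mask)
    b2 = str_encoder.encode(arr.copy(), mask.copy())
    np.testing.assert_array_equal(b1.projected, b2.projected)


def test_padding_beyond_mask_ignored(str_encoder, rng):
    arr, mask = _map_and_mask(rng)
    poisoned = arr.copy()
    # patches outside the coverage mask: bottom-right quadrant
    poisoned[:, 16:, 16:] = 123.0
    b1 = str_encoder.encode(arr, mask)
    b2 = str_encoder.encode(poisoned, mask)
    np.testing.assert_array_equal(b1.protein_embedding, b2.protein_embedding)


def test_all_masked_input_is_error(str_encoder):
    with pytest.raises(ValueError, match="masked"):
        str_encoder.encode(np.zeros((3, 32, 32)), np.zeros((4, 4), dtype=bool))


def test_wrong_input_side_is_error(str_encoder):
    with pytest.raises(ValueError, match="side"):
        str_encoder.encode(np.zeros((3, 64, 64)), np.ones((8, 8), dtype=bool))


def test_constant_map_pool_independent_of_valid_patch_count(str_encoder):
    """All-equal patch embeddings mean the pooled vector ignores the mask."""
    arr = np.full((3, 32, 32), 0.25)
    m1 = np.zeros((4, 4), dtype=bool)
    m1[:2, :2] = True
    m2 = np.ones((4, 4), dtype=bool)
    # position embeddings differ per patch, so equalise them first
    str_encoder.pos_emb.data = np.zeros_like(str_encoder.pos_emb.data)
    b1 = str_encoder.encode(arr, m1)
    b2 = str_encoder.encode(arr, m2)
    np.testing.assert_allclose(b1.protein_embedding, b2.protein_embedding, atol=1e-10)


# -- checkpointing -----------------------------------------------------------


def test_checkpoint_round_trip_bit_exact(tmp_path, seq_encoder, str_encoder):
    attach_structure_aware_modules(seq_encoder, top_k=1, seed=9)
    # make adapters nonzero so the round trip is nontrivial
    for layer in seq_encoder.layers:
        for stack in (layer.attn_adapters, layer.ffn_adapters):
            for a in stack.adapters:
                a.W_up.data = np.full_like(a.W_up.data, 0.01)
    tok = tokenize(ProteinRecord("p", "ACDEFGHIKL"), max_len=64)
    before = seq_encoder.encode(tok)
    save_checkpoint(tmp_path / "ck.zip", seq_encoder, str_encoder)
    seq2, str2, _ = load_checkpoint(tmp_path / "ck.zip")
    after = seq2.encode(tok)
    np.testing.assert_array_equal(before.projected, after.projected)
    for (n1, p1), (n2, p2) in zip(sorted(seq_encoder.named_parameters()),
                                  sorted(seq2.named_parameters())):
        assert n1 == n2
        np.testing.assert_array_equal(p1.data, p2.data)
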