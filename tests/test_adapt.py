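import numpy as np
import pytest

from seqstruct import (AdaptationSpec, SequenceEncoder, adapter_forward,
                       apply_strategy, count_strategy_params, count_trainable,
                       lora_forward, merge_parallel, tokenize)
from seqstruct.adapt import Adapter
from seqstruct.autodiff import SGD, Tensor
from seqstruct.contrast import multiview_loss_tensor
from seqstruct.downstream import DenseHead, TaskHeadSpec, train_head_with_encoder
from seqstruct.encoders import FULL_PROFILE
from seqstruct.seqio import pad_batch

from conftest import TEST_CONFIG


# -- functional forms --------------------------------------------------------


def test_lora_forward_zero_b_is_base():
    x = np.array([1.0, 2.0])
    W0 = np.array([[1.0, 0.0], [0.0, 1.0]])
    A = np.array([[0.5, 0.5]])
    B = np.zeros((2, 1))
    out = lora_forward(x, W0, A, B, alpha=8, r=1)
    np.testing.assert_allclose(out.data, x)


def test_lora_forward_scalar_case():
    out = lora_forward(1.0, 2.0, 3.0, 1.0, alpha=8, r=2)
    assert out.item() == pytest.approx(14.0)  # 2 + (8/2)*3


def test_lora_forward_zero_input():
    out = lora_forward(np.zeros(2), np.eye(2), np.ones((1, 2)), np.ones((2, 1)),
                       alpha=4, r=1)
    np.testing.assert_array_equal(out.data, np.zeros(2))


def test_lora_rank_bound_enforced():
    with pytest.raises(ValueError, match="rank"):
        lora_forward(np.zeros(2), np.eye(2), np.ones((3, 2)), np.ones((2, 3)),
                     alpha=1, r=3)


def test_lora_alpha_equal_r_is_unscaled():
    rng = np.random.default_rng(2)
    W0, A, B = rng.normal(size=(3, 3)), rng.normal(size=(2, 3)), rng.normal(size=(3, 2))
    x = rng.normal(size=3)
    out = lora_forward(x, W0, A, B, alpha=2, r=2)
    np.testing.assert_allclose(out.data, (W0 + B @ A) @ x, atol=1e-12)


def test_adapter_forward_zero_up_projection():
    out = adapter_forward(np.ones(3), np.ones((2, 3)), np.zeros(2),
                          np.zeros((3, 2)), np.zeros(3))
    np.testing.assert_array_equal(out.data, np.zeros(3))


def test_adapter_forward_scalar_case():
    out = adapter_forward(1.0, 2.0, -1.0, 3.0, 0.5)
    assert out.item() == pytest.approx(3.5)  # 3*ReLU(1) + 0.5


def test_adapter_forward_negative_preactivation_gives_bias():
    out = adapter_forward(np.ones(2), -np.ones((3, 2)), -np.ones(3),
                          np.ones((2, 3)), np.array([0.7, -0.2]))
    np.testing.assert_allclose(out.data, [0.7, -0.2])


def test_merge_parallel_definitions(rng):
    h = rng.normal(size=4)
    a1 = Adapter(4, 2, rng)
    a2 = Adapter(4, 2, rng)
    a1.W_up.data = rng.normal(size=(4, 2))
    a2.W_up.data = rng.normal(size=(4, 2))
    merged = merge_parallel(h, [a1, a2]).data
    expected = h + a1.increment(Tensor(h)).data + a2.increment(Tensor(h)).data
    np.testing.assert_allclose(merged, expected, atol=1e-12)

    zero = Adapter(4, 2, rng)  # W_up zero-init: identity after skip
    np.testing.assert_array_equal(merge_parallel(h, [zero]).data, h)


def test_merge_parallel_shape_mismatch():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="width"):
        merge_parallel(np.ones(4), [Adapter(4, 2, rng), Adapter(3, 2, rng)])


# -- strategy application ----------------------------------------------------


def test_finetune_all_layers_makes_encoder_layers_trainable():
    model = SequenceEncoder(TEST_CONFIG, seed=0)
    apply_strategy(model, AdaptationSpec("finetune_topK", K=TEST_CONFIG.n_layers))
    for layer in model.layers:
        assert all(p.requires_grad for p in layer.base_parameters())
    # embeddings/projector stay frozen under encoder-side topK
    assert not model.tok_emb.requires_grad


def test_topk_freezes_lower_layers():
    model = SequenceEncoder(TEST_CONFIG, seed=0)
    apply_strategy(model, AdaptationSpec("finetune_topK", K=1))
    assert not any(p.requires_grad for p in model.layers[0].base_parameters())
    assert all(p.requires_grad for p in model.layers[1].base_parameters())


def test_k_beyond_depth_is_error():
    model = SequenceEncoder(TEST_CONFIG, seed=0)
    with pytest.raises(ValueError, match="exceeds"):
        apply_strategy(model, AdaptationSpec("finetune_topK", K=99))


def test_empty_lora_targets_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        AdaptationSpec("lora", K=1, targets=())


def test_lora_strategy_trains_only_ab(rng):
    model = SequenceEncoder(TEST_CONFIG, seed=0)
    apply_strategy(model, AdaptationSpec("lora", K=1, r=2), rng)
    trainable = [n for n, p in model.named_parameters() if p.requires_grad]
    assert trainable and all(".lora." in n for n in trainable)


def test_frozen_parameters_get_exactly_zero_gradient(small_corpus):
    """Backward through a training loss leaves frozen leaves with no grad."""
    model = SequenceEncoder(TEST_CONFIG, seed=0)
    apply_strategy(model, AdaptationSpec("lora", K=1, r=2))
    ids, mask = pad_batch([tokenize(r, 32) for r in small_corpus[:4]])
    _, _, proj = model.forward_batch(ids, mask)
    loss, _ = multiview_loss_tensor(proj, proj + Tensor(np.ones_like(proj.data)), 0.5)
    loss.backward()
    for name, p in model.named_parameters():
        if p.requires_grad:
            assert p.grad is not None, name
        else:
            assert p.grad is None, name


# -- parameter accounting ----------------------------------------------------


def test_count_trainable_matches_closed_form_on_small_model():
    for spec in (AdaptationSpec("finetune_topK", K=1),
                 AdaptationSpec("lora", K=2, r=2),
                 AdaptationSpec("adapter", K=1, bottleneck=4)):
        model = SequenceEncoder(TEST_CONFIG, seed=0)
        apply_strategy(model, spec)
        walked = count_trainable(model)
        closed = count_strategy_params(TEST_CONFIG, spec)
        assert walked.trainable == closed.trainable, spec.strategy


def test_count_is_invariant_to_parameter_values():
    model = SequenceEncoder(TEST_CONFIG, seed=0)
    spec = AdaptationSpec("lora", K=1, r=2)
    apply_strategy(model, spec)
    before = count_trainable(model).trainable
    for p in model.parameters():
        p.data = p.data * 7.0 + 1.0
    assert count_trainable(model).trainable == before


def test_lora_closed_form_count_paper_profile():
    # r=2 on {Q,K,V,O} of top 16 layers at d=1280: 16 * 4 * (2*1280*2)
    spec = AdaptationSpec("lora", K=16, r=2)
    rep = count_strategy_params(FULL_PROFILE, spec)
    assert rep.per_component["encoder"] == 327_680
    rep = count_strategy_params(FULL_PROFILE, spec, head_out=1943)
    assert rep.per_component["head"] == 1280 * 1943 + 1943 == 2_488_983
    assert rep.trainable == 2_816_663


def test_continual_learning_adapter_training_leaves_base_intact(small_corpus):
    """Train only a task adapter; removing it restores the base bit-exactly."""
    model = SequenceEncoder(TEST_CONFIG, seed=0)
    toks = [tokenize(r, 32) for r in small_corpus[:6]]
    ids, mask = pad_batch(toks)
    base_out = model.forward_batch(ids, mask, adapters_enabled=False)[2].data.copy()

    apply_strategy(model, AdaptationSpec("adapter", K=2, bottleneck=4))
    head = DenseHead(TEST_CONFIG.embed_dim, 3, seed=1)
    y = np.array([0, 0, 1, 1, 2, 2])
    train_head_with_encoder(model, (ids, mask), y,
                            TaskHeadSpec("protein", 3, "focal_multiclass"),
                            strategy=AdaptationSpec("adapter", K=2, bottleneck=4),
                            epochs=3, lr=1e-2)
    # adapters have actually moved
    moved = any(np.abs(a.W_up.data).sum() > 0
                for layer in model.layers
                for stack in (layer.attn_adapters, layer.ffn_adapters)
                for a in stack.adapters)
    assert moved
    disabled = model.forward_batch(ids, mask, adapters_enabled=False)[2].data
    np.testing.assert_array_equal(disabled, base_out)


def test_lora_training_disabled_restores_base(small_corpus):
    model = SequenceEncoder(TEST_CONFIG, seed=0)
    toks = [tokenize(r, 32) for r in small_corpus[:4]]
    ids, mask = pad_batch(toks)
    base_out = model.forward_batch(ids, mask, lora_enabled=False)[2].data.copy()

    apply_strategy(model, AdaptationSpec("lora", K=2, r=2))
    params = model.trainable_parameters()
    opt = SGD(params, lr=0.05)
    for _ in range(3):
        _, _, proj = model.forward_batch(ids, mask)
        loss = (proj * proj).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert any(np.abs(p.grad if p.grad is not None else 0).sum() >= 0 for p in params)
    restored = model.forward_batch(ids, mask, lora_enabled=False)[2].data
    np.testing.assert_array_equal(restored, base_out)
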