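"""Contrastive pretraining loop for the twin encoders.

Defaults mirror the published training recipe: two separate SGD optimizers
(momentum 0.9) for the sequence and structure sides, a sawtooth cyclic
learning rate falling linearly from 1e-3 to 0 over 100 steps then
restarting, batch size 20, weight decay 5e-4, gradient-norm clipping at
1.0, temperature 0.05, 512-residue truncation.  The sequence base stays
frozen; only its structure-aware adapter modules (and projector) train.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import seqio, structmap
from .adapt import Adapter
from .autodiff import SGD, Adam, clip_grad_norm
from .contrast import DEFAULT_TAU, multiview_loss_tensor
from .encoders import SequenceEncoder, StructureEncoder, save_checkpoint
from .seqio import ProteinRecord


@dataclass
class PretrainConfig:
    batch_size: int = 20
    tau: float = DEFAULT_TAU
    lr_max: float = 0.001
    cycle_steps: int = 100
    momentum: float = 0.9
    weight_decay: float = 0.0005
    grad_clip_norm: float = 1.0
    max_len: int = 512
    epochs: int = 5
    seed: int = 0
    mixed_precision: bool = False  # single-precision arithmetic when True
    optimizer: str = "sgd"         # {"sgd", "adam"}; momentum applies to sgd
    adapter_top_k: int | None = None      # None -> all layers
    adapter_bottleneck: int | None = None  # None -> embed_dim // 2

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("contrastive training needs batch_size >= 2")
        if self.optimizer not in {"sgd", "adam"}:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def lr_at(step: int, cfg: PretrainConfig) -> float:
    """Sawtooth schedule: linear decay to 0 over a cycle, instant restart."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return cfg.lr_max * (1.0 - (step % cfg.cycle_steps) / cfg.cycle_steps)


def attach_structure_aware_modules(seq_encoder: SequenceEncoder,
                                   top_k: int | None = None,
                                   bottleneck: int | None = None,
                                   seed: int = 0) -> SequenceEncoder:
    """Freeze the sequence base and insert trainable adapter modules.

    Adapters go into the top ``top_k`` layers (both slots); the projector
    stays trainable so the contrastive space can form.  The frozen base plus
    zero-initialised adapters reproduce the base model's outputs exactly
    until the first optimizer step.
    """
    cfg = seq_encoder.config
    top_k = cfg.n_layers if top_k is None else top_k
    if not (1 <= top_k <= cfg.n_layers):
        raise ValueError(f"top_k must be in [1, {cfg.n_layers}]")
    m = bottleneck or max(1, cfg.embed_dim // 2)
    rng = np.random.default_rng(seed)
    for p in seq_encoder.parameters():
        p.requires_grad = False
    for layer in seq_encoder.layers[cfg.n_layers - top_k:]:
        for stack in (layer.attn_adapters, layer.ffn_adapters):
            a = Adapter(cfg.embed_dim, m, rng, seq_encoder.dtype)
            a.set_trainable(True)
            stack.append(a)
    for p in seq_encoder.projector.parameters():
        p.requires_grad = True
    return seq_encoder


def _prepare_inputs(records: list[ProteinRecord], cfg: PretrainConfig,
                    str_encoder: StructureEncoder):
    """Tokenize and featurize once up front."""
    toks, maps, masks = [], [], []
    side = str_encoder.config.input_side
    patch = str_encoder.config.patch_size
    for rec in records:
        if rec.coords is None:
            raise ValueError(f"protein {rec.id!r} has no coordinates; "
                             "pretraining needs paired structures")
        toks.append(seqio.tokenize(rec, cfg.max_len))
        cmap = structmap.contact_map_for(rec, max_len=cfg.max_len)
        arr, mask = structmap.resize_for_encoder(cmap, side, patch)
        maps.append(arr)
        masks.append(mask)
    return toks, np.stack(maps), np.stack(masks)


def train(records: list[ProteinRecord], cfg: PretrainConfig,
          seq_encoder: SequenceEncoder, str_encoder: StructureEncoder,
          checkpoint_path: str | Path | None = None,
          log_path: str | Path | None = None) -> list[dict]:
    """Run the contrastive loop; returns the per-step metrics log.

    Incomplete trailing batches are dropped (the loss needs N >= 2).
    Deterministic for a fixed config seed.
    """
    if cfg.mixed_precision:
        for model in (seq_encoder, str_encoder):
            for p in model.parameters():
                p.data = p.data.astype(np.float32)

    toks, maps, patch_masks = _prepare_inputs(records, cfg, str_encoder)

    seq_params = seq_encoder.trainable_parameters()
    str_params = [p for p in str_encoder.parameters()]
    for p in str_params:
        p.requires_grad = True
    if cfg.optimizer == "adam":
        opt_seq = Adam(seq_params, lr=cfg.lr_max, weight_decay=cfg.weight_decay)
        opt_str = Adam(str_params, lr=cfg.lr_max, weight_decay=cfg.weight_decay)
    else:
        opt_seq = SGD(seq_params, lr=cfg.lr_max, momentum=cfg.momentum,
                      weight_decay=cfg.weight_decay)
        opt_str = SGD(str_params, lr=cfg.lr_max, momentum=cfg.momentum,
                      weight_decay=cfg.weight_decay)

    rng = np.random.default_rng(cfg.seed)
    n = len(records)
    log: list[dict] = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            ids, mask = seqio.pad_batch([toks[i] for i in idx])
            _, _, seq_proj = seq_encoder.forward_batch(ids, mask)
            _, _, str_proj = str_encoder.forward_batch(maps[idx], patch_masks[idx])
            loss, _ = multiview_loss_tensor(seq_proj, str_proj, cfg.tau)
            opt_seq.zero_grad()
            opt_str.zero_grad()
            loss.backward()
            clip_grad_norm(seq_params, cfg.grad_clip_norm)
            clip_grad_norm(str_params, cfg.grad_clip_norm)
            lr = lr_at(step, cfg)
            opt_seq.lr = lr
            opt_str.lr = lr
            opt_seq.step()
            opt_str.step()
            log.append({"step": step, "epoch": epoch, "lr": lr,
                        "loss": float(loss.item())})
            step += 1

    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, seq_encoder, str_encoder,
                        extra={"pretrain_steps": step})
    if log_path is not None:
        write_metrics_log(log, log_path)
    return log


def write_metrics_log(log: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tepoch\tlr\tloss\n")
        for row in log:
            fh.write(f"{row['step']}\t{row['epoch']}\t{row['lr']:.6g}\t{row['loss']:.6g}\n")
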