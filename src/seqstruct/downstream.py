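"""Task heads, losses and metrics for supervised protein prediction.

Five task families are preset: fold classification (1195-way, focal loss),
enzyme-reaction classification (384-way, focal), GO term prediction
(multilabel BCE; 1943/489/320 labels for BP/MF/CC), EC number prediction
(538 labels, BCE), and 3-state secondary structure (residue-level, focal,
1022-residue truncation).  Each head is a single dense layer on top of
either pooled protein embeddings or per-residue embeddings.

Fmax follows the protein-centric CAFA convention: precision at threshold t
averages over proteins with at least one predicted label, recall averages
over all proteins, and a label is predicted when its score exceeds t
(strictly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adapt import AdaptationSpec, apply_strategy
from .autodiff import Adam, Parameter, Tensor, relu, softmax
from .encoders import Module, SequenceEncoder

FOCAL_EPS = 1e-12  # clamp for log(p_t); documents the p_t = 0 behaviour
DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


@dataclass
class TaskHeadSpec:
    level: str      # {"protein", "residue"}
    out_dim: int
    loss: str       # {"focal_multiclass", "bce_multilabel"}
    max_len: int = 512

    def __post_init__(self):
        if self.level not in {"protein", "residue"}:
            raise ValueError("level must be 'protein' or 'residue'")
        if self.loss not in {"focal_multiclass", "bce_multilabel"}:
            raise ValueError("unknown loss")


TASK_PRESETS: dict[str, TaskHeadSpec] = {
    "fold": TaskHeadSpec("protein", 1195, "focal_multiclass", 512),
    "reaction": TaskHeadSpec("protein", 384, "focal_multiclass", 512),
    "go-bp": TaskHeadSpec("protein", 1943, "bce_multilabel", 512),
    "go-mf": TaskHeadSpec("protein", 489, "bce_multilabel", 512),
    "go-cc": TaskHeadSpec("protein", 320, "bce_multilabel", 512),
    "ec": TaskHeadSpec("protein", 538, "bce_multilabel", 512),
    "ss": TaskHeadSpec("residue", 3, "focal_multiclass", 1022),
}


# -- losses ------------------------------------------------------------------


def focal_loss(probs: np.ndarray, targets: np.ndarray, gamma: float = 2.0) -> float:
    """Batch-averaged −(1 − p_t)^γ log p_t; γ=0 recovers cross-entropy."""
    probs = np.asarray(probs, dtype=float)
    targets = np.asarray(targets, dtype=int)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if probs.ndim == 1:
        probs = probs[None]
        targets = np.atleast_1d(targets)
    p_t = np.clip(probs[np.arange(len(targets)), targets], FOCAL_EPS, 1.0)
    return float(np.mean(-((1.0 - p_t) ** gamma) * np.log(p_t)))


def multilabel_bce(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean logistic cross-entropy over every (protein, label) entry."""
    x = np.asarray(logits, dtype=float)
    t = np.asarray(targets, dtype=float)
    if x.shape != t.shape:
        raise ValueError("logits/targets shape mismatch")
    # stable: max(x,0) - x*t + log(1 + exp(-|x|))
    return float(np.mean(np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))))


def _focal_loss_tensor(logits: Tensor, targets: np.ndarray, gamma: float) -> Tensor:
    probs = softmax(logits, axis=-1)
    p_t = probs[np.arange(len(targets)), np.asarray(targets, dtype=int)]
    p_t = p_t + FOCAL_EPS
    return (((1.0 - p_t) ** gamma) * -(p_t.log())).mean()


def _bce_tensor(logits: Tensor, targets: np.ndarray) -> Tensor:
    t = Tensor(np.asarray(targets, dtype=float))
    ax = relu(logits) + relu(-logits)  # |x|
    return (relu(logits) - logits * t + ((-ax).exp() + 1.0).log()).mean()


# -- metrics -----------------------------------------------------------------


def fmax(scores: np.ndarray, truth: np.ndarray,
         thresholds: np.ndarray = DEFAULT_THRESHOLD_GRID) -> float:
    """Protein-centric maximum F1 over a score-threshold grid (CAFA style)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores/truth shape mismatch")
    if truth.sum() == 0:
        raise ValueError("no positive truth labels")
    n = truth.shape[0]
    best = 0.0
    for t in np.asarray(thresholds, dtype=float):
        pred = scores > t
        has_pred = pred.any(axis=1)
        if not has_pred.any():
            continue
        tp = (pred & truth).sum(axis=1).astype(float)
        prec = float(np.mean(tp[has_pred] / pred.sum(axis=1)[has_pred]))
        denom_rc = truth.sum(axis=1).astype(float)
        rc = float(np.mean(np.divide(tp, denom_rc, out=np.zeros(n),
                                     where=denom_rc > 0)))
        if prec + rc > 0:
            best = max(best, 2 * prec * rc / (prec + rc))
    return best


def residue_accuracy(pred: np.ndarray, true: np.ndarray, mask: np.ndarray) -> float:
    """Percent correct over mask-true residues."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != true.shape or pred.shape != mask.shape:
        raise ValueError("shape mismatch")
    if mask.sum() == 0:
        raise ValueError("empty mask")
    return float(100.0 * np.mean(pred[mask] == true[mask]))


# -- heads and training ------------------------------------------------------


class DenseHead(Module):
    """Single dense classification layer."""

    def __init__(self, d_in: int, out_dim: int, seed: int = 0, dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.W = Parameter(rng.normal(0.0, 0.02, (d_in, out_dim)).astype(dtype))
        self.b = Parameter(np.zeros(out_dim, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


def _head_loss(spec: TaskHeadSpec, logits: Tensor, labels: np.ndarray,
               gamma: float) -> Tensor:
    if spec.loss == "focal_multiclass":
        return _focal_loss_tensor(logits, labels, gamma)
    return _bce_tensor(logits, labels)


def train_head(features: np.ndarray, labels: np.ndarray, spec: TaskHeadSpec,
               epochs: int = 100, lr: float = 1e-2, gamma: float = 2.0,
               seed: int = 0, batch_size: int | None = None) -> tuple[DenseHead, float]:
    """Train a dense head on fixed (frozen-encoder) features with Adam.

    ``features``: (N, D) pooled embeddings for protein-level tasks, or
    (R, D) per-residue embeddings (already mask-filtered) for residue-level.
    Returns the head and its final training metric (accuracy % for
    multiclass, Fmax for multilabel).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if spec.loss == "focal_multiclass":
        if y.ndim != 1:
            raise ValueError(f"{spec.level}-level multiclass task expects 1-D labels")
        if y.max() >= spec.out_dim:
            raise ValueError("label index exceeds head output dimension")
    else:
        if y.ndim != 2 or y.shape[1] != spec.out_dim:
            raise ValueError("multilabel task expects (N, out_dim) binary targets")
    head = DenseHead(x.shape[1], spec.out_dim, seed=seed)
    opt = Adam(head.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    bs = batch_size or n
    for _ in range(epochs):
        order = rng.permutation(n)
        for s in range(0, n, bs):
            idx = order[s:s + bs]
            logits = head(Tensor(x[idx]))
            loss = _head_loss(spec, logits, y[idx], gamma)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return head, evaluate_head(head, x, y, spec)


def evaluate_head(head: DenseHead, features: np.ndarray, labels: np.ndarray,
                  spec: TaskHeadSpec) -> float:
    logits = head(Tensor(np.asarray(features, dtype=float))).data
    if spec.loss == "focal_multiclass":
        pred = logits.argmax(axis=-1)
        return float(100.0 * np.mean(pred == np.asarray(labels)))
    scores = 1.0 / (1.0 + np.exp(-logits))
    return fmax(scores, labels)


def train_head_with_encoder(encoder: SequenceEncoder, tokens_batch,
                            labels: np.ndarray, spec: TaskHeadSpec,
                            strategy: AdaptationSpec | str = "fix",
                            epochs: int = 5, lr: float = 1e-3, gamma: float = 2.0,
                            seed: int = 0) -> tuple[SequenceEncoder, DenseHead, float]:
    """Joint encoder+head training under a lightweight-tuning strategy.

    ``strategy='fix'`` freezes the whole encoder (head only); otherwise an
    :class:`AdaptationSpec` selects top-K fine-tuning, LoRA or adapters.
    ``tokens_batch`` is a prepared (ids, mask) pair covering all proteins.
    """
    ids, mask = tokens_batch
    y = np.asarray(labels)
    if strategy == "fix":
        for p in encoder.parameters():
            p.requires_grad = False
    else:
        apply_strategy(encoder, strategy, np.random.default_rng(seed))
    head = DenseHead(encoder.config.embed_dim, spec.out_dim, seed=seed,
                     dtype=encoder.dtype)
    params = encoder.trainable_parameters() + head.parameters()
    opt = Adam(params, lr=lr)
    d = encoder.config.embed_dim

    def forward_features():
        resid, pooled, _ = encoder.forward_batch(ids, mask)
        if spec.level == "residue":
            return resid.reshape(-1, d)[mask.reshape(-1)]
        return pooled

    for _ in range(epochs):
        logits = head(forward_features())
        loss = _head_loss(spec, logits, y, gamma)
        opt.zero_grad()
        loss.backward()
        opt.step()
    metric = evaluate_head(head, forward_features().data, y, spec)
    return encoder, head, metric
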