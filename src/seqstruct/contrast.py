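"""Multi-view contrastive loss over paired sequence/structure projections.

For a batch of N proteins with projected sequence embeddings s_i and
structure embeddings c_i, the per-protein loss is

    L_i = -log  exp(sim(s_i, c_i)/τ) /
                Σ_{k≠i} [ exp(sim(s_i, c_k)/τ) + exp(sim(s_i, s_k)/τ)
                        + exp(sim(c_i, c_k)/τ) ]

a temperature-scaled cross-entropy (NT-Xent family) with the CLIP-style
cross-modal repulsion plus two intra-modality repulsion terms.  As written,
the positive pair is *excluded* from the denominator — unlike standard
NT-Xent; ``include_positive_in_denominator=True`` switches to the standard
variant.  The loss is sequence-anchored; ``symmetrize=True`` averages it
with the structure-anchored mirror.

A deliberately naive double-loop reference (:func:`multiview_loss_reference`)
is kept alongside as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, logsumexp

DEFAULT_TAU = 0.05
_MASKED = -1e30


@dataclass
class ContrastBatch:
    seq_proj: np.ndarray  # (N, dim)
    str_proj: np.ndarray  # (N, dim)
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        self.seq_proj = np.asarray(self.seq_proj, dtype=float)
        self.str_proj = np.asarray(self.str_proj, dtype=float)
        if self.seq_proj.shape != self.str_proj.shape:
            raise ValueError("seq_proj and str_proj must have matching shapes")
        if self.seq_proj.ndim != 2 or self.seq_proj.shape[0] < 2:
            raise ValueError("contrastive batch needs N >= 2 proteins")
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")


@dataclass
class LossBreakdown:
    per_pair: np.ndarray
    batch_loss: float


def cosine_sim(x: np.ndarray, y: np.ndarray) -> float:
    """sim(x, y) = xᵀy / (‖x‖‖y‖); errors on a zero vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(x @ y / (nx * ny))


def _normalize_rows(x: Tensor) -> Tensor:
    norms = np.linalg.norm(x.data, axis=-1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm embedding row")
    sq = (x * x).sum(axis=-1, keepdims=True)
    return x * (sq ** -0.5)


def multiview_loss_tensor(seq_proj: Tensor, str_proj: Tensor,
                          tau: float = DEFAULT_TAU,
                          include_positive_in_denominator: bool = False,
                          symmetrize: bool = False) -> tuple[Tensor, Tensor]:
    """Differentiable loss; returns (batch_loss scalar, per-pair vector)."""
    N = seq_proj.shape[0]
    if N < 2:
        raise ValueError("contrastive batch needs N >= 2 proteins")
    if tau <= 0:
        raise ValueError("temperature tau must be > 0")

    def anchored(a: Tensor, b: Tensor) -> Tensor:
        an = _normalize_rows(a)
        bn = _normalize_rows(b)
        s_cross = an @ bn.swapaxes(0, 1)       # sim(a_i, b_k)
        s_aa = an @ an.swapaxes(0, 1)          # sim(a_i, a_k)
        s_bb = bn @ bn.swapaxes(0, 1)          # sim(b_i, b_k)
        idx = np.arange(N)
        pos = s_cross[idx, idx]
        off_diag = np.where(np.eye(N, dtype=bool), _MASKED * tau, 0.0)
        cross_mask = np.zeros((N, N)) if include_positive_in_denominator else off_diag
        terms = [
            s_cross + Tensor(cross_mask),
            s_aa + Tensor(off_diag),
            s_bb + Tensor(off_diag),
        ]
        all_terms = concat(terms, axis=1) * (1.0 / tau)
        return -(pos * (1.0 / tau)) + logsumexp(all_terms, axis=1)

    per_pair = anchored(seq_proj, str_proj)
    if symmetrize:
        per_pair = (per_pair + anchored(str_proj, seq_proj)) * 0.5
    return per_pair.mean(), per_pair


def multiview_loss(batch: ContrastBatch,
                   include_positive_in_denominator: bool = False,
                   symmetrize: bool = False) -> LossBreakdown:
    loss, per_pair = multiview_loss_tensor(
        Tensor(batch.seq_proj), Tensor(batch.str_proj), batch.tau,
        include_positive_in_denominator, symmetrize)
    return LossBreakdown(per_pair=per_pair.data.copy(), batch_loss=loss.item())


def multiview_loss_reference(seq_proj: np.ndarray, str_proj: np.ndarray,
                             tau: float = DEFAULT_TAU,
                             include_positive_in_denominator: bool = False) -> LossBreakdown:
    """Naive double-loop evaluation; kept independent of the fast path."""
    seq_proj = np.asarray(seq_proj, dtype=float)
    str_proj = np.asarray(str_proj, dtype=float)
    N = seq_proj.shape[0]
    if N < 2:
        raise ValueError("contrastive batch needs N >= 2 proteins")
    losses = []
    for i in range(N):
        num = math.exp(cosine_sim(seq_proj[i], str_proj[i]) / tau)
        den = 0.0
        for k in range(N):
            if k == i:
                if include_positive_in_denominator:
                    den += math.exp(cosine_sim(seq_proj[i], str_proj[k]) / tau)
                continue
            den += math.exp(cosine_sim(seq_proj[i], str_proj[k]) / tau)
            den += math.exp(cosine_sim(seq_proj[i], seq_proj[k]) / tau)
            den += math.exp(cosine_sim(str_proj[i], str_proj[k]) / tau)
        losses.append(-math.log(num / den))
    per_pair = np.array(losses)
    return LossBreakdown(per_pair=per_pair, batch_loss=float(per_pair.mean()))


def loss_gradient_check(batch: ContrastBatch, h: float = 1e-6,
                        include_positive_in_denominator: bool = False) -> float:
    """Max relative disagreement between analytic and central-difference grads."""
    seq = Tensor(batch.seq_proj.copy(), requires_grad=True)
    stc = Tensor(batch.str_proj.copy(), requires_grad=True)
    loss, _ = multiview_loss_tensor(seq, stc, batch.tau,
                                    include_positive_in_denominator)
    loss.backward()
    worst = 0.0
    for arr, grad in ((batch.seq_proj, seq.grad), (batch.str_proj, stc.grad)):
        num = np.zeros_like(arr)
        flat = arr.reshape(-1)
        for j in range(flat.size):
            orig = flat[j]
            flat[j] = orig + h
            lp = multiview_loss(ContrastBatch(batch.seq_proj, batch.str_proj, batch.tau),
                                include_positive_in_denominator).batch_loss
            flat[j] = orig - h
            lm = multiview_loss(ContrastBatch(batch.seq_proj, batch.str_proj, batch.tau),
                                include_positive_in_denominator).batch_loss
            flat[j] = orig
            num.reshape(-1)[j] = (lp - lm) / (2 * h)
        rel = np.abs(grad - num) / np.maximum(np.abs(grad) + np.abs(num), 1e-8)
        worst = max(worst, float(rel.max()))
    return worst
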