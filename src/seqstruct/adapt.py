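"""Lightweight-tuning toolbox: top-K fine-tuning, LoRA, bottleneck adapters.

Three ways of adapting a frozen transformer encoder:

* **fine-tune top-K** — unfreeze the top K transformer layers outright;
* **LoRA** — keep every base weight W0 frozen and learn a rank-r update
  ``h = W0 x + (alpha / r) * B A x`` on selected attention projections;
* **adapters** — insert bottleneck modules ``a(h) = W_up σ(W_down h + b_down)
  + b_up`` (σ = ReLU) with a shared skip connection, twice per layer.  Several
  adapters can run in parallel, ``h' = h + Σ_i a_i(h)``, with at most the
  newest one trainable — earlier ones (e.g. a structure-aware module learned
  during contrastive pretraining) stay frozen, so removing the new adapter
  restores the previous model bit-for-bit.

The module also does exact trainable-parameter accounting, both by walking a
concrete model's flags and in closed form for an architecture profile that is
never instantiated (e.g. a 33-layer, 1280-dim encoder).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Parameter, Tensor, relu

ATTENTION_TARGETS = ("query", "key", "value", "output")


@dataclass
class AdaptationSpec:
    """Which tuning strategy to use and its hyperparameters."""

    strategy: str  # {"finetune_topK", "lora", "adapter"}
    K: int = 1
    r: int = 2
    alpha: float = 8.0
    bottleneck: int | None = None  # adapter hidden width; None -> embed_dim // 2
    targets: tuple[str, ...] = ATTENTION_TARGETS
    n_parallel: int = 1

    def __post_init__(self):
        if self.strategy not in {"finetune_topK", "lora", "adapter"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.r < 1:
            raise ValueError("LoRA rank r must be >= 1")
        if self.bottleneck is not None and self.bottleneck < 1:
            raise ValueError("adapter bottleneck must be >= 1")
        self.targets = tuple(self.targets)
        if self.strategy == "lora":
            if not self.targets:
                raise ValueError("lora requires a non-empty projection target set")
            bad = set(self.targets) - set(ATTENTION_TARGETS)
            if bad:
                raise ValueError(f"unknown LoRA targets {sorted(bad)}")


@dataclass
class ParamReport:
    """Exact trainable/frozen parameter counts, per component and total."""

    per_component: dict[str, int]
    trainable: int
    frozen: int

    @property
    def total(self) -> int:
        return self.trainable + self.frozen

    def __str__(self) -> str:
        lines = [f"{name:40s} {n:>12,d}" for name, n in self.per_component.items()]
        lines.append(f"{'trainable':40s} {self.trainable:>12,d}")
        lines.append(f"{'frozen':40s} {self.frozen:>12,d}")
        lines.append(f"{'total':40s} {self.total:>12,d}")
        return "\n".join(lines)


# -- functional forms --------------------------------------------------------


def _coerce(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def lora_forward(x, W0, A, B, alpha: float, r: int):
    """``W0 x + (alpha/r) * B A x`` with W0 (d×k), A (r×k), B (d×r)."""
    x, W0, A, B = map(_coerce, (x, W0, A, B))
    if W0.ndim == 0:  # scalar convenience form
        return W0 * x + (alpha / r) * (B * (A * x))
    d, k = W0.shape
    if r > min(d, k):
        raise ValueError(f"LoRA rank r={r} exceeds min(d,k)={min(d, k)}")
    return W0 @ x + (alpha / r) * (B @ (A @ x))


def adapter_forward(h, W_down, b_down, W_up, b_up):
    """Bottleneck increment a(h) = W_up · ReLU(W_down · h + b_down) + b_up.

    Returns the increment only; the caller adds the skip connection.
    """
    h, W_down, b_down, W_up, b_up = map(_coerce, (h, W_down, b_down, W_up, b_up))
    if W_down.ndim == 0:  # scalar convenience form
        return W_up * relu(W_down * h + b_down) + b_up
    return W_up @ relu(W_down @ h + b_down) + b_up


def merge_parallel(h, adapters: Sequence["Adapter"]):
    """Shared-skip merge of N parallel adapters: h' = h + Σ_i a_i(h)."""
    if len(adapters) < 1:
        raise ValueError("need at least one adapter")
    dims = {a.dim for a in adapters}
    if len(dims) != 1:
        raise ValueError(f"parallel adapters disagree on width: {sorted(dims)}")
    h = _coerce(h)
    out = h
    for a in adapters:
        out = out + a.increment(h)
    return out


# -- module classes ----------------------------------------------------------


class Adapter:
    """Bottleneck adapter; identity at initialisation (W_up = b_up = 0)."""

    def __init__(self, dim: int, bottleneck: int, rng: np.random.Generator,
                 dtype=np.float64, name: str = "adapter"):
        self.dim = dim
        self.bottleneck = bottleneck
        self.name = name
        self.W_down = Parameter(rng.normal(0.0, 0.02, (bottleneck, dim)).astype(dtype))
        self.b_down = Parameter(np.zeros(bottleneck, dtype=dtype))
        self.W_up = Parameter(np.zeros((dim, bottleneck), dtype=dtype))
        self.b_up = Parameter(np.zeros(dim, dtype=dtype))

    def increment(self, h: Tensor) -> Tensor:
        """a(h) for h of shape (..., dim); row-major batched."""
        z = relu(h @ self.W_down.swapaxes(0, 1) + self.b_down)
        return z @ self.W_up.swapaxes(0, 1) + self.b_up

    def parameters(self):
        return [self.W_down, self.b_down, self.W_up, self.b_up]

    def named_parameters(self, prefix=""):
        yield from ((prefix + n, p) for n, p in
                    zip(("W_down", "b_down", "W_up", "b_up"), self.parameters()))

    def set_trainable(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag


class ParallelAdapters:
    """An ordered stack of parallel adapters sharing one skip connection."""

    def __init__(self, adapters: Sequence[Adapter] | None = None):
        self.adapters: list[Adapter] = list(adapters or [])

    def append(self, adapter: Adapter):
        self.adapters.append(adapter)

    def __len__(self):
        return len(self.adapters)

    def __call__(self, h: Tensor) -> Tensor:
        if not self.adapters:
            return h
        return merge_parallel(h, self.adapters)

    def parameters(self):
        return [p for a in self.adapters for p in a.parameters()]

    def named_parameters(self, prefix=""):
        for i, a in enumerate(self.adapters):
            yield from a.named_parameters(f"{prefix}{i}.")


class LoRADelta:
    """Trainable rank-r update attached to a frozen linear weight.

    A is Gaussian-initialised, B is zero, so training starts at the base
    model exactly.
    """

    def __init__(self, d: int, k: int, r: int, alpha: float,
                 rng: np.random.Generator, dtype=np.float64):
        if r > min(d, k):
            raise ValueError(f"LoRA rank r={r} exceeds min(d,k)={min(d, k)}")
        self.r = r
        self.alpha = alpha
        self.A = Parameter(rng.normal(0.0, 0.02, (r, k)).astype(dtype))
        self.B = Parameter(np.zeros((d, r), dtype=dtype))

    def delta(self, x: Tensor) -> Tensor:
        """(alpha/r) * B A x for x of shape (..., k)."""
        return (self.alpha / self.r) * ((x @ self.A.swapaxes(0, 1)) @ self.B.swapaxes(0, 1))

    def parameters(self):
        return [self.A, self.B]

    def named_parameters(self, prefix=""):
        yield prefix + "A", self.A
        yield prefix + "B", self.B


# -- strategy application ----------------------------------------------------


def apply_strategy(model, spec: AdaptationSpec, rng: np.random.Generator | None = None):
    """Set trainable/frozen flags on a sequence encoder per the chosen strategy.

    ``model`` must expose ``config.n_layers``, ``layers`` (each with an
    ``attn`` holding query/key/value/output linears and adapter slots), and
    ``parameters()``.  The model is modified in place and returned; any task
    head on top is the caller's responsibility (heads are always trainable).
    """
    n_layers = model.config.n_layers
    if spec.K > n_layers:
        raise ValueError(f"K={spec.K} exceeds the encoder's {n_layers} layers")
    rng = rng or np.random.default_rng(0)

    for p in model.parameters():
        p.requires_grad = False

    top = range(n_layers - spec.K, n_layers)
    if spec.strategy == "finetune_topK":
        for i in top:
            for p in model.layers[i].base_parameters():
                p.requires_grad = True
    elif spec.strategy == "lora":
        dim = model.config.embed_dim
        dtype = model.dtype
        for i in top:
            attn = model.layers[i].attn
            for tgt in spec.targets:
                lin = attn.target_linear(tgt)
                if lin.lora is None:
                    lin.lora = LoRADelta(dim, dim, spec.r, spec.alpha, rng, dtype)
                for p in lin.lora.parameters():
                    p.requires_grad = True
    elif spec.strategy == "adapter":
        dim = model.config.embed_dim
        m = spec.bottleneck or max(1, dim // 2)
        dtype = model.dtype
        for i in top:
            layer = model.layers[i]
            for stack in (layer.attn_adapters, layer.ffn_adapters):
                a = Adapter(dim, m, rng, dtype)
                a.set_trainable(True)
                stack.append(a)
    return model


def count_trainable(model, head=None) -> ParamReport:
    """Walk a concrete model's parameter flags and count exactly."""
    per: dict[str, int] = {}
    trainable = frozen = 0
    for name, p in model.named_parameters():
        n = int(p.data.size)
        if p.requires_grad:
            trainable += n
            comp = name.split(".")[0]
            per[comp] = per.get(comp, 0) + n
        else:
            frozen += n
    if head is not None:
        for name, p in head.named_parameters():
            n = int(p.data.size)
            trainable += n
            per["head"] = per.get("head", 0) + n
    return ParamReport(per, trainable, frozen)


# -- closed-form accounting for uninstantiated profiles ----------------------


def _per_layer_base_params(embed_dim: int, ffn_dim: int) -> int:
    attn = 4 * (embed_dim * embed_dim + embed_dim)           # Q, K, V, O with biases
    ffn = (embed_dim * ffn_dim + ffn_dim) + (ffn_dim * embed_dim + embed_dim)
    norms = 2 * 2 * embed_dim                                # two LayerNorms, weight+bias
    return attn + ffn + norms


def count_strategy_params(config, spec: AdaptationSpec,
                          head_in: int | None = None,
                          head_out: int | None = None) -> ParamReport:
    """Closed-form trainable count for an encoder profile + optional dense head.

    Counting convention: biases and LayerNorm weights count; LoRA matrices
    carry no biases.  ``config`` needs ``n_layers``, ``embed_dim``, ``ffn_dim``.
    """
    if spec.K > config.n_layers:
        raise ValueError("K exceeds n_layers")
    d, f = config.embed_dim, config.ffn_dim
    per: dict[str, int] = {}
    if spec.strategy == "finetune_topK":
        per["encoder"] = spec.K * _per_layer_base_params(d, f)
    elif spec.strategy == "lora":
        per["encoder"] = spec.K * len(spec.targets) * (2 * d * spec.r)
    elif spec.strategy == "adapter":
        m = spec.bottleneck or max(1, d // 2)
        per_adapter = 2 * d * m + m + d
        per["encoder"] = spec.K * 2 * per_adapter
    if head_out is not None:
        head_in = head_in if head_in is not None else d
        per["head"] = head_in * head_out + head_out
    trainable = sum(per.values())
    total_base = config.n_layers * _per_layer_base_params(d, f)
    return ParamReport(per, trainable, frozen=total_base - per.get("encoder", 0)
                       if spec.strategy == "finetune_topK" else total_base)
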