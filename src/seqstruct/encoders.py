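"""Twin encoders: a sequence transformer and a patch-based contact-map encoder.

Both encoders end in masked mean pooling (BEGIN/END/PAD tokens and padding
patches are excluded) followed by a modality-specific two-layer projector
into a shared 256-dimensional contrastive space.

The sequence encoder is a pre-LayerNorm transformer whose top-K layers can
carry structure-aware bottleneck adapters and/or LoRA deltas on the
attention projections (see :mod:`seqstruct.adapt`).  With every adapter at
its zero initialisation and LoRA disabled, the forward pass is bit-identical
to the plain base encoder — the continual-learning guarantee the whole
tuning toolbox rests on.

The structure encoder is a small vision transformer over non-overlapping
patches of the 3-channel contact map.  Any hierarchical patch encoder
honouring the same input/masking contract would do; a plain ViT keeps the
desk-scale artifact simple.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import seqio
from .adapt import ParallelAdapters
from .autodiff import Parameter, Tensor, gelu, relu, softmax
from .seqio import PAD_ID, VOCAB_SIZE, TokenSeq

PROJECTED_DIM = 256


@dataclass
class EncoderConfig:
    n_layers: int = 2
    embed_dim: int = 32
    ffn_dim: int = 64
    n_heads: int = 4
    max_len: int = 512
    # structure-encoder-only fields
    patch_size: int = 8
    input_side: int = 64

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.input_side % self.patch_size != 0:
            raise ValueError("input_side must be divisible by patch_size")


#: Small profile: pretrains on synthetic corpora in CPU-minutes.
TINY_PROFILE = EncoderConfig(n_layers=2, embed_dim=32, ffn_dim=64, n_heads=4,
                             max_len=512, patch_size=8, input_side=64)

#: Full-scale profile (33-layer, 1280-dim sequence encoder).  Used only for
#: closed-form parameter accounting; never instantiated or trained here.
FULL_PROFILE = EncoderConfig(n_layers=33, embed_dim=1280, ffn_dim=5120,
                              n_heads=20, max_len=512, patch_size=4,
                              input_side=256)

PROFILES = {"tiny": TINY_PROFILE, "full": FULL_PROFILE}


@dataclass
class EmbeddingBundle:
    """Per-residue (or per-patch), pooled, and projected embeddings."""

    residue_embeddings: np.ndarray  # (L, D)
    protein_embedding: np.ndarray   # (D,)
    projected: np.ndarray           # (256,)
    modality: str                   # {"sequence", "structure"}


# -- module infrastructure ---------------------------------------------------


class Module:
    """Minimal parameter container with recursive discovery."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
            elif hasattr(val, "named_parameters"):
                yield from val.named_parameters(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if hasattr(item, "named_parameters"):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.requires_grad]


class Linear(Module):
    """Affine map with an optional LoRA delta riding on a frozen weight."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype):
        self.W = Parameter(rng.normal(0.0, 0.02, (d_in, d_out)).astype(dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype))
        self.lora = None  # adapt.LoRADelta | None

    def __call__(self, x: Tensor, lora_enabled: bool = True) -> Tensor:
        out = x @ self.W + self.b
        if self.lora is not None and lora_enabled:
            out = out + self.lora.delta(x)
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, dtype, eps: float = 1e-5):
        self.g = Parameter(np.ones(dim, dtype=dtype))
        self.b = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.g + self.b


class MultiHeadAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, dtype):
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.query = Linear(dim, dim, rng, dtype)
        self.key = Linear(dim, dim, rng, dtype)
        self.value = Linear(dim, dim, rng, dtype)
        self.output = Linear(dim, dim, rng, dtype)

    def target_linear(self, name: str) -> Linear:
        return {"query": self.query, "key": self.key,
                "value": self.value, "output": self.output}[name]

    def __call__(self, x: Tensor, key_valid: np.ndarray,
                 lora_enabled: bool = True) -> Tensor:
        B, T, D = x.shape
        H, hd = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, hd).transpose((0, 2, 1, 3))

        q = split(self.query(x, lora_enabled))
        k = split(self.key(x, lora_enabled))
        v = split(self.value(x, lora_enabled))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd))
        bias = np.where(key_valid[:, None, None, :], 0.0, -1e9).astype(scores.dtype)
        attn = softmax(scores + Tensor(bias), axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, T, D)
        return self.output(ctx, lora_enabled)


class TransformerLayer(Module):
    """Pre-LN block with two adapter slots (post-attention, post-FFN)."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator, dtype):
        d = cfg.embed_dim
        self.ln1 = LayerNorm(d, dtype)
        self.attn = MultiHeadAttention(d, cfg.n_heads, rng, dtype)
        self.ln2 = LayerNorm(d, dtype)
        self.ffn_in = Linear(d, cfg.ffn_dim, rng, dtype)
        self.ffn_out = Linear(cfg.ffn_dim, d, rng, dtype)
        self.attn_adapters = ParallelAdapters()
        self.ffn_adapters = ParallelAdapters()

    def base_parameters(self):
        """Parameters of the frozen backbone (no adapters, no LoRA)."""
        out = []
        for mod in (self.ln1, self.ln2):
            out.extend(mod.parameters())
        for lin in (self.attn.query, self.attn.key, self.attn.value,
                    self.attn.output, self.ffn_in, self.ffn_out):
            out.extend([lin.W, lin.b])
        return out

    def __call__(self, x: Tensor, key_valid: np.ndarray,
                 adapters_enabled: bool = True, lora_enabled: bool = True) -> Tensor:
        x = x + self.attn(self.ln1(x), key_valid, lora_enabled)
        if adapters_enabled and len(self.attn_adapters):
            x = self.attn_adapters(x)
        x = x + self.ffn_out(gelu(self.ffn_in(self.ln2(x))))
        if adapters_enabled and len(self.ffn_adapters):
            x = self.ffn_adapters(x)
        return x


class Projector(Module):
    """Two dense layers (ReLU between) into the 256-d contrastive space."""

    def __init__(self, d_in: int, rng: np.random.Generator, dtype,
                 d_out: int = PROJECTED_DIM):
        self.fc1 = Linear(d_in, d_out, rng, dtype)
        self.fc2 = Linear(d_out, d_out, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(x)))


def mean_pool(embeddings, mask) -> Tensor:
    """Arithmetic mean over mask-true rows.

    ``embeddings`` is (T, D) or batched (B, T, D); ``mask`` matches the
    leading dims.  Raises on an empty mask.
    """
    x = embeddings if isinstance(embeddings, Tensor) else Tensor(np.asarray(embeddings, dtype=float))
    mask = np.asarray(mask, dtype=bool)
    counts = mask.sum(axis=-1)
    if np.any(counts == 0):
        raise ValueError("mean_pool: mask selects no rows")
    w = mask.astype(x.dtype) / counts[..., None]
    if x.ndim == 2:
        return Tensor(w[0] if w.ndim == 2 else w) @ x
    return (Tensor(w[:, None, :]) @ x).reshape(x.shape[0], x.shape[2])


# -- sequence encoder --------------------------------------------------------


class SequenceEncoder(Module):
    def __init__(self, config: EncoderConfig | None = None, seed: int = 0,
                 dtype=np.float64):
        self.config = config or TINY_PROFILE
        self.dtype = np.dtype(dtype).type
        rng = np.random.default_rng(seed)
        d = self.config.embed_dim
        n_pos = self.config.max_len + 2  # BEGIN + residues + END
        self.tok_emb = Parameter(rng.normal(0.0, 0.02, (VOCAB_SIZE, d)).astype(dtype))
        self.pos_emb = Parameter(rng.normal(0.0, 0.02, (n_pos, d)).astype(dtype))
        self.layers = [TransformerLayer(self.config, rng, dtype)
                       for _ in range(self.config.n_layers)]
        self.final_ln = LayerNorm(d, dtype)
        self.projector = Projector(d, rng, dtype)

    def forward_batch(self, ids: np.ndarray, mask: np.ndarray,
                      adapters_enabled: bool = True,
                      lora_enabled: bool = True) -> tuple[Tensor, Tensor, Tensor]:
        """(B, T) ids -> residue (B,T,D), pooled (B,D), projected (B,256)."""
        ids = np.asarray(ids)
        if ids.min() < 0 or ids.max() >= VOCAB_SIZE:
            raise ValueError("token id out of vocabulary")
        B, T = ids.shape
        if T > self.config.max_len + 2:
            raise ValueError(f"token length {T} exceeds positions {self.config.max_len + 2}")
        x = self.tok_emb[ids] + self.pos_emb[np.arange(T)]
        key_valid = ids != PAD_ID
        for layer in self.layers:
            x = layer(x, key_valid, adapters_enabled, lora_enabled)
        x = self.final_ln(x)
        pooled = mean_pool(x, mask)
        projected = self.projector(pooled)
        return x, pooled, projected

    def encode(self, tokens: TokenSeq, adapters_enabled: bool = True,
               lora_enabled: bool = True) -> EmbeddingBundle:
        ids, mask = seqio.pad_batch([tokens])
        resid, pooled, proj = self.forward_batch(ids, mask, adapters_enabled, lora_enabled)
        return EmbeddingBundle(
            residue_embeddings=resid.data[0][mask[0]],
            protein_embedding=pooled.data[0],
            projected=proj.data[0],
            modality="sequence")


def encode_sequence(model: SequenceEncoder, tokens: TokenSeq,
                    adapters_enabled: bool = True) -> EmbeddingBundle:
    return model.encode(tokens, adapters_enabled=adapters_enabled)


def project(model: Module, protein_embedding: np.ndarray) -> np.ndarray:
    """Apply a modality's projector to a pooled embedding."""
    x = np.asarray(protein_embedding, dtype=float)
    if x.shape[-1] != model.projector.fc1.W.shape[0]:
        raise ValueError(
            f"dimension mismatch: got {x.shape[-1]}, "
            f"projector expects {model.projector.fc1.W.shape[0]}")
    return model.projector(Tensor(x)).data


# -- structure encoder -------------------------------------------------------


class StructureEncoder(Module):
    def __init__(self, config: EncoderConfig | None = None, seed: int = 1,
                 dtype=np.float64):
        self.config = config or TINY_PROFILE
        self.dtype = np.dtype(dtype).type
        rng = np.random.default_rng(seed)
        cfg = self.config
        d = cfg.embed_dim
        n_patches = (cfg.input_side // cfg.patch_size) ** 2
        patch_dim = 3 * cfg.patch_size ** 2
        self.patch_embed = Linear(patch_dim, d, rng, dtype)
        self.pos_emb = Parameter(rng.normal(0.0, 0.02, (n_patches, d)).astype(dtype))
        self.layers = [TransformerLayer(cfg, rng, dtype) for _ in range(cfg.n_layers)]
        self.final_ln = LayerNorm(d, dtype)
        self.projector = Projector(d, rng, dtype)

    def _patchify(self, maps: np.ndarray) -> np.ndarray:
        """(B, 3, S, S) -> (B, n_patches, 3·p·p), row-major patch order."""
        B, C, S, _ = maps.shape
        p = self.config.patch_size
        n = S // p
        x = maps.reshape(B, C, n, p, n, p)
        return x.transpose(0, 2, 4, 1, 3, 5).reshape(B, n * n, C * p * p)

    def forward_batch(self, maps: np.ndarray,
                      patch_masks: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        """maps (B,3,S,S), patch_masks (B,n,n) -> patch/pooled/projected."""
        maps = np.asarray(maps, dtype=float)
        if maps.shape[-1] != self.config.input_side:
            raise ValueError(
                f"input side {maps.shape[-1]} != configured {self.config.input_side}")
        flat_mask = np.asarray(patch_masks, dtype=bool).reshape(maps.shape[0], -1)
        if np.any(flat_mask.sum(axis=1) == 0):
            raise ValueError("all patches masked out for at least one protein")
        x = Tensor(self._patchify(maps).astype(self.dtype))
        x = self.patch_embed(x) + self.pos_emb
        for layer in self.layers:
            x = layer(x, flat_mask)
        x = self.final_ln(x)
        pooled = mean_pool(x, flat_mask)
        projected = self.projector(pooled)
        return x, pooled, projected

    def encode(self, resized_map: np.ndarray, patch_mask: np.ndarray) -> EmbeddingBundle:
        patches, pooled, proj = self.forward_batch(resized_map[None], patch_mask[None])
        return EmbeddingBundle(
            residue_embeddings=patches.data[0][patch_mask.reshape(-1)],
            protein_embedding=pooled.data[0],
            projected=proj.data[0],
            modality="structure")


def encode_structure(model: StructureEncoder, resized_map: np.ndarray,
                     patch_mask: np.ndarray) -> EmbeddingBundle:
    return model.encode(resized_map, patch_mask)


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(path: str | Path, seq_encoder: SequenceEncoder,
                    str_encoder: StructureEncoder | None = None,
                    extra: dict | None = None) -> None:
    """Single-file archive: JSON configs + raw little-endian float weights."""
    path = Path(path)
    meta = {
        "seq_config": asdict(seq_encoder.config),
        "seq_dtype": np.dtype(seq_encoder.dtype).name,
        "str_config": asdict(str_encoder.config) if str_encoder else None,
        "str_dtype": np.dtype(str_encoder.dtype).name if str_encoder else None,
        "extra": extra or {},
        "seq_adapter_layout": _adapter_layout(seq_encoder),
        "seq_lora_layout": _lora_layout(seq_encoder),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for tag, model in (("seq", seq_encoder), ("str", str_encoder)):
            if model is None:
                continue
            for name, p in model.named_parameters():
                buf = io.BytesIO()
                np.save(buf, p.data)
                zf.writestr(f"{tag}/{name}.npy", buf.getvalue())


def _adapter_layout(model: SequenceEncoder) -> list[dict]:
    layout = []
    for i, layer in enumerate(model.layers):
        for slot_name in ("attn_adapters", "ffn_adapters"):
            stack = getattr(layer, slot_name)
            for j, a in enumerate(stack.adapters):
                layout.append({"layer": i, "slot": slot_name, "index": j,
                               "bottleneck": a.bottleneck})
    return layout


def _lora_layout(model: SequenceEncoder) -> list[dict]:
    layout = []
    for i, layer in enumerate(model.layers):
        for tgt in ("query", "key", "value", "output"):
            lin = layer.attn.target_linear(tgt)
            if lin.lora is not None:
                layout.append({"layer": i, "target": tgt,
                               "r": lin.lora.r, "alpha": lin.lora.alpha})
    return layout


def load_checkpoint(path: str | Path) -> tuple[SequenceEncoder, StructureEncoder | None, dict]:
    from .adapt import Adapter, LoRADelta  # local import to avoid cycle at module load
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        seq = SequenceEncoder(EncoderConfig(**meta["seq_config"]),
                              dtype=np.dtype(meta["seq_dtype"]))
        rng = np.random.default_rng(0)
        d = seq.config.embed_dim
        for ent in meta["seq_adapter_layout"]:
            stack = getattr(seq.layers[ent["layer"]], ent["slot"])
            stack.append(Adapter(d, ent["bottleneck"], rng,
                                 np.dtype(meta["seq_dtype"])))
        for ent in meta.get("seq_lora_layout", []):
            lin = seq.layers[ent["layer"]].attn.target_linear(ent["target"])
            lin.lora = LoRADelta(d, d, ent["r"], ent["alpha"], rng,
                                 np.dtype(meta["seq_dtype"]))
        _load_params(zf, "seq", seq)
        stc = None
        if meta["str_config"] is not None:
            stc = StructureEncoder(EncoderConfig(**meta["str_config"]),
                                   dtype=np.dtype(meta["str_dtype"]))
            _load_params(zf, "str", stc)
    return seq, stc, meta.get("extra", {})


def _load_params(zf: zipfile.ZipFile, tag: str, model: Module) -> None:
    names = set()
    for name, p in model.named_parameters():
        data = np.load(io.BytesIO(zf.read(f"{tag}/{name}.npy")))
        if data.shape != p.data.shape:
            raise ValueError(f"checkpoint shape mismatch for {name}")
        p.data = data
        names.add(name)
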