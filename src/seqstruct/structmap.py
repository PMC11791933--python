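"""Cα coordinate parsing and contact-map featurization.

A protein's 3D structure enters the model as a clipped-similarity matrix over
pairwise Cα–Cα distances: with distance C and threshold d (Å),

    value = (d - min(C, d)) / d

so residues in contact score near 1 and residues farther than d apart score
exactly 0.  The matrix is replicated into three channels (an image-encoder
convention); per-channel thresholds are configurable, defaulting to 22 Å for
every channel — the contact cutoff AlphaFold2 popularised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import h5py
import numpy as np
from scipy.ndimage import zoom
from scipy.spatial.distance import pdist, squareform

from .seqio import DEFAULT_MAX_LEN, ProteinRecord, clean_sequence

DEFAULT_CONTACT_THRESHOLD = 22.0  # Å, per channel
N_CHANNELS = 3


@dataclass
class ContactMapTensor:
    """3 × L × L clipped-similarity tensor with per-channel thresholds."""

    values: np.ndarray
    thresholds: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != N_CHANNELS:
            raise ValueError("values must be 3 x L x L")
        if self.values.shape[1] != self.values.shape[2]:
            raise ValueError("contact map must be square")

    @property
    def length(self) -> int:
        return self.values.shape[1]


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def read_calpha_coords(path: str | Path, chain: str | None = None) -> ProteinRecord:
    """Extract the Cα trace of one chain from a PDB or mmCIF file.

    Residues lacking a Cα atom are dropped with a warning; alternate
    locations resolve to the highest-occupancy conformer (ties break to
    altloc 'A' by lexicographic order).
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if len(names) != 1:
            raise ValueError(f"{path}: multiple chains {names}, specify one")
        chain = names[0]
    if chain not in names:
        raise ValueError(f"{path}: chain {chain!r} not found; available: {names}")

    coords, letters = [], []
    n_dropped = 0
    for res in model[chain]:
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            n_dropped += 1
            continue
        # altloc rule: highest occupancy wins, ties go to the earliest altloc
        best = min(cas, key=lambda a: (-a.occ, a.altloc or "A"))
        coords.append([best.pos.x, best.pos.y, best.pos.z])
        letters.append(_one_letter(res.name))
    if not coords:
        raise ValueError(f"{path}: chain {chain!r} has no CA atoms")
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} residue(s) lacking a CA atom")
    return ProteinRecord(id=f"{path.stem}_{chain}",
                         sequence=clean_sequence("".join(letters)),
                         coords=np.array(coords, dtype=float))


def read_xyz_table(path: str | Path) -> np.ndarray:
    """Read a plain TSV of (index, x, y, z) rows into an (L, 3) array."""
    tbl = np.loadtxt(path, dtype=float, ndmin=2)
    if tbl.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns (index, x, y, z)")
    order = np.argsort(tbl[:, 0], kind="stable")
    return tbl[order, 1:4]


def write_xyz_table(coords: np.ndarray, path: str | Path) -> None:
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(coords):
            fh.write(f"{i}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean Cα–Cα distance matrix in Å."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (L, 3)")
    if coords.shape[0] < 1:
        raise ValueError("need at least one coordinate")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinate")
    if coords.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(coords))


def featurize(dist: np.ndarray,
              thresholds: float | Sequence[float] = DEFAULT_CONTACT_THRESHOLD,
              max_len: int = DEFAULT_MAX_LEN) -> ContactMapTensor:
    """Clipped-similarity transform (d - min(C, d)) / d, three channels.

    The distance matrix is truncated to its first ``max_len`` rows/columns
    (mirroring sequence truncation) before the transform.
    """
    dist = np.asarray(dist, dtype=float)
    if np.isscalar(thresholds) or np.ndim(thresholds) == 0:
        thresholds = (float(thresholds),) * N_CHANNELS
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) != N_CHANNELS:
        raise ValueError(f"need {N_CHANNELS} thresholds")
    if any(t <= 0 for t in thresholds):
        raise ValueError("distance threshold d must be > 0")
    dist = dist[:max_len, :max_len]
    chans = [(d - np.minimum(dist, d)) / d for d in thresholds]
    return ContactMapTensor(np.stack(chans), thresholds)


def contact_map_for(record: ProteinRecord,
                    thresholds: float | Sequence[float] = DEFAULT_CONTACT_THRESHOLD,
                    max_len: int = DEFAULT_MAX_LEN) -> ContactMapTensor:
    if record.coords is None:
        raise ValueError(f"protein {record.id!r} has no coordinates")
    return featurize(distance_matrix(record.coords), thresholds, max_len)


def resize_for_encoder(cmap: ContactMapTensor, side: int,
                       patch_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Fit a contact map to the structure encoder's fixed input resolution.

    Maps no larger than ``side`` are zero-padded bottom/right (0 = "no
    contact") with a patch-coverage mask marking patches that overlap real
    residues; larger maps are bilinearly downscaled to ``side`` with a
    full-coverage mask.

    Returns ``(array of shape (3, side, side), mask of shape (side/patch,)²)``.
    """
    if side % patch_size != 0:
        raise ValueError("side must be divisible by the encoder patch size")
    n_patches = side // patch_size
    L = cmap.length
    if L <= side:
        out = np.zeros((N_CHANNELS, side, side), dtype=float)
        out[:, :L, :L] = cmap.values
        covered = int(np.ceil(L / patch_size))
        mask = np.zeros((n_patches, n_patches), dtype=bool)
        mask[:covered, :covered] = True
    else:
        factor = side / L
        out = np.stack([zoom(c, factor, order=1, mode="nearest", grid_mode=True)
                        for c in cmap.values])
        out = out[:, :side, :side]
        if out.shape[1] != side:  # zoom rounding safety
            fixed = np.zeros((N_CHANNELS, side, side), dtype=float)
            fixed[:, :out.shape[1], :out.shape[2]] = out
            out = fixed
        mask = np.ones((n_patches, n_patches), dtype=bool)
    return out, mask


# -- HDF5 cache -------------------------------------------------------------


def save_contact_cache(path: str | Path,
                       tensors: dict[str, ContactMapTensor]) -> None:
    """Write contact tensors to an HDF5 file keyed by protein id."""
    with h5py.File(path, "w") as h5:
        for pid, cm in tensors.items():
            ds = h5.create_dataset(pid, data=cm.values, compression="gzip")
            ds.attrs["thresholds"] = cm.thresholds


def load_contact_cache(path: str | Path) -> dict[str, ContactMapTensor]:
    out = {}
    with h5py.File(path, "r") as h5:
        for pid in h5:
            ds = h5[pid]
            out[pid] = ContactMapTensor(ds[...], tuple(ds.attrs["thresholds"]))
    return out
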