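"""Protein sequence I/O, tokenization and truncation.

Sequences are strings over the 20 canonical amino-acid letters plus ``X`` for
anything non-canonical.  Tokenization adds a BEGIN token before and an END
token after the (possibly truncated) residues, mirroring the ``<cls>`` /
``<eos>`` convention of transformer protein language models; PAD fills
batches to a common width.  The boolean mask marks real-residue positions
only — BEGIN, END and PAD are always mask-false, so downstream mean pooling
never sees them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

CANONICAL_AAS = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_AA = "X"

# Fixed integer vocabulary: canonical residues 0..19, X, then specials.
AA_TO_ID = {aa: i for i, aa in enumerate(CANONICAL_AAS)}
AA_TO_ID[UNKNOWN_AA] = 20
BEGIN_ID = 21
END_ID = 22
PAD_ID = 23
VOCAB_SIZE = 24

ID_TO_AA = {v: k for k, v in AA_TO_ID.items()}

DEFAULT_MAX_LEN = 512


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


@dataclass
class ProteinRecord:
    """One protein: identifier, sequence, optional Cα trace, optional family."""

    id: str
    sequence: str
    coords: np.ndarray | None = None  # (L, 3) in Å
    family: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (len(self.sequence), 3):
                raise ValueError(
                    f"protein {self.id!r}: {self.coords.shape[0]} coordinates "
                    f"for {len(self.sequence)} residues")
            if not np.all(np.isfinite(self.coords)):
                raise ValueError(f"protein {self.id!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TokenSeq:
    """Integer token ids with a real-residue mask.

    ``mask`` is True exactly at residue positions; BEGIN/END/PAD are False.
    """

    token_ids: np.ndarray
    mask: np.ndarray
    original_length: int

    def __post_init__(self):
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.token_ids.shape != self.mask.shape:
            raise ValueError("token_ids and mask must have the same length")


def clean_sequence(seq: str, rec_id: str = "?") -> str:
    """Uppercase, strip ``*`` stop characters, map non-canonical letters to X."""
    seq = seq.upper()
    if "*" in seq:
        warnings.warn(f"protein {rec_id!r}: stripped '*' stop character(s)")
        seq = seq.replace("*", "")
    cleaned = []
    n_mapped = 0
    for ch in seq:
        if ch in AA_TO_ID:
            cleaned.append(ch)
        else:
            cleaned.append(UNKNOWN_AA)
            n_mapped += 1
    if n_mapped:
        warnings.warn(
            f"protein {rec_id!r}: mapped {n_mapped} non-canonical letter(s) to 'X'")
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Order is preserved; non-canonical letters become ``X`` with a warning.
    A file whose first non-blank line is not a header raises
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}:{lineno}: expected FASTA header, got {line.strip()!r}")
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=clean_sequence(str(rec.seq), rec.id)))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def tokenize(rec: ProteinRecord | str, max_len: int = DEFAULT_MAX_LEN) -> TokenSeq:
    """Truncate to the first ``max_len`` residues, then wrap in BEGIN/END."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    seq = rec.sequence if isinstance(rec, ProteinRecord) else rec
    kept = seq[:max_len]
    ids = [BEGIN_ID] + [AA_TO_ID[ch] for ch in kept] + [END_ID]
    mask = [False] + [True] * len(kept) + [False]
    return TokenSeq(np.array(ids), np.array(mask), original_length=len(seq))


def detokenize(tokens: TokenSeq) -> str:
    """Recover the (possibly truncated) residue string from real positions."""
    return "".join(ID_TO_AA[i] for i in tokens.token_ids[tokens.mask])


def pad_batch(seqs: Sequence[TokenSeq]) -> tuple[np.ndarray, np.ndarray]:
    """Stack token sequences into (B, T) id and mask arrays, PAD-filled."""
    width = max(len(s.token_ids) for s in seqs)
    ids = np.full((len(seqs), width), PAD_ID, dtype=np.int64)
    mask = np.zeros((len(seqs), width), dtype=bool)
    for i, s in enumerate(seqs):
        ids[i, :len(s.token_ids)] = s.token_ids
        mask[i, :len(s.mask)] = s.mask
    return ids, mask
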