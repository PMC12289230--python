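"""Per-residue embedding matrices M (L x 1280) via pluggable backends.

The contract mirrors what a protein language model in the ESM-1b family
produces: one 1280-dimensional vector per residue. Two backends are
provided:

* :class:`SyntheticEmbedder` — fully deterministic, dependency-free rows
  built from a per-letter base vector, a positional sinusoid, seeded noise,
  and additive motif signatures, so that planted sequence rules are
  learnable without any external model weights.
* :func:`load_precomputed` — adapter for embeddings computed elsewhere and
  stored in HDF5 (one dataset per protein id) or a flat ``.npy`` file. If a
  stored matrix has L+2 rows the BOS/EOS token rows are stripped.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
from numpy.random import Generator, Philox

EMBED_DIM = 1280
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}

# amplitudes of the synthetic components, chosen so motif signatures are a
# clear but not overwhelming additive signal on top of the residue identity
_BASE_SCALE = 0.4
_POS_SCALE = 0.2
_NOISE_SCALE = 0.3
_SIG_DIMS = 48
_SIG_SCALE = 1.0


class EmbeddingError(ValueError):
    pass


@dataclass
class ResidueEmbeddingMatrix:
    """L x 1280 per-residue features for one protein."""

    matrix: np.ndarray
    protein_id: str = ""
    backend: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != EMBED_DIM:
            raise EmbeddingError(
                f"embedding matrix must be L x {EMBED_DIM}, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise EmbeddingError("embedding matrix contains non-finite entries")

    def __len__(self) -> int:
        return self.matrix.shape[0]


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise EmbeddingError("empty sequence")
    for i, c in enumerate(seq):
        if c not in _LETTER_INDEX:
            raise EmbeddingError(f"illegal character {c!r} at position {i}")


@lru_cache(maxsize=4096)
def _positional_row(pos: int) -> np.ndarray:
    half = EMBED_DIM // 2
    freq = np.exp(-np.arange(half) * (np.log(10000.0) / half))
    row = np.empty(EMBED_DIM)
    row[0::2] = np.sin(pos * freq)
    row[1::2] = np.cos(pos * freq)
    return row


def motif_signature(motif: str, seed: int) -> np.ndarray:
    """Sparse +-1 signature vector for a motif, deterministic in (motif, seed)."""
    key = (seed << 64) ^ int.from_bytes(motif.encode(), "big")
    rng = Generator(Philox(key=key))
    sig = np.zeros(EMBED_DIM)
    dims = rng.choice(EMBED_DIM, size=_SIG_DIMS, replace=False)
    sig[dims] = rng.choice([-_SIG_SCALE, _SIG_SCALE], size=_SIG_DIMS)
    return sig


class SyntheticEmbedder:
    """Deterministic stand-in embedding backend (synthetic by construction).

    Row for (letter, position) = base[letter] + positional sinusoid +
    counter-seeded Gaussian noise keyed on (seed, letter, position), plus the
    signature of any planted motif covering that position. Because each
    component depends only on those quantities, two sequences sharing a
    prefix share the prefix's rows whenever no motif overlaps it.
    """

    name = "synthetic"

    def __init__(self, seed: int = 0, motifs: dict[str, np.ndarray] | None = None):
        self.seed = int(seed)
        self.motifs = dict(motifs or {})
        rng = Generator(Philox(key=self.seed))
        self._base = rng.normal(0.0, _BASE_SCALE, size=(len(ALPHABET), EMBED_DIM))

    def _noise_row(self, letter_idx: int, pos: int) -> np.ndarray:
        key = ((self.seed & 0xFFFFFFFF) << 64) | (letter_idx << 40) | pos
        rng = Generator(Philox(key=key))
        return rng.normal(0.0, _NOISE_SCALE, size=EMBED_DIM)

    def rows(self, seq: str) -> np.ndarray:
        L = len(seq)
        out = np.empty((L, EMBED_DIM))
        for pos, c in enumerate(seq):
            li = _LETTER_INDEX[c]
            out[pos] = self._base[li] + _POS_SCALE * _positional_row(pos) \
                + self._noise_row(li, pos)
        for motif, sig in self.motifs.items():
            start = seq.find(motif)
            while start != -1:
                out[start : start + len(motif)] += sig
                start = seq.find(motif, start + 1)
        return out


def embed(seq: str, backend: SyntheticEmbedder, protein_id: str = "") -> ResidueEmbeddingMatrix:
    """Embed a protein sequence with the given backend."""
    _validate_sequence(seq)
    matrix = backend.rows(seq)
    return ResidueEmbeddingMatrix(matrix=matrix, protein_id=protein_id,
                                  backend=backend.name)


def load_precomputed(path: str | Path, protein_id: str | None = None,
                     expected_length: int | None = None) -> ResidueEmbeddingMatrix:
    """Load a precomputed embedding matrix from HDF5 or ``.npy``.

    HDF5 files hold one dataset per protein id. When the stored row count is
    ``expected_length + 2`` the first and last rows (BOS/EOS token positions)
    are stripped.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            if protein_id is None:
                keys = list(fh.keys())
                if len(keys) != 1:
                    raise EmbeddingError(
                        f"{path.name} holds {len(keys)} datasets; pass protein_id")
                protein_id = keys[0]
            if protein_id not in fh:
                raise EmbeddingError(f"{path.name}: no dataset {protein_id!r}")
            matrix = np.asarray(fh[protein_id])
    else:
        matrix = np.load(path)
        protein_id = protein_id or path.stem
    if matrix.ndim != 2:
        raise EmbeddingError(f"expected a 2-D array, got shape {matrix.shape}")
    if matrix.shape[1] != EMBED_DIM:
        raise EmbeddingError(
            f"wrong embedding width: found {matrix.shape[1]}, expected {EMBED_DIM}")
    if expected_length is not None:
        if matrix.shape[0] == expected_length + 2:
            matrix = matrix[1:-1]
        if matrix.shape[0] != expected_length:
            raise EmbeddingError(
                f"row count {matrix.shape[0]} does not match sequence length "
                f"{expected_length}")
    return ResidueEmbeddingMatrix(matrix=matrix, protein_id=protein_id or "",
                                  backend="precomputed")


def save_embeddings(embeddings: dict[str, np.ndarray], path: str | Path) -> None:
    """Write one dataset per protein id into an HDF5 container."""
    with h5py.File(path, "w") as fh:
        for pid in sorted(embeddings):
            # track_times=False keeps the container byte-identical across runs
            fh.create_dataset(pid, data=np.asarray(embeddings[pid]),
                              track_times=False)
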