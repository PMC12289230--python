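"""Residue-level saliency from cross-attention weights.

The attention a residue receives as a *key* — averaged over both fusion
directions and all heads (column means of the row-stochastic L x L maps) —
serves as a per-residue functional-importance score. Scores are min-max
normalized to [0, 1] for heatmap comparability (a constant score vector maps
to all 0.5); the raw averages are kept alongside. Agreement with known
binding-site residues is quantified as the ROC AUC: the probability that a
random binding residue outranks a random non-binding one, ties counted 1/2,
computed exactly from midranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .fusion import AttentionRecord

logger = logging.getLogger(__name__)

AXIS_MODES = ("key", "query")


class SaliencyError(ValueError):
    pass


@dataclass
class ResidueSaliency:
    """Per-residue functional-importance scores in [0, 1]."""

    scores: np.ndarray
    raw: np.ndarray
    direction: str = "both"
    axis: str = "key"

    def __len__(self) -> int:
        return self.scores.size


def residue_scores(rec: AttentionRecord, direction: str | None = None,
                   axis: str = "key") -> ResidueSaliency:
    """Average attention mass per residue, min-max normalized.

    `direction` restricts to 'seq' or 'stru' queries (default: both);
    `axis='key'` averages the attention each residue receives (column mean),
    `axis='query'` the attention it emits (row mean).
    """
    if axis not in AXIS_MODES:
        raise SaliencyError(f"axis must be one of {AXIS_MODES}")
    mats = rec.matrices(direction)
    if not mats:
        raise SaliencyError("attention record holds no matrices for this direction")
    pooled = np.zeros(mats[0].shape[0], dtype=np.float64)
    for m in mats:
        pooled += m.mean(axis=0) if axis == "key" else m.mean(axis=1)
    raw = pooled / len(mats)
    span = raw.max() - raw.min()
    if span < 1e-12:
        scores = np.full_like(raw, 0.5)
    else:
        scores = (raw - raw.min()) / span
    return ResidueSaliency(scores=scores, raw=raw,
                           direction=direction or "both", axis=axis)


def saliency_auc(s: ResidueSaliency | np.ndarray, mask: np.ndarray) -> float:
    """Exact rank-based ROC AUC of scores against a binary residue mask."""
    scores = s.scores if isinstance(s, ResidueSaliency) else np.asarray(s, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != scores.shape:
        raise SaliencyError(f"mask shape {mask.shape} != scores {scores.shape}")
    n_pos = int(mask.sum())
    n_neg = int((~mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise SaliencyError("mask must contain at least one positive and one negative")
    ranks = rankdata(scores)  # midranks give ties weight 1/2
    return float((ranks[mask].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def write_saliency_tsv(protein_id: str, s: ResidueSaliency, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tresidue_index\tscore\traw\n")
        for i, (score, raw) in enumerate(zip(s.scores, s.raw)):
            fh.write(f"{protein_id}\t{i}\t{score:.6f}\t{raw:.6g}\n")


def read_binding_masks(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-residue binding masks from TSV (protein_id, residue_index, 0/1)."""
    rows: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("protein_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SaliencyError(f"{path}:{lineno}: expected 3 tab-separated fields")
            pid, idx, val = parts
            rows.setdefault(pid, {})[int(idx)] = int(val)
    masks = {}
    for pid, positions in rows.items():
        L = max(positions) + 1
        mask = np.zeros(L, dtype=np.uint8)
        for i, v in positions.items():
            mask[i] = v
        masks[pid] = mask
    return masks


def write_binding_masks(masks: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tresidue_index\tmask\n")
        for pid in sorted(masks):
            for i, v in enumerate(masks[pid]):
                fh.write(f"{pid}\t{i}\t{int(v)}\n")


def stamp_bfactors(pdb_path: str | Path, chain: str, s: ResidueSaliency,
                   out_path: str | Path) -> None:
    """Copy a PDB file with saliency written into the B-factor column of the
    target chain's residues (for structure-viewer heatmaps)."""
    import gemmi

    st = gemmi.read_structure(str(pdb_path))
    model = st[0]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
    if target is None:
        raise SaliencyError(f"chain {chain!r} not in {pdb_path}")
    idx = 0
    for res in target:
        has_ca = any(a.name == "CA" and a.element.name == "C" for a in res)
        if not has_ca:
            continue
        if idx >= len(s):
            logger.warning("more CA residues than saliency scores; stopping at %d", idx)
            break
        for atom in res:
            atom.b_iso = float(np.round(100.0 * s.scores[idx], 2))
        idx += 1
    st.setup_entities()
    st.write_pdb(str(out_path))
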