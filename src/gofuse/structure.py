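"""Protein structures, residue contact maps and normalized adjacency.

A contact map is a symmetric boolean residue x residue matrix with an edge
wherever the Euclidean distance between two residues' alpha carbons is
strictly below a threshold (default 10 Angstrom, the value shown to work
well for CA-CA maps in the function-prediction literature). Self-loops are
not part of the map; graph layers add them explicitly when normalizing
(A_hat = A + I, then D_hat^-1/2 A_hat D_hat^-1/2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    pass


@dataclass
class ResidueRecord:
    chain: str
    seqid: str  # author residue number + insertion code
    name: str
    ca: np.ndarray  # (3,) float64, Angstrom


@dataclass
class StructureModel:
    """Ordered CA-resolved residues of one chain."""

    protein_id: str
    residues: list[ResidueRecord]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    @property
    def coordinates(self) -> np.ndarray:
        return np.stack([r.ca for r in self.residues])


@dataclass
class ContactGraph:
    """Boolean residue adjacency (no self-loops) plus provenance."""

    adjacency: np.ndarray  # (L, L) bool
    coordinates: np.ndarray | None = None
    protein_id: str = ""
    chain: str = ""
    threshold: float = 10.0

    @property
    def size(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def _pick_ca(residue: gemmi.Residue) -> np.ndarray | None:
    """Highest-occupancy CA (carbon only, so calcium ions never match);
    occupancy ties resolve to altloc 'A' / blank."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element.name != "C":
            continue
        key = (atom.occ, -ord(atom.altloc or "A"))
        if best is None or key > best[0]:
            best = (key, atom)
    if best is None:
        return None
    pos = best[1].pos
    return np.array([pos.x, pos.y, pos.z])


def parse_structure(path: str | Path, chain: str,
                    protein_id: str | None = None) -> StructureModel:
    """Parse a PDB or mmCIF file and extract one chain's CA trace.

    Residues without a CA atom are skipped (count logged). HETATM residues
    are excluded except selenomethionine (MSE), which is read as MET.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")
    model = st[0]
    available = [ch.name for ch in model]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise StructureError(
            f"chain {chain!r} not found in {path.name}; available chains: {available}")

    residues: list[ResidueRecord] = []
    skipped = 0
    for res in target:
        name = res.name
        if res.het_flag == "H":
            if name == "MSE":
                name = "MET"
            else:
                continue
        ca = _pick_ca(res)
        if ca is None:
            skipped += 1
            continue
        seqid = f"{res.seqid.num}{res.seqid.icode.strip()}"
        residues.append(ResidueRecord(chain=chain, seqid=seqid, name=name, ca=ca))
    if skipped:
        logger.info("%s chain %s: skipped %d residues lacking a CA atom",
                    path.name, chain, skipped)
    if not residues:
        raise StructureError(f"{path.name} chain {chain}: no residues with CA atoms")
    pid = protein_id or f"{path.stem}_{chain}"
    return StructureModel(protein_id=pid, residues=residues)


def build_contact_map(s: StructureModel, threshold: float = 10.0) -> ContactGraph:
    """CA-CA contact map: edge iff distance < threshold (strict), i != j."""
    coords = s.coordinates
    if not np.all(np.isfinite(coords)):
        bad = int(np.where(~np.isfinite(coords).all(axis=1))[0][0])
        raise StructureError(
            f"non-finite CA coordinate at residue {bad} ({s.residues[bad].seqid})")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    adjacency = dist < threshold
    np.fill_diagonal(adjacency, False)
    return ContactGraph(adjacency=adjacency, coordinates=coords,
                        protein_id=s.protein_id,
                        chain=s.residues[0].chain if s.residues else "",
                        threshold=threshold)


def normalized_adjacency(g: ContactGraph) -> np.ndarray:
    """Symmetric GCN normalization D_hat^-1/2 (A + I) D_hat^-1/2."""
    a_hat = g.adjacency.astype(np.float64) + np.eye(g.size)
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def save_contact_graph(g: ContactGraph, prefix: str | Path) -> None:
    """Write adjacency as .npy with a JSON sidecar of provenance."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), g.adjacency)
    meta = {"protein_id": g.protein_id, "chain": g.chain,
            "L": int(g.size), "threshold": g.threshold}
    prefix.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True) + "\n")


def load_contact_graph(prefix: str | Path) -> ContactGraph:
    prefix = Path(prefix)
    adjacency = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return ContactGraph(adjacency=adjacency.astype(bool), protein_id=meta["protein_id"],
                        chain=meta["chain"], threshold=meta["threshold"])
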