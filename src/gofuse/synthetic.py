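"""Self-contained synthetic fixtures: toy structures, sequences, embeddings,
a toy GO DAG, planted-rule annotations, and binding-site masks.

The generator emulates the *shapes and contracts* of real data, not its
statistics. Structures are compact self-avoiding CA chains with canonical
3.8 Angstrom consecutive spacing, so a 10 Angstrom contact map contains both
the backbone band and genuine tertiary contacts. Function labels follow
planted rules: every leaf term owns a sequence motif (a k-mer whose
embedding rows carry an additive signature), and a configurable fraction of
leaves additionally fire on a structural contact-density rule. Labels are
ancestor-closed on the toy DAG; binding-site masks mark motif positions.
Everything is deterministic given the spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .embeddings import (SyntheticEmbedder, embed, motif_signature,
                         save_embeddings)
from .ontology import AnnotationSet, GoDag, TermVocabulary, propagate, write_annotations
from .saliency import write_binding_masks
from .structure import (THREE_TO_ONE, ContactGraph, ResidueRecord, StructureModel,
                        build_contact_map)

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_STEP = 3.8        # consecutive CA-CA spacing, Angstrom (canonical backbone)
_MIN_DIST = 3.0    # self-avoidance radius, Angstrom
_ROOT = "GO:9000000"


class GenerationError(RuntimeError):
    pass


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (30, 60)
    n_terms: int = 16                 # leaf terms
    dag_depth: int = 3                # root -> internal layer(s) -> leaves
    motif_length: int = 3
    contact_rule_fraction: float = 0.25
    plant_prob_range: tuple[float, float] = (0.25, 0.6)
    label_noise: float = 0.0
    # proteins come in two folding regimes (loose / compact centroid bias);
    # contact-cluster rules threshold the contact density inside the gap
    # between the two regimes' density distributions
    compactness_modes: tuple[float, float] = (-0.3, 1.5)
    compact_fraction: float = 0.5
    contact_density_threshold: float = 0.40
    seed: int = 1

    def __post_init__(self):
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label noise must lie in [0, 0.5)")
        if min(self.n_proteins, self.n_terms, self.motif_length) <= 0:
            raise ValueError("counts must be positive")
        if self.dag_depth < 2:
            raise ValueError("DAG depth must be >= 2 (root plus leaves)")
        if self.length_range[0] < self.motif_length:
            raise ValueError("proteins must be long enough to hold a motif")


@dataclass
class TermRule:
    """Planted firing rule of one leaf term."""

    term: str
    motif: str
    plant_prob: float
    contact_threshold: float | None = None  # None: sequence rule only

    def fires(self, sequence: str, contact_density: float) -> bool:
        if self.motif in sequence:
            return True
        return (self.contact_threshold is not None
                and contact_density >= self.contact_threshold)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    dag: GoDag
    rules: list[TermRule]
    leaf_terms: list[str]
    structures: dict[str, StructureModel]
    sequences: dict[str, str]
    graphs: dict[str, ContactGraph]
    embeddings: dict[str, np.ndarray]
    raw_annotations: AnnotationSet
    annotations: AnnotationSet          # propagated
    binding_masks: dict[str, np.ndarray]
    splits: dict[str, list[str]] = field(default_factory=dict)

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self.sequences)


# --------------------------------------------------------------------- chains
def make_structure(L: int, seed: int, sequence: str | None = None,
                   compactness: float = 0.8, protein_id: str = "synthetic"
                   ) -> StructureModel:
    """Compact self-avoiding CA chain of length L.

    Consecutive CAs sit exactly 3.8 Angstrom apart; all other pairs stay at
    least 3.0 Angstrom apart. Steps are biased toward the running centroid so
    chains of L >= 15 fold back on themselves and produce tertiary contacts.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    for _attempt in range(50):
        coords = _grow_chain(L, rng, compactness)
        if coords is not None:
            break
    else:
        raise GenerationError(
            f"could not place a self-avoiding chain of length {L}; try another seed")
    seq = sequence or "A" * L
    residues = [
        ResidueRecord(chain="A", seqid=str(i + 1),
                      name=ONE_TO_THREE.get(c, "UNK"), ca=coords[i])
        for i, c in enumerate(seq)
    ]
    return StructureModel(protein_id=protein_id, residues=residues)


def _grow_chain(L: int, rng: np.random.Generator, compactness: float
                ) -> np.ndarray | None:
    coords = np.zeros((L, 3))
    for i in range(1, L):
        centroid = coords[:i].mean(axis=0)
        placed = False
        for _retry in range(200):
            g = rng.normal(size=3)
            pull = centroid - coords[i - 1]
            norm = np.linalg.norm(pull)
            if norm > 1e-9:
                g = g + compactness * pull / norm
            g /= np.linalg.norm(g)
            candidate = coords[i - 1] + _STEP * g
            if i < 2:
                placed = True
            else:
                d = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
                placed = bool(d.min() >= _MIN_DIST)
            if placed:
                coords[i] = candidate
                break
        if not placed:
            return None
    return coords


# --------------------------------------------------------------------- toy DAG
def make_toy_dag(n_leaves: int, depth: int = 3, namespace: str = "MF") -> tuple[GoDag, list[str]]:
    """Toy ontology: a root, `depth - 2` internal layers, and leaf terms."""
    parents: dict[str, set[str]] = {_ROOT: set()}
    ns = {_ROOT: namespace}
    previous = [_ROOT]
    n_internal_layers = depth - 2
    for layer in range(n_internal_layers):
        width = max(2, n_leaves // (2 ** (n_internal_layers - layer)))
        layer_terms = [f"GO:90{layer + 1:02d}{i:03d}" for i in range(width)]
        for i, t in enumerate(layer_terms):
            parents[t] = {previous[i % len(previous)]}
            ns[t] = namespace
        previous = layer_terms
    leaves = [f"GO:91{0:02d}{i:03d}" for i in range(n_leaves)]
    for i, t in enumerate(leaves):
        parents[t] = {previous[i % len(previous)]}
        ns[t] = namespace
    dag = GoDag(parents=parents, namespace=ns, roots={namespace: _ROOT})
    return dag, leaves


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Serialize a toy DAG as a minimal OBO 1.2 file readable by parse_obo."""
    ns_long = {"MF": "molecular_function", "BP": "biological_process",
               "CC": "cellular_component"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: gofuse-toy\n")
        for term in sorted(dag.parents):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            fh.write(f"namespace: {ns_long[dag.namespace[term]]}\n")
            for parent in sorted(dag.parents[term]):
                fh.write(f"is_a: {parent} ! synthetic term {parent}\n")


# --------------------------------------------------------------------- dataset
def _contact_density(graph: ContactGraph) -> float:
    L = graph.size
    if L < 2:
        return 0.0
    return float(graph.adjacency.sum() / (L * (L - 1)))


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a complete, deterministic synthetic dataset."""
    rng = np.random.default_rng(spec.seed)
    dag, leaves = make_toy_dag(spec.n_terms, spec.dag_depth)

    # planted rules: unique motifs, per-term plant probability, and a
    # contact-density rule on a leading fraction of terms
    motifs: set[str] = set()
    rules: list[TermRule] = []
    n_contact = int(round(spec.contact_rule_fraction * spec.n_terms))
    for i, term in enumerate(leaves):
        while True:
            motif = "".join(rng.choice(list(_AA20), size=spec.motif_length))
            if motif not in motifs:
                motifs.add(motif)
                break
        plant = float(rng.uniform(*spec.plant_prob_range))
        threshold = spec.contact_density_threshold if i < n_contact else None
        rules.append(TermRule(term=term, motif=motif, plant_prob=plant,
                              contact_threshold=threshold))

    embedder = SyntheticEmbedder(
        seed=spec.seed,
        motifs={r.motif: motif_signature(r.motif, spec.seed) for r in rules})

    ids = [f"syn{i:04d}" for i in range(spec.n_proteins)]
    sequences: dict[str, str] = {}
    structures: dict[str, StructureModel] = {}
    graphs: dict[str, ContactGraph] = {}
    densities: dict[str, float] = {}
    lo, hi = spec.length_range
    for i, pid in enumerate(ids):
        L = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(_AA20), size=L))
        for rule in rules:
            if rng.random() < rule.plant_prob:
                start = int(rng.integers(0, L - spec.motif_length + 1))
                seq[start : start + spec.motif_length] = list(rule.motif)
        sequences[pid] = "".join(seq)
        compact = rng.random() < spec.compact_fraction
        mode = spec.compactness_modes[1] if compact else spec.compactness_modes[0]
        structure = make_structure(L, seed=int(rng.integers(0, 2**31 - 1)),
                                   sequence=sequences[pid],
                                   compactness=mode, protein_id=pid)
        structures[pid] = structure
        graphs[pid] = build_contact_map(structure)
        densities[pid] = _contact_density(graphs[pid])

    # leaf labels from the planted rules, then optional noise, then closure
    raw: dict[str, set[str]] = {pid: set() for pid in ids}
    for pid in ids:
        for rule in rules:
            fired = rule.fires(sequences[pid], densities[pid])
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                fired = not fired
            if fired:
                raw[pid].add(rule.term)

    # rebalance rare terms by force-planting motifs (labels stay rule-consistent)
    min_count = max(1, int(np.ceil(0.05 * spec.n_proteins)))
    for rule in rules:
        carriers = [pid for pid in ids if rule.term in raw[pid]]
        deficit = min_count - len(carriers)
        if deficit > 0 and spec.label_noise == 0:
            for pid in [p for p in ids if p not in carriers][:deficit]:
                seq = list(sequences[pid])
                start = int(rng.integers(0, len(seq) - spec.motif_length + 1))
                seq[start : start + spec.motif_length] = list(rule.motif)
                sequences[pid] = "".join(seq)
                for r2 in rules:  # re-evaluate every rule on the edited sequence
                    if r2.fires(sequences[pid], densities[pid]):
                        raw[pid].add(r2.term)

    embeddings = {pid: embed(sequences[pid], embedder, protein_id=pid).matrix
                  for pid in ids}

    # binding masks: motif positions of any planted rule present in the sequence
    masks: dict[str, np.ndarray] = {}
    for pid in ids:
        seq = sequences[pid]
        mask = np.zeros(len(seq), dtype=np.uint8)
        for rule in rules:
            start = seq.find(rule.motif)
            while start != -1:
                mask[start : start + spec.motif_length] = 1
                start = seq.find(rule.motif, start + 1)
        masks[pid] = mask

    raw_ann = AnnotationSet(annotations=raw, propagated=False)
    closed = propagate(dag, raw_ann)

    order = list(rng.permutation(ids))
    n_train = int(round(0.7 * len(order)))
    n_val = int(round(0.15 * len(order)))
    splits = {"train": sorted(order[:n_train]),
              "val": sorted(order[n_train : n_train + n_val]),
              "test": sorted(order[n_train + n_val :])}

    return SyntheticDataset(spec=spec, dag=dag, rules=rules, leaf_terms=leaves,
                            structures=structures, sequences=sequences,
                            graphs=graphs, embeddings=embeddings,
                            raw_annotations=raw_ann, annotations=closed,
                            binding_masks=masks, splits=splits)


def oracle_predictions(ds: SyntheticDataset, vocab: TermVocabulary,
                       proteins: list[str]) -> np.ndarray:
    """Evaluate the planted rules directly as a classifier (closure included)."""
    index = vocab.index()
    out = np.zeros((len(proteins), len(vocab)))
    for i, pid in enumerate(proteins):
        density = _contact_density(ds.graphs[pid])
        fired: set[str] = set()
        for rule in ds.rules:
            if rule.fires(ds.sequences[pid], density):
                fired.add(rule.term)
                fired |= ds.dag.ancestors(rule.term)
        fired -= set(ds.dag.roots.values())
        for t in fired:
            j = index.get(t)
            if j is not None:
                out[i, j] = 1.0
    return out


# --------------------------------------------------------------------- writers
def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write the CA trace as a standard PDB file."""
    st = gemmi.Structure()
    st.name = structure.protein_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, rec in enumerate(structure.residues):
        res = gemmi.Residue()
        res.name = rec.name
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*rec.ca)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(sequences):
            fh.write(f">{pid}\n{sequences[pid]}\n")


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Persist every artifact in the standard on-disk formats."""
    outdir = Path(outdir)
    (outdir / "pdb").mkdir(parents=True, exist_ok=True)
    for pid, structure in ds.structures.items():
        write_pdb(structure, outdir / "pdb" / f"{pid}.pdb")
    write_fasta(ds.sequences, outdir / "sequences.fasta")
    write_obo(ds.dag, outdir / "ontology.obo")
    write_annotations(ds.raw_annotations, outdir / "annotations.tsv")
    write_binding_masks(ds.binding_masks, outdir / "binding_sites.tsv")
    save_embeddings(ds.embeddings, outdir / "embeddings.h5")
    (outdir / "splits.json").write_text(json.dumps(ds.splits, indent=2, sort_keys=True) + "\n")
    (outdir / "spec.json").write_text(json.dumps({
        "n_proteins": ds.spec.n_proteins, "length_range": list(ds.spec.length_range),
        "n_terms": ds.spec.n_terms, "dag_depth": ds.spec.dag_depth,
        "motif_length": ds.spec.motif_length,
        "contact_rule_fraction": ds.spec.contact_rule_fraction,
        "plant_prob_range": list(ds.spec.plant_prob_range),
        "label_noise": ds.spec.label_noise,
        "compactness_modes": list(ds.spec.compactness_modes),
        "compact_fraction": ds.spec.compact_fraction,
        "contact_density_threshold": ds.spec.contact_density_threshold,
        "seed": ds.spec.seed}, indent=2, sort_keys=True) + "\n")
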