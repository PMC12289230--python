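"""Gene Ontology handling: DAG parsing, true-path propagation, information
content, and label matrices.

Only ``is_a`` and ``part_of`` relations are retained, the CAFA convention.
Annotations are propagated by the true-path rule (a protein annotated with a
term is implicitly annotated with every ancestor of that term); namespace
roots are excluded everywhere since they carry no information (IC = 0).

Information content of a term is IC(t) = -log2 P(t), where P(t) is the
fraction of training proteins annotated (after propagation) with t among
proteins carrying at least one annotation in the term's namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = {"molecular_function": "MF", "biological_process": "BP",
              "cellular_component": "CC"}
ROOT_IDS = {"MF": "GO:0003674", "BP": "GO:0008150", "CC": "GO:0005575"}


class OntologyError(ValueError):
    pass


@dataclass
class GoDag:
    """A parsed GO DAG restricted to is_a / part_of relations."""

    parents: dict[str, set[str]]
    namespace: dict[str, str]
    roots: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def canonical(self, term: str) -> str:
        return self.alt_ids.get(term, term)

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of `term` (excluding itself), transitively closed."""
        out: set[str] = set()
        frontier = list(self.parents.get(term, ()))
        while frontier:
            t = frontier.pop()
            if t not in out:
                out.add(t)
                frontier.extend(self.parents.get(t, ()))
        return out


@dataclass
class AnnotationSet:
    """Protein -> set of GO term ids."""

    annotations: dict[str, set[str]]
    propagated: bool = False

    def __getitem__(self, protein: str) -> set[str]:
        return self.annotations[protein]

    def __len__(self) -> int:
        return len(self.annotations)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.annotations)


@dataclass
class TermVocabulary:
    """Ordered terms of one namespace with IC and training counts."""

    namespace: str
    terms: list[str]
    ic: dict[str, float]
    train_count: dict[str, int]

    def __len__(self) -> int:
        return len(self.terms)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def ic_vector(self) -> np.ndarray:
        return np.array([self.ic[t] for t in self.terms])


@dataclass
class LabelMatrix:
    proteins: list[str]
    terms: list[str]
    values: np.ndarray  # (n_proteins, n_terms) uint8


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO 1.2 ontology into a :class:`GoDag`.

    Obsolete terms are dropped, alt_ids map to their canonical term, and only
    is_a / part_of edges are kept. A cyclic closure raises an error naming a
    cycle member.
    """
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
    except FileNotFoundError:
        raise
    except OSError:
        raise
    except Exception as exc:  # malformed file
        raise OntologyError(f"could not parse OBO file {path}: {exc}") from exc

    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = NAMESPACES.get(data.get("namespace", ""), None)
        if ns is None:
            continue
        namespace[term] = ns
        pset: set[str] = set()
        for parent in data.get("is_a", []):
            pset.add(parent.split("!")[0].strip())
        for rel in data.get("relationship", []):
            fieldsplit = rel.split("!")[0].split()
            if len(fieldsplit) == 2 and fieldsplit[0] == "part_of":
                pset.add(fieldsplit[1].strip())
        parents[term] = pset
        for alt in data.get("alt_id", []):
            alt_ids[alt.strip()] = term

    # restrict to known terms (targets outside the file or obsolete are dropped)
    for term, pset in parents.items():
        parents[term] = {p for p in pset if p in parents}

    dg = nx.DiGraph((child, parent) for child, pset in parents.items() for parent in pset)
    if not nx.is_directed_acyclic_graph(dg):
        cycle = nx.find_cycle(dg)
        raise OntologyError(f"ontology is cyclic; cycle includes {cycle[0][0]}")

    roots = {}
    for term, pset in parents.items():
        if not pset:
            roots[namespace[term]] = term
    return GoDag(parents=parents, namespace=namespace, roots=roots, alt_ids=alt_ids)


def propagate(dag: GoDag, raw: AnnotationSet) -> AnnotationSet:
    """True-path closure: add every ancestor of each annotated term.

    Namespace roots are excluded from the result. Idempotent; unknown term
    ids raise a validation error listing them.
    """
    root_set = set(dag.roots.values())
    unknown = sorted(
        {dag.canonical(t) for terms in raw.annotations.values() for t in terms}
        - dag.terms
    )
    if unknown:
        raise OntologyError(f"unknown GO terms in annotations: {unknown}")

    closed: dict[str, set[str]] = {}
    for protein, terms in raw.annotations.items():
        full: set[str] = set()
        for t in terms:
            t = dag.canonical(t)
            full.add(t)
            full |= dag.ancestors(t)
        closed[protein] = full - root_set
    return AnnotationSet(annotations=closed, propagated=True)


def compute_ic(train: AnnotationSet, dag: GoDag, namespace: str) -> TermVocabulary:
    """Per-namespace term vocabulary with information content.

    P(t) = (# training proteins annotated with t) / (# training proteins with
    >= 1 term in `namespace`); IC(t) = -log2 P(t). Terms never seen in
    training are excluded (their IC is undefined).
    """
    if namespace not in ROOT_IDS and namespace not in dag.roots:
        raise OntologyError(f"unknown namespace {namespace!r}; expected MF/BP/CC")
    if not train.propagated:
        raise OntologyError("training annotations must be propagated before IC")
    if len(train) == 0:
        raise OntologyError("empty training set")

    counts: dict[str, int] = {}
    n_covered = 0
    for terms in train.annotations.values():
        ns_terms = [t for t in terms if dag.namespace.get(t) == namespace]
        if ns_terms:
            n_covered += 1
        for t in ns_terms:
            counts[t] = counts.get(t, 0) + 1
    if n_covered == 0:
        raise OntologyError(f"no training protein has a {namespace} annotation")

    terms = sorted(counts)
    ic = {t: float(-np.log2(counts[t] / n_covered)) + 0.0 for t in terms}  # +0.0 kills -0.0
    n_dropped = sum(1 for t in dag.terms
                    if dag.namespace.get(t) == namespace and t not in counts)
    if n_dropped:
        logger.info("%d %s terms absent from training set excluded from vocabulary",
                    n_dropped, namespace)
    return TermVocabulary(namespace=namespace, terms=terms, ic=ic, train_count=counts)


def build_label_matrix(ann: AnnotationSet, vocab: TermVocabulary,
                       proteins: list[str] | None = None) -> LabelMatrix:
    """Binary protein x term matrix in vocabulary order.

    Terms outside the vocabulary are dropped (count logged); proteins left
    with no in-vocabulary term get an all-zero row and a warning.
    """
    if not ann.propagated:
        raise OntologyError("annotations must be propagated before building labels")
    if proteins is None:
        proteins = ann.proteins
    index = vocab.index()
    mat = np.zeros((len(proteins), len(vocab)), dtype=np.uint8)
    dropped = 0
    for i, protein in enumerate(proteins):
        terms = ann.annotations.get(protein, set())
        hit = False
        for t in terms:
            j = index.get(t)
            if j is None:
                dropped += 1
            else:
                mat[i, j] = 1
                hit = True
        if terms and not hit:
            logger.warning("protein %s has no in-vocabulary terms (all-zero row)", protein)
    if dropped:
        logger.info("dropped %d annotation pairs outside the vocabulary", dropped)
    return LabelMatrix(proteins=list(proteins), terms=list(vocab.terms), values=mat)


def save_label_matrix(lm: LabelMatrix, prefix: str | Path) -> None:
    """Persist a label matrix as .npy plus plain-text id sidecars."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), lm.values)
    prefix.with_suffix(".proteins.txt").write_text("\n".join(lm.proteins) + "\n")
    prefix.with_suffix(".terms.txt").write_text("\n".join(lm.terms) + "\n")


def load_label_matrix(prefix: str | Path) -> LabelMatrix:
    prefix = Path(prefix)
    return LabelMatrix(
        proteins=prefix.with_suffix(".proteins.txt").read_text().split(),
        terms=prefix.with_suffix(".terms.txt").read_text().split(),
        values=np.load(prefix.with_suffix(".npy")),
    )


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a 2-column TSV (protein_id, GO_id); '#' comment lines allowed."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OntologyError(f"{path}:{lineno}: expected 2 tab-separated fields")
            annotations.setdefault(parts[0], set()).add(parts[1])
    return AnnotationSet(annotations=annotations, propagated=False)


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for protein in ann.proteins:
            for term in sorted(ann.annotations[protein]):
                fh.write(f"{protein}\t{term}\n")
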