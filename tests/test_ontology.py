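"""GO DAG parsing, true-path propagation, information content, labels."""

from __future__ import annotations

import numpy as np
import pytest

from gofuse.ontology import (AnnotationSet, GoDag, OntologyError, build_label_matrix,
                             compute_ic, parse_obo, propagate, read_annotations)
from gofuse.synthetic import make_toy_dag, write_obo

ROOT = "GO:0003674"


def _write(tmp_path, text):
    path = tmp_path / "toy.obo"
    path.write_text(text)
    return path


HEADER = "format-version: 1.2\n"


def _term(tid, ns="molecular_function", **extra):
    lines = [f"\n[Term]\nid: {tid}\nname: {tid}\nnamespace: {ns}\n"]
    for key, values in extra.items():
        for v in (values if isinstance(values, list) else [values]):
            lines.append(f"{key}: {v}\n")
    return "".join(lines)


def chain_dag():
    """root <- A <- B as a GoDag."""
    parents = {ROOT: set(), "GO:000000A": {ROOT}, "GO:000000B": {"GO:000000A"}}
    ns = {t: "MF" for t in parents}
    return GoDag(parents=parents, namespace=ns, roots={"MF": ROOT})


class TestParseObo:
    def test_three_term_chain_parses_parents(self, tmp_path):
        text = HEADER + _term(ROOT) + _term("GO:000000A", is_a=ROOT) + \
            _term("GO:000000B", is_a="GO:000000A")
        dag = parse_obo(_write(tmp_path, text))
        assert dag.parents["GO:000000B"] == {"GO:000000A"}
        assert dag.parents["GO:000000A"] == {ROOT}
        assert dag.roots["MF"] == ROOT

    def test_alt_id_resolves_to_canonical(self, tmp_path):
        text = HEADER + _term(ROOT) + _term("GO:000000A", is_a=ROOT,
                                            alt_id="GO:0999999")
        dag = parse_obo(_write(tmp_path, text))
        assert dag.canonical("GO:0999999") == "GO:000000A"

    def test_part_of_retained_other_relations_dropped(self, tmp_path):
        text = HEADER + _term(ROOT) + _term("GO:000000A", is_a=ROOT) + _term(
            "GO:000000B", is_a=ROOT,
            relationship=["part_of GO:000000A", "regulates GO:000000A"])
        dag = parse_obo(_write(tmp_path, text))
        assert dag.parents["GO:000000B"] == {ROOT, "GO:000000A"}

    def test_obsolete_terms_excluded(self, tmp_path):
        text = HEADER + _term(ROOT) + _term("GO:000000A", is_a=ROOT,
                                            is_obsolete="true")
        dag = parse_obo(_write(tmp_path, text))
        assert "GO:000000A" not in dag.terms

    def test_cycle_raises_validation_error(self, tmp_path):
        text = HEADER + _term("GO:000000A", is_a="GO:000000B") + \
            _term("GO:000000B", is_a="GO:000000A")
        with pytest.raises(OntologyError, match="cycl"):
            parse_obo(_write(tmp_path, text))

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises((OSError, FileNotFoundError)):
            parse_obo(tmp_path / "absent.obo")


class TestPropagate:
    def test_transitive_closure_excludes_root(self):
        dag = chain_dag()
        raw = AnnotationSet({"p1": {"GO:000000B"}})
        closed = propagate(dag, raw)
        assert closed["p1"] == {"GO:000000A", "GO:000000B"}
        assert closed.propagated

    def test_idempotent_on_already_closed_sets(self):
        dag = chain_dag()
        once = propagate(dag, AnnotationSet({"p1": {"GO:000000A", "GO:000000B"}}))
        twice = propagate(dag, once)
        assert once.annotations == twice.annotations

    def test_root_only_annotation_becomes_empty(self):
        closed = propagate(chain_dag(), AnnotationSet({"p1": {ROOT}}))
        assert closed["p1"] == set()

    def test_unknown_term_raises_listing_ids(self):
        with pytest.raises(OntologyError, match="GO:7777777"):
            propagate(chain_dag(), AnnotationSet({"p1": {"GO:7777777"}}))

    def test_idempotent_on_random_toy_dags(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            dag, leaves = make_toy_dag(6, depth=4)
            ann = {f"p{i}": set(rng.choice(leaves, size=2, replace=False))
                   for i in range(8)}
            once = propagate(dag, AnnotationSet(ann))
            twice = propagate(dag, once)
            assert once.annotations == twice.annotations


class TestInformationContent:
    def test_universal_term_has_zero_ic(self):
        dag = chain_dag()
        train = propagate(dag, AnnotationSet({f"p{i}": {"GO:000000A"} for i in range(4)}))
        vocab = compute_ic(train, dag, "MF")
        assert vocab.ic["GO:000000A"] == pytest.approx(0.0)

    def test_quarter_frequency_gives_two_bits(self):
        dag = chain_dag()
        ann = {f"p{i}": {"GO:000000A"} for i in range(4)}
        ann["p0"] = {"GO:000000B"}  # B on 1 of 4 -> P=0.25
        vocab = compute_ic(propagate(dag, AnnotationSet(ann)), dag, "MF")
        assert vocab.ic["GO:000000B"] == pytest.approx(2.0)

    def test_low_frequency_threshold_at_ic_over_ten(self):
        """A term at frequency 2^-11 has IC = 11 bits, past the rare-term cut."""
        n = 2**11
        dag = chain_dag()
        ann = {f"p{i}": {"GO:000000A"} for i in range(n)}
        ann["p0"] = {"GO:000000B"}
        vocab = compute_ic(propagate(dag, AnnotationSet(ann)), dag, "MF")
        assert vocab.ic["GO:000000B"] == pytest.approx(11.0)
        assert vocab.ic["GO:000000B"] > 10.0

    def test_ic_antitone_in_frequency(self, tiny_dataset):
        ds = tiny_dataset
        vocab = compute_ic(ds.annotations, ds.dag, "MF")
        for t1 in vocab.terms:
            for t2 in vocab.terms:
                if vocab.train_count[t1] < vocab.train_count[t2]:
                    assert vocab.ic[t1] > vocab.ic[t2]

    def test_child_count_never_exceeds_parent_count(self, tiny_dataset):
        ds = tiny_dataset
        vocab = compute_ic(ds.annotations, ds.dag, "MF")
        for child, parents in ds.dag.parents.items():
            for parent in parents:
                if child in vocab.train_count and parent in vocab.train_count:
                    assert vocab.train_count[child] <= vocab.train_count[parent]

    def test_empty_training_set_rejected(self):
        with pytest.raises(OntologyError):
            compute_ic(AnnotationSet({}, propagated=True), chain_dag(), "MF")

    def test_unpropagated_training_set_rejected(self):
        with pytest.raises(OntologyError):
            compute_ic(AnnotationSet({"p": {"GO:000000A"}}), chain_dag(), "MF")


class TestLabelMatrix:
    def _vocab(self):
        dag = chain_dag()
        ann = {"p0": {"GO:000000A"}, "p1": {"GO:000000B"}}
        train = propagate(dag, AnnotationSet(ann))
        return dag, compute_ic(train, dag, "MF")

    def test_single_protein_row(self):
        dag, vocab = self._vocab()
        ann = propagate(dag, AnnotationSet({"p": {"GO:000000A"}}))
        lm = build_label_matrix(ann, vocab)
        assert lm.terms == vocab.terms
        row = dict(zip(lm.terms, lm.values[0]))
        assert row["GO:000000A"] == 1 and row["GO:000000B"] == 0

    def test_out_of_vocab_terms_dropped(self):
        dag, vocab = self._vocab()
        small = compute_ic(
            propagate(dag, AnnotationSet({"q": {"GO:000000A"}})), dag, "MF")
        ann = propagate(dag, AnnotationSet({"p": {"GO:000000B"}}))
        lm = build_label_matrix(ann, small)
        # B itself is outside the vocabulary; its ancestor A remains
        assert lm.values[0].sum() == 1

    def test_ancestor_closure_holds_rowwise(self):
        dag, vocab = self._vocab()
        ann = propagate(dag, AnnotationSet({"p": {"GO:000000B"}}))
        lm = build_label_matrix(ann, vocab)
        assert lm.values[0].tolist() == [1, 1]


def test_obo_roundtrip_via_writer(tmp_path):
    """The synthetic OBO writer emits files parse_obo reads back identically."""
    dag, leaves = make_toy_dag(5, depth=3)
    path = tmp_path / "toy.obo"
    write_obo(dag, path)
    parsed = parse_obo(path)
    assert parsed.parents == dag.parents
    assert parsed.namespace == dag.namespace


def test_label_matrix_persistence_roundtrip(tmp_path):
    from gofuse.ontology import LabelMatrix, load_label_matrix, save_label_matrix

    lm = LabelMatrix(proteins=["p1", "p2"], terms=["GO:000000A", "GO:000000B"],
                     values=np.array([[1, 0], [1, 1]], dtype=np.uint8))
    save_label_matrix(lm, tmp_path / "labels")
    back = load_label_matrix(tmp_path / "labels")
    assert back.proteins == lm.proteins and back.terms == lm.terms
    np.testing.assert_array_equal(back.values, lm.values)


def test_annotation_tsv_roundtrip(tmp_path):
    from gofuse.ontology import write_annotations

    ann = AnnotationSet({"p1": {"GO:000000A", "GO:000000B"}, "p2": {"GO:000000A"}})
    path = tmp_path / "ann.tsv"
    write_annotations(ann, path)
    back = read_annotations(path)
    assert back.annotations == ann.annotations
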