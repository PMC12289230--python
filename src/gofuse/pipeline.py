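"""High-level experiment plumbing: vocabulary construction from a dataset's
training split, sample assembly, end-to-end training and evaluation.

These helpers exist so the command-line interface, the examples and the
reproduction script all run the exact same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .metrics import EvalResult, evaluate
from .model import GoTermPredictor, ModelConfig
from .ontology import AnnotationSet, TermVocabulary, build_label_matrix, compute_ic
from .saliency import residue_scores, saliency_auc
from .synthetic import SyntheticDataset
from .train import ProteinSample, TrainConfig, TrainHistory, train

logger = logging.getLogger(__name__)


def vocabulary_from_split(ds: SyntheticDataset, namespace: str = "MF",
                          split: str = "train") -> TermVocabulary:
    """IC-bearing vocabulary computed on the training split only."""
    train_ids = set(ds.splits[split])
    subset = AnnotationSet(
        annotations={p: t for p, t in ds.annotations.annotations.items()
                     if p in train_ids},
        propagated=True)
    return compute_ic(subset, ds.dag, namespace)


def samples_for_split(ds: SyntheticDataset, vocab: TermVocabulary,
                      split: str) -> list[ProteinSample]:
    ids = ds.splits[split]
    labels = build_label_matrix(ds.annotations, vocab, proteins=ids)
    return [
        ProteinSample(protein_id=pid, embedding=ds.embeddings[pid],
                      graph=ds.graphs[pid], labels=labels.values[i])
        for i, pid in enumerate(ids)
    ]


@dataclass
class ExperimentResult:
    model: GoTermPredictor
    vocab: TermVocabulary
    history: TrainHistory
    evaluation: EvalResult
    predictions: np.ndarray      # test proteins x terms
    truth: np.ndarray
    test_ids: list[str]


def run_experiment(ds: SyntheticDataset, cfg: TrainConfig | None = None,
                   model_config: ModelConfig | None = None,
                   namespace: str = "MF") -> ExperimentResult:
    """Train on the train split, early-stop on val, evaluate on test."""
    from .train import label_matrix_of, predict_matrix

    vocab = vocabulary_from_split(ds, namespace)
    model = GoTermPredictor(vocab, model_config)
    train_set = samples_for_split(ds, vocab, "train")
    val_set = samples_for_split(ds, vocab, "val")
    test_set = samples_for_split(ds, vocab, "test")
    _, history = train(model, train_set, val_set, cfg)
    pred = predict_matrix(model, test_set)
    truth = label_matrix_of(test_set)
    result = evaluate(pred, truth, vocab)
    return ExperimentResult(model=model, vocab=vocab, history=history,
                            evaluation=result, predictions=pred, truth=truth,
                            test_ids=list(ds.splits["test"]))


def saliency_aucs(model: GoTermPredictor, ds: SyntheticDataset,
                  protein_ids: list[str]) -> dict[str, float]:
    """Residue-saliency AUC against planted binding sites, per protein.

    Proteins whose mask is degenerate (all 0 or all 1) are skipped.
    """
    out: dict[str, float] = {}
    for pid in protein_ids:
        mask = ds.binding_masks[pid]
        if mask.sum() == 0 or mask.sum() == mask.size:
            continue
        _, record = model.forward(ds.embeddings[pid], ds.graphs[pid])
        scores = residue_scores(record)
        out[pid] = saliency_auc(scores, mask)
    return out
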