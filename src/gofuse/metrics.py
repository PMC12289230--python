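"""Protein-centric evaluation metrics: Fmax, Smin and micro-AUPR.

Definitions follow the CAFA assessment conventions:

* **Fmax** — sweep a threshold grid tau in {0.01, ..., 1.00}; at each tau a
  term is predicted when its score >= tau. Precision is averaged over
  proteins with at least one predicted term, recall over proteins with at
  least one true term; Fmax is the maximum harmonic mean over the grid.
* **Smin** — with per-term information content ic(t), remaining uncertainty
  ru(tau) is the mean summed IC of true-but-missed terms and misinformation
  mi(tau) the mean summed IC of predicted-but-false terms;
  Smin = min_tau sqrt(ru^2 + mi^2).
* **AUPR** — area under the precision-recall curve micro-averaged over all
  (protein, term) pairs, computed by the step-wise interpolation-free rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score

from .ontology import TermVocabulary

DEFAULT_GRID = np.round(np.arange(0.01, 1.005, 0.01), 2)


class MetricError(ValueError):
    pass


@dataclass
class EvalResult:
    fmax: float
    fmax_threshold: float
    smin: float | None
    smin_threshold: float | None
    aupr: float
    curves: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "fmax": self.fmax, "fmax_threshold": self.fmax_threshold,
            "smin": self.smin, "smin_threshold": self.smin_threshold,
            "aupr": self.aupr, "curves": self.curves,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _check_shapes(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise MetricError(f"prediction shape {pred.shape} != truth {truth.shape}")
    if pred.ndim != 2:
        raise MetricError("expected proteins x terms matrices")
    return pred, truth.astype(bool)


def fmax(pred: np.ndarray, truth: np.ndarray,
         grid: np.ndarray = DEFAULT_GRID) -> tuple[float, float]:
    """Protein-centric Fmax and the smallest threshold attaining it."""
    pred, truth = _check_shapes(pred, truth)
    if truth.sum() == 0:
        raise MetricError("truth matrix has no positive annotation")
    has_truth = truth.any(axis=1)
    n_truth = max(int(has_truth.sum()), 1)
    best_f, best_tau = 0.0, float(grid[0])
    precisions, recalls = [], []
    for tau in grid:
        decided = pred >= tau
        n_pred_terms = decided.sum(axis=1)
        covered = n_pred_terms > 0
        tp = (decided & truth).sum(axis=1)
        if covered.any():
            precision = float((tp[covered] / n_pred_terms[covered]).mean())
        else:
            precision = 0.0
        recall_terms = np.zeros(truth.shape[0])
        recall_terms[has_truth] = tp[has_truth] / truth.sum(axis=1)[has_truth]
        recall = float(recall_terms[has_truth].sum() / n_truth)
        precisions.append(precision)
        recalls.append(recall)
        if covered.any() and precision + recall > 0:
            f = 2 * precision * recall / (precision + recall)
            if f > best_f + 1e-12:
                best_f, best_tau = f, float(tau)
    return best_f, best_tau


def smin(pred: np.ndarray, truth: np.ndarray, vocab: TermVocabulary,
         grid: np.ndarray = DEFAULT_GRID) -> tuple[float, float]:
    """IC-weighted semantic distance minimum and its threshold."""
    pred, truth = _check_shapes(pred, truth)
    if len(vocab) != pred.shape[1]:
        raise MetricError(f"vocabulary size {len(vocab)} != {pred.shape[1]} columns")
    missing = [t for t in vocab.terms if t not in vocab.ic]
    if missing:
        raise MetricError(f"missing IC for terms: {missing[:5]}")
    ic = vocab.ic_vector()
    if not np.all(np.isfinite(ic)):
        raise MetricError("non-finite IC values")
    best_s, best_tau = np.inf, float(grid[0])
    for tau in grid:
        decided = pred >= tau
        ru = float(((truth & ~decided) * ic).sum(axis=1).mean())
        mi = float(((decided & ~truth) * ic).sum(axis=1).mean())
        s = float(np.sqrt(ru * ru + mi * mi))
        if s < best_s - 1e-12:
            best_s, best_tau = s, float(tau)
    return best_s, best_tau


def aupr(pred: np.ndarray, truth: np.ndarray) -> float:
    """Micro-averaged area under the precision-recall curve."""
    pred, truth = _check_shapes(pred, truth)
    flat_truth = truth.ravel()
    if flat_truth.sum() == 0:
        raise MetricError("no positive (protein, term) pair")
    return float(average_precision_score(flat_truth, pred.ravel()))


def evaluate(pred: np.ndarray, truth: np.ndarray,
             vocab: TermVocabulary | None = None,
             grid: np.ndarray = DEFAULT_GRID,
             keep_curves: bool = False) -> EvalResult:
    """Full CAFA-style evaluation of a prediction matrix."""
    f, tau_f = fmax(pred, truth, grid)
    if vocab is not None:
        s, tau_s = smin(pred, truth, vocab, grid)
    else:
        s, tau_s = None, None
    a = aupr(pred, truth)
    curves: dict[str, list[float]] = {}
    if keep_curves:
        predm, truthm = _check_shapes(pred, truth)
        has_truth = truthm.any(axis=1)
        n_truth = max(int(has_truth.sum()), 1)
        ic = vocab.ic_vector() if vocab is not None else None
        pr, rc, rus, mis = [], [], [], []
        for tau in grid:
            decided = predm >= tau
            n_pred = decided.sum(axis=1)
            covered = n_pred > 0
            tp = (decided & truthm).sum(axis=1)
            pr.append(float((tp[covered] / n_pred[covered]).mean()) if covered.any() else 0.0)
            rec = tp[has_truth] / truthm.sum(axis=1)[has_truth]
            rc.append(float(rec.sum() / n_truth))
            if ic is not None:
                rus.append(float(((truthm & ~decided) * ic).sum(axis=1).mean()))
                mis.append(float(((decided & ~truthm) * ic).sum(axis=1).mean()))
        curves = {"threshold": [float(t) for t in grid],
                  "precision": pr, "recall": rc}
        if ic is not None:
            curves["ru"] = rus
            curves["mi"] = mis
    return EvalResult(fmax=f, fmax_threshold=tau_f, smin=s, smin_threshold=tau_s,
                      aupr=a, curves=curves)


def propagate_scores_max(pred: np.ndarray, terms: list[str],
                         parents: dict[str, set[str]]) -> np.ndarray:
    """Optional post-hoc consistency: parent score := max(parent, children).

    Off by default in evaluation; provided for DAG-consistent exports.
    """
    index = {t: i for i, t in enumerate(terms)}
    out = np.asarray(pred, dtype=np.float64).copy()
    # iterate children in an order that visits descendants first
    order = sorted(terms, key=lambda t: -len(_ancestors_of(t, parents)))
    for t in order:
        i = index[t]
        for p in parents.get(t, ()):  # push child scores up
            j = index.get(p)
            if j is not None:
                out[:, j] = np.maximum(out[:, j], out[:, i])
    return out


def _ancestors_of(term: str, parents: dict[str, set[str]]) -> set[str]:
    seen: set[str] = set()
    frontier = list(parents.get(term, ()))
    while frontier:
        t = frontier.pop()
        if t not in seen:
            seen.add(t)
            frontier.extend(parents.get(t, ()))
    return seen
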