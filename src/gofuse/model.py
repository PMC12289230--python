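"""The end-to-end predictor: sequence encoder ∥ structure encoder →
cross-attention fusion → per-term probabilities.

A :class:`GoTermPredictor` owns the three sub-modules and the term
vocabulary it predicts over. Checkpoints serialize every weight, the
vocabulary (terms + IC), and the architecture config into a single ``.npz``
file so a trained model can be reloaded for prediction or saliency analysis.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .embeddings import EMBED_DIM, ResidueEmbeddingMatrix
from .fusion import AttentionRecord, FusionPredictor, Prediction
from .layers import DTYPE, Module, sigmoid_np
from .ontology import TermVocabulary
from .sequence_encoder import SequenceEncoder
from .structure import ContactGraph
from .structure_encoder import StructureEncoder


@dataclass
class ModelConfig:
    embed_dim: int = EMBED_DIM
    width: int = 512
    kernels: tuple[int, ...] = (3, 5, 7)
    gnn_hidden: tuple[int, ...] = (512, 256, 256)
    heads: int = 2
    freq_summary: str = "absmean"
    freq_variant: str = "reweight"
    freq_enabled: bool = True
    dropout: float = 0.0   # applied to X, Y and the fused hidden while training
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        data = json.loads(text)
        data["kernels"] = tuple(data["kernels"])
        data["gnn_hidden"] = tuple(data["gnn_hidden"])
        return cls(**data)


class GoTermPredictor(Module):
    """Full sequence+structure GO-term prediction model."""

    def __init__(self, vocab: TermVocabulary, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.vocab = vocab
        rng = np.random.default_rng(self.config.seed)
        c = self.config
        self.sequence_encoder = SequenceEncoder(
            rng, d_in=c.embed_dim, width=c.width, kernels=c.kernels,
            freq_summary=c.freq_summary, freq_variant=c.freq_variant,
            freq_enabled=c.freq_enabled)
        self.structure_encoder = StructureEncoder(
            rng, d_in=c.embed_dim, hidden=c.gnn_hidden)
        self.fusion = FusionPredictor(rng, n_terms=len(vocab),
                                      width=c.width, heads=c.heads)
        self.training = False
        self._dropout_rng = np.random.default_rng(self.config.seed + 1)

    def train_mode(self, training: bool = True,
                   dropout_seed: int | None = None) -> None:
        """Toggle dropout; a fresh seeded mask stream keeps runs reproducible."""
        self.training = training
        if dropout_seed is not None:
            self._dropout_rng = np.random.default_rng(dropout_seed)

    def _dropout(self, t: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p <= 0.0:
            return t
        keep = (self._dropout_rng.random(t.shape) >= p).astype(t.dtype)
        return t * Tensor(keep * (1.0 / (1.0 - p)))

    # ------------------------------------------------------------------ forward
    def forward(self, m: ResidueEmbeddingMatrix | np.ndarray, graph: ContactGraph
                ) -> tuple[Tensor, AttentionRecord]:
        """Logits (n_terms,) plus the retained cross-attention record."""
        matrix = m.matrix if isinstance(m, ResidueEmbeddingMatrix) else np.asarray(m)
        matrix = matrix.astype(DTYPE, copy=False)
        if graph.size != matrix.shape[0]:
            raise ValueError(
                f"contact graph size {graph.size} != embedding rows {matrix.shape[0]}")
        mt = Tensor(matrix)
        x = self._dropout(self.sequence_encoder(mt).X)
        y = self._dropout(self.structure_encoder(mt, graph).Y)
        return self.fusion(x, y, dropout_fn=self._dropout)

    def predict(self, m: ResidueEmbeddingMatrix | np.ndarray, graph: ContactGraph,
                protein_id: str = "") -> tuple[Prediction, AttentionRecord]:
        logits, record = self.forward(m, graph)
        probs = sigmoid_np(logits.data.astype(np.float64))
        pred = Prediction(protein_id=protein_id or graph.protein_id,
                          probabilities=probs, terms=list(self.vocab.terms))
        return pred, record

    # --------------------------------------------------------------- checkpoint
    def save(self, path: str | Path) -> None:
        arrays = {f"param/{k}": v for k, v in self.state_dict().items()}
        arrays["vocab/terms"] = np.array(self.vocab.terms)
        arrays["vocab/ic"] = self.vocab.ic_vector()
        arrays["vocab/train_count"] = np.array(
            [self.vocab.train_count.get(t, 0) for t in self.vocab.terms])
        arrays["meta/config"] = np.array(self.config.to_json())
        arrays["meta/namespace"] = np.array(self.vocab.namespace)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GoTermPredictor":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig.from_json(str(data["meta/config"]))
            terms = [str(t) for t in data["vocab/terms"]]
            ic = {t: float(v) for t, v in zip(terms, data["vocab/ic"])}
            counts = {t: int(v) for t, v in zip(terms, data["vocab/train_count"])}
            vocab = TermVocabulary(namespace=str(data["meta/namespace"]),
                                   terms=terms, ic=ic, train_count=counts)
            model = cls(vocab, config)
            state = {k[len("param/"):]: data[k] for k in data.files
                     if k.startswith("param/")}
        model.load_state_dict(state)
        return model


def write_predictions_tsv(predictions: list[Prediction], path: str | Path) -> None:
    """Export predictions as TSV rows (protein_id, GO_id, probability)."""
    with open(path, "w") as fh:
        for pred in predictions:
            terms = pred.terms or [str(i) for i in range(pred.probabilities.size)]
            for term, p in zip(terms, pred.probabilities):
                fh.write(f"{pred.protein_id}\t{term}\t{p:.6f}\n")
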