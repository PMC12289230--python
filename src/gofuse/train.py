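"""Training loop: Adam on mean per-term binary cross-entropy with
validation-based early stopping.

Defaults follow the reference training recipe (learning rate 1e-4, batch
size 64, up to 100 epochs, early-stopping patience 5). Proteins have
variable length, so a batch is processed as gradient accumulation over
per-protein forward passes — mathematically identical to a padded, masked
batch because the loss is the mean of per-protein losses and pooling divides
by each protein's true length. The checkpoint kept is the weights at the
lowest validation loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import Adam, bce_with_logits
from .model import GoTermPredictor
from .structure import ContactGraph

logger = logging.getLogger(__name__)


@dataclass
class ProteinSample:
    """One training/evaluation instance."""

    protein_id: str
    embedding: np.ndarray      # (L, 1280)
    graph: ContactGraph
    labels: np.ndarray         # (n_terms,) 0/1


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("learning rate, batch size and max epochs must be positive")
        if self.patience <= 0 or self.patience > self.max_epochs:
            raise ValueError("patience must be in [1, max_epochs]")


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,val_loss\n")
            for e, tr, va in zip(self.epochs, self.train_loss, self.val_loss):
                fh.write(f"{e},{tr:.6f},{va:.6f}\n")


class EarlyStopping:
    """Stop when validation loss fails to improve `patience` epochs in a row."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.counter = 0

    def update(self, epoch: int, val_loss: float) -> tuple[bool, bool]:
        """Returns (improved, should_stop)."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.counter = 0
            return True, False
        self.counter += 1
        return False, self.counter >= self.patience


def bce_np(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean BCE from logits, tape-free (for validation)."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    return float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def _dataset_loss(model: GoTermPredictor, samples: list[ProteinSample]) -> float:
    losses = [bce_np(model.forward(s.embedding, s.graph)[0].data, s.labels)
              for s in samples]
    return float(np.mean(losses))


def train(model: GoTermPredictor, train_set: list[ProteinSample],
          val_set: list[ProteinSample], cfg: TrainConfig | None = None,
          ) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Optimize `model` in place; returns (best state dict, history).

    The model is left holding the best-validation-loss weights.
    """
    cfg = cfg or TrainConfig()
    if not train_set or not val_set:
        raise ValueError("training and validation sets must be non-empty")
    n_terms = len(model.vocab)
    for s in train_set + val_set:
        if s.labels.shape != (n_terms,):
            raise ValueError(
                f"label vector of {s.protein_id} has shape {s.labels.shape}, "
                f"expected ({n_terms},)")

    rng = np.random.default_rng(cfg.seed)
    model.train_mode(True, dropout_seed=cfg.seed + 7)
    params = model.parameters()
    optimizer = Adam(params, lr=cfg.learning_rate)
    stopper = EarlyStopping(cfg.patience)
    history = TrainHistory()
    best_state = model.state_dict()

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_losses: list[float] = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[start:start + cfg.batch_size]]
            optimizer.zero_grad()
            total = None
            for sample in batch:
                logits, _ = model.forward(sample.embedding, sample.graph)
                loss = bce_with_logits(logits, sample.labels)
                total = loss if total is None else total + loss
            total = total * (1.0 / len(batch))
            value = float(total.data)
            if not np.isfinite(value):
                stats = {s.protein_id: float(np.abs(s.embedding).max()) for s in batch}
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={cfg.learning_rate}, batch max|M|={max(stats.values()):.3g})")
            total.backward()
            optimizer.step()
            epoch_losses.append(value)

        train_loss = float(np.mean(epoch_losses))
        model.train_mode(False)
        val_loss = _dataset_loss(model, val_set)
        model.train_mode(True)
        history.epochs.append(epoch)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        improved, stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = model.state_dict()
        logger.info("epoch %d: train %.4f val %.4f%s", epoch, train_loss, val_loss,
                    " *" if improved else "")
        if stop:
            history.stopped_early = True
            break

    history.best_epoch = stopper.best_epoch
    model.train_mode(False)
    model.load_state_dict(best_state)
    return best_state, history


def predict_matrix(model: GoTermPredictor, samples: list[ProteinSample]) -> np.ndarray:
    """Stack per-protein probability vectors into a proteins x terms matrix."""
    from .layers import sigmoid_np

    rows = [sigmoid_np(model.forward(s.embedding, s.graph)[0].data.astype(np.float64))
            for s in samples]
    return np.stack(rows)


def label_matrix_of(samples: list[ProteinSample]) -> np.ndarray:
    return np.stack([s.labels for s in samples]).astype(np.uint8)
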