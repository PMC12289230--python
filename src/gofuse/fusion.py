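"""Cross-modal fusion: bidirectional two-head cross-attention between the
sequence features X and structure features Y, followed by residue pooling
and the linear GO-term head.

Per direction and head, the query matrix comes from the query-side modality
and keys/values from the other side: attention = softmax(Q K^T / sqrt(d_k)) V
with d_k = width/heads per head. The two heads' outputs are concatenated per
direction and passed through an output projection. The predictor
concatenates both directions per residue (L x 1024), maps to 512, mean-pools
over residues and applies a linear layer + sigmoid to produce independent
per-term probabilities.

Attention weight matrices are recorded per head and direction so that
residue-level saliency can be derived from them afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .layers import Linear, Module


@dataclass
class AttentionRecord:
    """Row-stochastic L x L attention maps kept from a forward pass.

    Keys are (direction, head) with direction 'seq' (sequence-side queries)
    or 'stru' (structure-side queries).
    """

    weights: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    @property
    def directions(self) -> list[str]:
        return sorted({d for d, _ in self.weights})

    @property
    def n_heads(self) -> int:
        return len({h for _, h in self.weights})

    def matrices(self, direction: str | None = None) -> list[np.ndarray]:
        return [w for (d, _), w in sorted(self.weights.items())
                if direction is None or d == direction]


@dataclass
class Prediction:
    """Per-term probabilities in vocabulary order."""

    protein_id: str
    probabilities: np.ndarray
    terms: list[str] | None = None

    def __post_init__(self):
        p = np.asarray(self.probabilities)
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")


class CrossAttention(Module):
    """One direction of multihead cross-attention (queries from `q_input`)."""

    def __init__(self, width: int, heads: int, rng: np.random.Generator):
        if width % heads != 0:
            raise ValueError(f"width {width} not divisible by heads {heads}")
        self.width = width
        self.heads = heads
        self.d_k = width // heads
        self.wq = [Linear(width, self.d_k, rng, bias=False) for _ in range(heads)]
        self.wk = [Linear(width, self.d_k, rng, bias=False) for _ in range(heads)]
        self.wv = [Linear(width, self.d_k, rng, bias=False) for _ in range(heads)]
        self.proj = Linear(width, width, rng)

    def __call__(self, q_input: Tensor, kv_input: Tensor
                 ) -> tuple[Tensor, list[np.ndarray]]:
        outs, maps = [], []
        scale = 1.0 / np.sqrt(self.d_k)
        for h in range(self.heads):
            q = self.wq[h](q_input)
            k = self.wk[h](kv_input)
            v = self.wv[h](kv_input)
            alpha = ((q @ k.T) * scale).softmax(axis=1)
            maps.append(alpha.data.copy())
            outs.append(alpha @ v)
        return self.proj(concat(outs, axis=1)), maps


class FusionPredictor(Module):
    """Bidirectional cross-attention fusion + pooled linear GO-term head."""

    def __init__(self, rng: np.random.Generator, n_terms: int,
                 width: int = 512, heads: int = 2):
        self.width = width
        self.heads = heads
        self.n_terms = n_terms
        self.seq_attn = CrossAttention(width, heads, rng)   # queries from X
        self.stru_attn = CrossAttention(width, heads, rng)  # queries from Y
        self.combine = Linear(2 * width, width, rng)
        self.head = Linear(width, n_terms, rng)

    def cross_attention(self, x: Tensor, y: Tensor
                        ) -> tuple[Tensor, Tensor, AttentionRecord]:
        if x.shape[0] != y.shape[0]:
            raise ValueError(
                f"sequence ({x.shape[0]}) and structure ({y.shape[0]}) lengths differ")
        att_seq, maps_seq = self.seq_attn(x, y)
        att_stru, maps_stru = self.stru_attn(y, x)
        record = AttentionRecord()
        for h, m in enumerate(maps_seq):
            record.weights[("seq", h)] = m
        for h, m in enumerate(maps_stru):
            record.weights[("stru", h)] = m
        return att_seq, att_stru, record

    def logits(self, att_seq: Tensor, att_stru: Tensor, dropout_fn=None) -> Tensor:
        fused = self.combine(concat([att_seq, att_stru], axis=1)).relu()
        if dropout_fn is not None:
            fused = dropout_fn(fused)
        pooled = fused.mean(axis=0, keepdims=True)  # exact mean over residues
        return self.head(pooled).reshape(-1)

    def predict_terms(self, att_seq: Tensor, att_stru: Tensor,
                      protein_id: str = "", terms: list[str] | None = None
                      ) -> Prediction:
        probs = self.logits(att_seq, att_stru).sigmoid().data
        return Prediction(protein_id=protein_id, probabilities=probs, terms=terms)

    def __call__(self, x: Tensor, y: Tensor, dropout_fn=None
                 ) -> tuple[Tensor, AttentionRecord]:
        att_seq, att_stru, record = self.cross_attention(x, y)
        return self.logits(att_seq, att_stru, dropout_fn), record
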