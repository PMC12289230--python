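"""Structure feature extraction: parallel GCN and GAT stacks on the residue
contact graph, fused by channel concatenation.

Both stacks consume the raw L x 1280 node features. The GCN updates are
H' = ReLU(D_hat^-1/2 (A+I) D_hat^-1/2 H W); the GAT updates aggregate
neighbors (self-loop included) with softmax-normalized attention
coefficients alpha_ij = softmax_j(LeakyReLU(a^T [W h_i || W h_j])), slope
0.2, single head per layer. Three layers each (1280 -> 512 -> 256 -> 256)
give two L x 256 outputs whose concatenation is the structural feature
matrix Y in R^{L x 512}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .layers import DTYPE, Module, glorot_uniform
from .structure import ContactGraph, normalized_adjacency

_NEG_INF = -1e30


@dataclass
class StructureFeatures:
    """Encoder output Y (L x 512)."""

    Y: Tensor


def gcn_layer(h: Tensor, a_norm: Tensor | np.ndarray, w: Tensor) -> Tensor:
    """One graph-convolution update: ReLU(A_norm @ H @ W)."""
    if not isinstance(a_norm, Tensor):
        a_norm = Tensor(np.asarray(a_norm, dtype=h.dtype))
    if h.shape[0] != a_norm.shape[0]:
        raise ValueError(f"H has {h.shape[0]} rows but A_norm is {a_norm.shape}")
    if h.shape[1] != w.shape[0]:
        raise ValueError(f"H width {h.shape[1]} != W input dim {w.shape[0]}")
    return (a_norm @ (h @ w)).relu()


def gat_layer(h: Tensor, neighbor_mask: np.ndarray, w: Tensor, a: Tensor,
              slope: float = 0.2) -> Tensor:
    """One graph-attention update with a single head.

    `neighbor_mask` is the boolean adjacency *with* self-loops; attention
    logits outside it are masked to -inf before the row softmax, so
    sum_j alpha_ij = 1 over N_i for every node i.
    """
    L = h.shape[0]
    if neighbor_mask.shape != (L, L):
        raise ValueError(f"neighbor mask shape {neighbor_mask.shape} != ({L}, {L})")
    wh = h @ w  # (L, d_out)
    d_out = wh.shape[1]
    a_src = a[:d_out].reshape(1, -1)   # scores a^T[Wh_i || Wh_j] split into
    a_dst = a[d_out:].reshape(1, -1)   # source and destination halves
    src = (wh * a_src).sum(axis=1, keepdims=True)        # (L, 1)
    dst = (wh * a_dst).sum(axis=1, keepdims=True)        # (L, 1)
    e = (src + dst.T).leaky_relu(slope)                  # e_ij, (L, L)
    bias = np.where(neighbor_mask, 0.0, _NEG_INF).astype(h.dtype)
    alpha = (e + Tensor(bias)).softmax(axis=1)
    return (alpha @ wh).relu()


class GcnStack(Module):
    def __init__(self, dims: tuple[int, ...], rng: np.random.Generator):
        self.weights = [
            Tensor(glorot_uniform(rng, dims[i], dims[i + 1]), requires_grad=True)
            for i in range(len(dims) - 1)
        ]

    def parameters(self):
        return {f"W{i}": w for i, w in enumerate(self.weights)}

    def __call__(self, h: Tensor, a_norm: Tensor) -> Tensor:
        for w in self.weights:
            h = gcn_layer(h, a_norm, w)
        return h


class GatStack(Module):
    def __init__(self, dims: tuple[int, ...], rng: np.random.Generator):
        self.weights = []
        self.attn = []
        for i in range(len(dims) - 1):
            self.weights.append(
                Tensor(glorot_uniform(rng, dims[i], dims[i + 1]), requires_grad=True))
            self.attn.append(
                Tensor(glorot_uniform(rng, 2 * dims[i + 1], 1,
                                      shape=(2 * dims[i + 1],)), requires_grad=True))

    def parameters(self):
        out = {}
        for i, (w, a) in enumerate(zip(self.weights, self.attn)):
            out[f"W{i}"] = w
            out[f"a{i}"] = a
        return out

    def __call__(self, h: Tensor, neighbor_mask: np.ndarray) -> Tensor:
        for w, a in zip(self.weights, self.attn):
            h = gat_layer(h, neighbor_mask, w, a)
        return h


class StructureEncoder(Module):
    """L x 1280 node features + contact graph -> L x 512 features Y."""

    def __init__(self, rng: np.random.Generator, d_in: int = 1280,
                 hidden: tuple[int, ...] = (512, 256, 256)):
        dims = (d_in,) + tuple(hidden)
        self.d_in = d_in
        self.gcn = GcnStack(dims, rng)
        self.gat = GatStack(dims, rng)

    def __call__(self, m: Tensor | np.ndarray, graph: ContactGraph) -> StructureFeatures:
        if not isinstance(m, Tensor):
            m = Tensor(np.asarray(m, dtype=DTYPE))
        if graph.size != m.shape[0]:
            raise ValueError(
                f"graph has {graph.size} residues but features have {m.shape[0]} rows")
        a_norm = Tensor(normalized_adjacency(graph).astype(m.dtype))
        mask = graph.adjacency | np.eye(graph.size, dtype=bool)
        y_gcn = self.gcn(m, a_norm)
        y_gat = self.gat(m, mask)
        return StructureFeatures(Y=concat([y_gcn, y_gat], axis=1))
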