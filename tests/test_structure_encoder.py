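"""GCN / GAT layers and the parallel structure encoder."""

from __future__ import annotations

import numpy as np
import pytest

from gofuse.autodiff import Tensor
from gofuse.structure import ContactGraph, normalized_adjacency
from gofuse.structure_encoder import StructureEncoder, gat_layer, gcn_layer


def random_graph(rng, L, p=0.4) -> ContactGraph:
    a = rng.random((L, L)) < p
    a = np.triu(a, 1)
    return ContactGraph(adjacency=a | a.T)


def dense_gat_oracle(h, adj_self, w, a_vec, slope=0.2):
    """Brute-force per-node GAT aggregation from the definition."""
    wh = h @ w
    d = wh.shape[1]
    L = h.shape[0]
    out = np.zeros_like(wh)
    for i in range(L):
        neigh = np.where(adj_self[i])[0]
        e = np.array([
            np.concatenate([wh[i], wh[j]]) @ a_vec for j in neigh])
        e = np.where(e > 0, e, slope * e)
        alpha = np.exp(e - e.max())
        alpha /= alpha.sum()
        out[i] = np.maximum(sum(al * wh[j] for al, j in zip(alpha, neigh)), 0.0)
    return out


class TestGcnLayer:
    def test_isolated_node_relu_clips(self):
        h = Tensor(np.array([[-3.0, 2.0]]))
        out = gcn_layer(h, np.array([[1.0]]), Tensor(np.eye(2)))
        np.testing.assert_allclose(out.data, [[0.0, 2.0]])

    def test_two_node_clique_averages(self):
        h = Tensor(np.array([[1.0], [1.0]]))
        g = ContactGraph(adjacency=np.array([[False, True], [True, False]]))
        out = gcn_layer(h, normalized_adjacency(g), Tensor(np.array([[1.0]])))
        np.testing.assert_allclose(out.data, [[1.0], [1.0]])

    def test_matches_dense_oracle_on_random_graphs(self, rng):
        for _ in range(100):
            L = int(rng.integers(1, 7))
            g = random_graph(rng, L)
            h = rng.normal(size=(L, 4))
            w = rng.normal(size=(4, 3))
            got = gcn_layer(Tensor(h), normalized_adjacency(g), Tensor(w)).data
            a_hat = g.adjacency + np.eye(L)
            d_inv = np.diag(1.0 / np.sqrt(a_hat.sum(axis=1)))
            expected = np.maximum(d_inv @ a_hat @ d_inv @ h @ w, 0.0)
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            gcn_layer(Tensor(rng.normal(size=(3, 4))), np.eye(3),
                      Tensor(rng.normal(size=(5, 2))))


class TestGatLayer:
    def test_self_only_node_gets_unit_attention(self, rng):
        h = rng.normal(size=(1, 4))
        w = rng.normal(size=(4, 3))
        a = rng.normal(size=6)
        out = gat_layer(Tensor(h), np.eye(1, dtype=bool), Tensor(w), Tensor(a))
        np.testing.assert_allclose(out.data, np.maximum(h @ w, 0.0), atol=1e-7)

    def test_zero_attention_vector_means_mean_aggregation(self, rng):
        L = 5
        g = random_graph(rng, L)
        mask = g.adjacency | np.eye(L, dtype=bool)
        h = rng.normal(size=(L, 4))
        w = rng.normal(size=(4, 3))
        out = gat_layer(Tensor(h), mask, Tensor(w), Tensor(np.zeros(6)))
        wh = h @ w
        expected = np.stack([np.maximum(wh[mask[i]].mean(axis=0), 0.0)
                             for i in range(L)])
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_matches_dense_oracle_on_random_graphs(self, rng):
        for _ in range(100):
            L = int(rng.integers(1, 7))
            g = random_graph(rng, L)
            mask = g.adjacency | np.eye(L, dtype=bool)
            h = rng.normal(size=(L, 4))
            w = rng.normal(size=(4, 3))
            a = rng.normal(size=6)
            got = gat_layer(Tensor(h), mask, Tensor(w), Tensor(a)).data
            expected = dense_gat_oracle(h, mask, w, a)
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_attention_rows_sum_to_one(self, rng):
        """Softmax normalization over each node's neighborhood."""
        L = 12
        g = random_graph(rng, L)
        mask = g.adjacency | np.eye(L, dtype=bool)
        h = Tensor(rng.normal(size=(L, 6)))
        wh = h @ Tensor(rng.normal(size=(6, 4)))
        a = rng.normal(size=8)
        src = (wh * Tensor(a[:4].reshape(1, -1))).sum(axis=1, keepdims=True)
        dst = (wh * Tensor(a[4:].reshape(1, -1))).sum(axis=1, keepdims=True)
        e = (src + dst.T).leaky_relu(0.2)
        bias = np.where(mask, 0.0, -1e30)
        alpha = (e + Tensor(bias)).softmax(axis=1).data
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(alpha[~mask] < 1e-12)


class TestStructureEncoder:
    def test_output_width_512(self, rng):
        enc = StructureEncoder(rng)
        L = 20
        g = random_graph(rng, L)
        y = enc(rng.normal(size=(L, 1280)).astype(np.float32), g).Y
        assert y.shape == (L, 512)
        assert np.all(np.isfinite(y.data))

    def test_permutation_equivariance(self, rng):
        enc = StructureEncoder(rng)
        L = 10
        g = random_graph(rng, L)
        m = rng.normal(size=(L, 1280)).astype(np.float32)
        perm = rng.permutation(L)
        g_perm = ContactGraph(adjacency=g.adjacency[np.ix_(perm, perm)])
        y = enc(m, g).Y.data
        y_perm = enc(m[perm], g_perm).Y.data
        np.testing.assert_allclose(y_perm, y[perm], atol=1e-4)

    def test_empty_graph_processes_nodes_independently(self, rng):
        enc = StructureEncoder(rng)
        L = 6
        g = ContactGraph(adjacency=np.zeros((L, L), dtype=bool))
        m = rng.normal(size=(L, 1280)).astype(np.float32)
        perm = rng.permutation(L)
        y = enc(m, g).Y.data
        y_perm = enc(m[perm], g).Y.data
        np.testing.assert_allclose(y_perm, y[perm], atol=1e-4)

    @pytest.mark.parametrize("case", ["zero_features", "complete", "chain"])
    def test_no_nan_on_adversarial_inputs(self, rng, case):
        enc = StructureEncoder(rng)
        L = 8
        if case == "zero_features":
            m = np.zeros((L, 1280), dtype=np.float32)
            g = random_graph(rng, L)
        elif case == "complete":
            m = rng.normal(size=(L, 1280)).astype(np.float32) * 100
            g = ContactGraph(adjacency=~np.eye(L, dtype=bool))
        else:
            adj = np.zeros((L, L), dtype=bool)
            for i in range(L - 1):
                adj[i, i + 1] = adj[i + 1, i] = True
            m = rng.normal(size=(L, 1280)).astype(np.float32)
            g = ContactGraph(adjacency=adj)
        y = enc(m, g).Y.data
        assert np.all(np.isfinite(y))

    def test_length_mismatch_rejected(self, rng):
        enc = StructureEncoder(rng)
        with pytest.raises(ValueError, match="residues"):
            enc(rng.normal(size=(5, 1280)).astype(np.float32), random_graph(rng, 4))
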