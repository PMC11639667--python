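"""Graph branch: graph convolution, attention pooling, sub-branch fusion, head.

Each operation is checked against an independent dense/loop oracle built from
scratch inside this module.
"""

import numpy as np
import pytest

from conftest import random_graph
from funfuse._tensor import Tensor
from funfuse.agcn import (AGCNBranch, AGCNSubBranch, AttentionPool, GCNLayer,
                          fuse_subbranches, gcn_propagate, normalized_adjacency)
from funfuse.structure import ContactGraph


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def dense_gcn_oracle(H: np.ndarray, graph: ContactGraph, W: np.ndarray) -> np.ndarray:
    """Explicitly build Ã = A + I and D̃, then ReLU(D̃^-0.5 Ã D̃^-0.5 H W)."""
    L = graph.n_nodes
    A_t = np.eye(L)
    for u, v in graph.edges.T:
        A_t[u, v] = 1.0
        A_t[v, u] = 1.0
    D = np.diag(A_t.sum(axis=1))
    D_inv_sqrt = np.diag(1.0 / np.sqrt(np.diag(D)))
    return np.maximum(D_inv_sqrt @ A_t @ D_inv_sqrt @ H @ W, 0.0)


def attention_oracle(T: np.ndarray, Q: np.ndarray, n_heads: int) -> np.ndarray:
    """Loop over heads, queries and key positions (softmax written out)."""
    m, d_model = Q.shape
    L = T.shape[0]
    D = d_model // n_heads
    out = np.zeros((m, d_model))
    for i in range(n_heads):
        Qi = Q[:, i * D:(i + 1) * D]
        KVi = T[:, i * D:(i + 1) * D]
        for q in range(m):
            logits = np.array([Qi[q] @ KVi[l] / np.sqrt(D) for l in range(L)])
            e = np.exp(logits - logits.max())
            w = e / e.sum()
            out[q, i * D:(i + 1) * D] = sum(w[l] * KVi[l] for l in range(L))
    return out


# ---------------------------------------------------------------------------
# gcn_propagate
# ---------------------------------------------------------------------------


class TestGcnPropagate:
    def test_isolated_node_identity_weight(self):
        g = ContactGraph(n_nodes=1, edges=np.zeros((2, 0)), theta=10.0)
        H = np.array([[-1.0, 2.0]])
        out = gcn_propagate(H, g, np.eye(2)).data
        np.testing.assert_allclose(out, [[0.0, 2.0]])  # normalization collapses to 1

    def test_two_nodes_hand_computation(self):
        g = ContactGraph(n_nodes=2, edges=np.array([[0], [1]]), theta=10.0)
        out = gcn_propagate(np.array([[1.0], [1.0]]), g, np.array([[1.0]])).data
        np.testing.assert_allclose(out, [[1.0], [1.0]])

    def test_matches_dense_oracle_on_random_graphs(self, rng):
        for _ in range(100):
            L = int(rng.integers(2, 51))
            g = random_graph(L, rng)
            H = rng.standard_normal((L, 4))
            W = rng.standard_normal((4, 3))
            np.testing.assert_allclose(gcn_propagate(H, g, W).data,
                                       dense_gcn_oracle(H, g, W), atol=1e-6)

    def test_size_mismatch_raises(self, rng):
        g = random_graph(5, rng)
        with pytest.raises(ValueError, match="nodes"):
            gcn_propagate(rng.standard_normal((4, 2)), g, np.eye(2))


# ---------------------------------------------------------------------------
# attention pooling
# ---------------------------------------------------------------------------


class TestAttentionPool:
    def _pool(self, m, heads, d_model, d_in, rng):
        return AttentionPool(m, heads, d_model, d_in=d_in, rng=rng)

    def test_single_key_returns_value_row(self, rng):
        pool = self._pool(3, 2, 6, d_in=4, rng=rng)
        H = Tensor(rng.standard_normal((1, 4)))
        out = pool(H, Tensor(np.eye(1))).data
        T = np.maximum(H.data @ pool.kv_gcn.weight.data, 0.0)  # Â = I for L = 1
        for q in range(3):  # softmax over one key is 1 regardless of the query
            np.testing.assert_allclose(out[q], T[0], atol=1e-12)

    def test_identical_keys_give_uniform_average(self, rng):
        pool = self._pool(2, 2, 6, d_in=4, rng=rng)
        row = rng.standard_normal(4)
        H = Tensor(np.tile(row, (5, 1)))
        A_hat = Tensor(np.eye(5))
        out, weights = pool.forward_with_weights(H, A_hat)
        for S in weights:
            np.testing.assert_allclose(S, 1.0 / 5, atol=1e-12)
        T = np.maximum(H.data @ pool.kv_gcn.weight.data, 0.0)
        np.testing.assert_allclose(out.data, np.tile(T.mean(axis=0), (2, 1)), atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(2, 11))
            pool = self._pool(2, 2, 6, d_in=3, rng=rng)
            g = random_graph(L, rng)
            H = Tensor(rng.standard_normal((L, 3)))
            A_hat = Tensor(normalized_adjacency(g))
            out = pool(H, A_hat).data
            T = np.maximum(A_hat.data @ H.data @ pool.kv_gcn.weight.data, 0.0)
            Q = pool.query_seed.data @ pool.query_linear.weight.data + pool.query_linear.bias.data
            np.testing.assert_allclose(out, attention_oracle(T, Q, 2), atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        pool = self._pool(4, 2, 8, d_in=5, rng=rng)
        g = random_graph(12, rng)
        out, weights = pool.forward_with_weights(Tensor(rng.standard_normal((12, 5))),
                                                 Tensor(normalized_adjacency(g)))
        for S in weights:
            np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-6)

    def test_m_below_one_rejected(self, rng):
        with pytest.raises(ValueError, match="m must be"):
            AttentionPool(0, 2, 6, d_in=3, rng=rng)


# ---------------------------------------------------------------------------
# sub-branches, fusion, head
# ---------------------------------------------------------------------------


class TestSubBranch:
    def test_output_shape_and_final_m_is_one(self, rng):
        sub = AGCNSubBranch(d_in=8, hidden=6, n_heads=2, m0=3, rng=rng)
        g = random_graph(7, rng)
        out = sub(rng.standard_normal((7, 8)), g)
        assert out.shape == (1, 6)
        assert sub.pool2.m == 1

    def test_node_relabeling_invariance(self, rng):
        sub = AGCNSubBranch(d_in=6, hidden=4, n_heads=2, m0=2, rng=rng)
        L = 9
        g = random_graph(L, rng)
        H = rng.standard_normal((L, 6))
        base = sub(H, g).data

        perm = rng.permutation(L)
        inv = np.argsort(perm)
        # relabel node i -> inv[perm[i]]; consistently permute rows and edges
        H_p = H[perm]
        e = inv[g.edges]
        e.sort(axis=0)
        order = np.lexsort((e[1], e[0]))
        g_p = ContactGraph(n_nodes=L, edges=e[:, order], theta=g.theta)
        # permutation breaks residue order for the LSTM; bypass the context
        # stage to test the graph pipeline's invariance in isolation
        sub2 = AGCNSubBranch(d_in=6, hidden=4, n_heads=2, m0=2, rng=np.random.default_rng(0))
        sub2.load_state_arrays(sub.state_arrays())

        def graph_only(s, feats, graph):
            from funfuse._tensor import as_tensor
            from funfuse.agcn import normalized_adjacency as na
            Hl = as_tensor(feats)
            A_hat = Tensor(na(graph))
            for layer in s.gcn_layers:
                Hl = layer(Hl, A_hat)
            pooled = s.pool1(Hl, A_hat)
            return s.pool2(pooled, Tensor(np.eye(s.pool1.m))).data

        np.testing.assert_allclose(graph_only(sub, H, g), graph_only(sub2, H_p, g_p),
                                   atol=1e-5)

    def test_wrong_width_rejected(self, rng):
        sub = AGCNSubBranch(d_in=8, hidden=6, n_heads=2, m0=3, rng=rng)
        with pytest.raises(ValueError, match="width"):
            sub(rng.standard_normal((7, 5)), random_graph(7, rng))


class TestFuseSubbranches:
    def test_endpoints_and_midpoint(self):
        a = Tensor(np.array([[2.0, 2.0]]))
        b = Tensor(np.array([[4.0, 4.0]]))
        np.testing.assert_allclose(fuse_subbranches(a, b, 1.0).data, a.data)
        np.testing.assert_allclose(fuse_subbranches(a, b, 0.0).data, b.data)
        np.testing.assert_allclose(fuse_subbranches(a, b, 0.5).data, [[3.0, 3.0]])

    def test_output_bounded_by_inputs(self, rng):
        a = rng.standard_normal((1, 8))
        b = rng.standard_normal((1, 8))
        for alpha in rng.random(20):
            out = fuse_subbranches(Tensor(a), Tensor(b), float(alpha)).data
            assert np.all(out >= np.minimum(a, b) - 1e-12)
            assert np.all(out <= np.maximum(a, b) + 1e-12)

    def test_width_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_subbranches(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 4))), 0.5)


class TestBranchHead:
    def _branch(self, rng):
        return AGCNBranch(n_terms=5, lm_dim=16, onehot_dim=8, hidden=8, n_heads=2,
                          m0=2, dropout=0.2, seed=11, context_width=8)

    def test_zero_input_gives_half(self, rng):
        br = self._branch(rng).eval()
        br.head.bias.data[:] = 0.0
        z = Tensor(np.zeros((1, 8)))
        out = br.head(z).relu().sigmoid().data
        np.testing.assert_allclose(out, 0.5)

    def test_scores_in_open_unit_interval_and_deterministic(self, rng):
        br = self._branch(rng).eval()
        g = random_graph(6, rng)
        lm = rng.standard_normal((6, 16))
        tokens = rng.integers(0, 21, size=6)
        s1 = br(lm, tokens, g).data
        s2 = br(lm, tokens, g).data
        assert s1.shape == (5,)
        assert np.all((s1 > 0) & (s1 < 1))
        np.testing.assert_array_equal(s1, s2)

    def test_head_matches_affine_relu_sigmoid_oracle(self, rng):
        br = self._branch(rng).eval()
        x = rng.standard_normal((1, 8))
        out = br.head(Tensor(x)).relu().sigmoid().data
        oracle = 1.0 / (1.0 + np.exp(-np.maximum(
            x @ br.head.weight.data + br.head.bias.data, 0.0)))
        np.testing.assert_allclose(out, oracle, atol=1e-6)

    def test_alpha_is_logistic_of_learnable_scalar(self, rng):
        br = self._branch(rng)
        assert 0.0 < br.alpha < 1.0
        br.alpha_logit.data = np.array(50.0)
        assert br.alpha > 0.999
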