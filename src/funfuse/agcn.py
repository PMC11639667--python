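"""Graph branch: contact-graph convolutions with attention pooling.

Per protein, residue features are first passed through a bidirectional LSTM
for sequential context, then through three graph-convolution layers over the
contact graph,

    H_{l+1} = ReLU( D̃^{-1/2} (A + I) D̃^{-1/2} H_l W_l ),

and finally pooled to a single graph representation by two stages of
learnable-query multi-head attention: m learnable seed queries attend over
the L residue nodes (keys/values produced by one more graph-convolution
transform), then a single query pools the m pooled nodes down to one row.

Two sub-branches of identical architecture consume different input channels —
language-model embeddings alone (width 1280) and their concatenation with the
learnable one-hot embedding (width 1376) — and are merged by a learnable
convex combination before the sigmoid classifier head.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, as_tensor, concat, softmax
from .nn import BiLSTM, Dropout, Embedding, Linear, Module
from .structure import ContactGraph

__all__ = [
    "normalized_adjacency",
    "gcn_propagate",
    "GCNLayer",
    "AttentionPool",
    "AGCNSubBranch",
    "AGCNBranch",
    "fuse_subbranches",
]


def normalized_adjacency(graph: ContactGraph | None, n_nodes: int | None = None) -> np.ndarray:
    """Dense symmetric-normalized adjacency with self-loops, D̃^{-1/2}(A+I)D̃^{-1/2}.

    With ``graph=None`` (used by the second pooling stage, whose m pooled
    nodes carry no edges) this is the identity matrix.
    """
    if graph is None:
        if n_nodes is None:
            raise ValueError("n_nodes required when graph is None")
        return np.eye(n_nodes)
    A_tilde = graph.adjacency() + np.eye(graph.n_nodes)
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)  # degree ≥ 1 thanks to the self-loop
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_propagate(H, graph: ContactGraph, weight) -> Tensor:
    """One graph-convolution layer: ReLU(Â H W) with Â the normalized adjacency."""
    H = as_tensor(H)
    weight = as_tensor(weight)
    if graph.n_nodes != H.shape[0]:
        raise ValueError(f"graph has {graph.n_nodes} nodes but features have {H.shape[0]} rows")
    A_hat = Tensor(normalized_adjacency(graph))
    return (A_hat @ (H @ weight)).relu()


class GCNLayer(Module):
    """Learnable weight for one Eq.-style graph convolution (no bias).

    He-initialized (gain √2) since a ReLU always follows; an extra gain
    factor compensates the contraction of neighbourhood averaging so that
    activations keep a healthy scale through the stacked layers.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, gain: float = 2.0):
        super().__init__()
        self.weight = Tensor(rng.standard_normal((d_in, d_out)) * (gain / np.sqrt(d_in)),
                             requires_grad=True)

    def __call__(self, H: Tensor, A_hat: Tensor) -> Tensor:
        return (A_hat @ (H @ self.weight)).relu()


class AttentionPool(Module):
    """Learnable-query multi-head attention pooling of node features.

    ``m`` seed feature rows (drawn once at initialization, then trained) are
    linearly mapped to queries; keys and values are one graph-convolution
    transform of the input nodes.  Per head i,
    Ψ_i = softmax(Q_i K_iᵀ / √D) V_i with the softmax over the L key
    positions, and the heads are concatenated to an m×(H·D) output.
    """

    def __init__(self, m: int, n_heads: int, d_model: int, d_in: int,
                 rng: np.random.Generator):
        super().__init__()
        if m < 1:
            raise ValueError("m must be ≥ 1")
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.m = m
        self.n_heads = n_heads
        self.head_dim = d_model // n_heads
        self.query_seed = Tensor(rng.standard_normal((m, d_model)), requires_grad=True)
        self.query_linear = Linear(d_model, d_model, rng)
        self.kv_gcn = GCNLayer(d_in, d_model, rng)

    def __call__(self, H: Tensor, A_hat: Tensor) -> Tensor:
        out, _ = self.forward_with_weights(H, A_hat)
        return out

    def forward_with_weights(self, H: Tensor, A_hat: Tensor) -> tuple[Tensor, list[np.ndarray]]:
        """Pooled m×(H·D) output plus per-head attention weight matrices (m×L)."""
        T = self.kv_gcn(H, A_hat)  # (L, d_model): both keys and values
        Q = self.query_linear(self.query_seed)  # (m, d_model)
        D = self.head_dim
        heads: list[Tensor] = []
        weights: list[np.ndarray] = []
        for i in range(self.n_heads):
            sl = slice(i * D, (i + 1) * D)
            Qi, KVi = Q[:, sl], T[:, sl]
            S = softmax((Qi @ KVi.T) * (1.0 / np.sqrt(D)), axis=-1)  # (m, L)
            heads.append(S @ KVi)
            weights.append(S.data)
        return concat(heads, axis=1), weights


class AGCNSubBranch(Module):
    """sequence context → 3 graph convolutions → two-stage attention pooling."""

    def __init__(self, d_in: int, hidden: int, n_heads: int, m0: int,
                 rng: np.random.Generator, n_gcn_layers: int = 3,
                 context_width: int | None = None):
        super().__init__()
        if context_width is not None and context_width % 2:
            raise ValueError("context_width must be even")
        self.d_in = d_in
        self.context = BiLSTM(d_in, rng,
                              hidden=None if context_width is None else context_width // 2)
        dims = [self.context.out_width] + [hidden] * n_gcn_layers
        self.gcn_layers = [GCNLayer(dims[k], dims[k + 1], rng) for k in range(n_gcn_layers)]
        self.pool1 = AttentionPool(m0, n_heads, hidden, d_in=hidden, rng=rng)
        self.pool2 = AttentionPool(1, n_heads, hidden, d_in=hidden, rng=rng)

    def __call__(self, features, graph: ContactGraph) -> Tensor:
        H = as_tensor(features)
        if H.shape[1] != self.d_in:
            raise ValueError(f"sub-branch expects width {self.d_in}, got {H.shape[1]}")
        if graph.n_nodes != H.shape[0]:
            raise ValueError("feature/graph size mismatch")
        A_hat = Tensor(normalized_adjacency(graph))
        H = self.context(H)
        for layer in self.gcn_layers:
            H = layer(H, A_hat)
        pooled = self.pool1(H, A_hat)  # (m0, hidden)
        eye = Tensor(np.eye(self.pool1.m))  # pooled nodes carry no edges
        return self.pool2(pooled, eye)  # (1, hidden)


def fuse_subbranches(a_esm: Tensor, a_concat: Tensor, alpha) -> Tensor:
    """Convex combination α·a_esm + (1−α)·a_concat of the two pooled rows."""
    a_esm, a_concat = as_tensor(a_esm), as_tensor(a_concat)
    if a_esm.shape != a_concat.shape:
        raise ValueError(f"width mismatch {a_esm.shape} vs {a_concat.shape}")
    alpha = as_tensor(alpha)
    return alpha * a_esm + (1.0 - alpha) * a_concat


class AGCNBranch(Module):
    """Full graph branch: two sub-branches, learnable fusion, classifier head.

    Sub-branch 1 sees the language-model channel (L×1280); sub-branch 2 sees
    its concatenation with the branch's own learnable 21×96 token embedding
    (L×1376).  Their pooled rows are merged with a logistic-squashed learnable
    scalar α (initialized at 0.5) and classified by
    sigmoid(dropout(ReLU(affine))).
    """

    def __init__(self, n_terms: int, lm_dim: int = 1280, onehot_dim: int = 96,
                 hidden: int = 512, n_heads: int = 4, m0: int = 32,
                 dropout: float = 0.2, seed: int = 0, n_gcn_layers: int = 3,
                 context_width: int | None = None):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.token_embedding = Embedding(21, onehot_dim, rng)
        self.sub_esm = AGCNSubBranch(lm_dim, hidden, n_heads, m0, rng, n_gcn_layers,
                                     context_width)
        self.sub_concat = AGCNSubBranch(lm_dim + onehot_dim, hidden, n_heads, m0, rng,
                                        n_gcn_layers, context_width)
        self.alpha_logit = Tensor(0.0, requires_grad=True)
        self.head = Linear(hidden, n_terms, rng, gain=np.sqrt(2.0))
        # positive bias keeps sigmoid(ReLU(.)) head units alive at init
        self.head.bias.data[:] = 0.5
        self.dropout = Dropout(dropout, rng)

    @property
    def alpha(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.alpha_logit.data)))

    def __call__(self, lm: np.ndarray, tokens: np.ndarray, graph: ContactGraph) -> Tensor:
        lm_t = as_tensor(lm)
        concat_t = concat([lm_t, self.token_embedding(tokens)], axis=1)
        a_esm = self.sub_esm(lm_t, graph)
        a_concat = self.sub_concat(concat_t, graph)
        alpha = self.alpha_logit.sigmoid()
        a_final = fuse_subbranches(a_esm, a_concat, alpha)
        z = self.head(a_final).relu()
        z = self.dropout(z)
        return z.sigmoid().reshape(-1)  # (C,), each entry a positive probability
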