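"""Convolutional branch: multi-scale 1-D CNN with channel attention.

The residue feature matrix (L×1376, channel-major inside the branch) passes
through a three-stage cascade of same-padding 1-D convolutions
(512→256→128 channels, each conv → batch-norm → ReLU).  The three scale maps
are aligned to 512 channels by 1×1 convolutions, summed, and refined by a
depthwise-separable + 1×1 convolution (the feature-pyramid step).  A bank of
channel-attention heads — each gating channels via
sigmoid(conv_k(avgpool) + conv_k(maxpool)) with a head-specific kernel size —
produces h reweighted maps that are mixed with softmax weights on the
probability simplex.  Global pooling over positions and a
sigmoid(dropout(ReLU(affine))) head yield per-term probabilities.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, as_tensor, softmax
from .nn import BatchNorm1d, Dropout, Embedding, Linear, Module, conv1d

__all__ = [
    "ConvCascade",
    "PyramidFuse",
    "ChannelAttention",
    "MCAM",
    "mcam_mix",
    "MCNNBranch",
]


class ConvCascade(Module):
    """Three cascaded conv→batchnorm→ReLU stages; all scale maps are returned."""

    def __init__(self, d_in: int, rng: np.random.Generator,
                 channels: tuple[int, int, int] = (512, 256, 128),
                 kernels: tuple[int, int, int] = (7, 5, 3)):
        super().__init__()
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        self.norms: list[BatchNorm1d] = []
        prev = d_in
        for c_out, k in zip(channels, kernels):
            fan_in = prev * k
            self.weights.append(Tensor(rng.standard_normal((c_out, prev, k)) / np.sqrt(fan_in),
                                       requires_grad=True))
            self.biases.append(Tensor(np.zeros(c_out), requires_grad=True))
            self.norms.append(BatchNorm1d(c_out))
            prev = c_out

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """x: (d_in, L) channel-major map → maps at the three channel widths."""
        maps = []
        h = x
        for w, b, bn in zip(self.weights, self.biases, self.norms):
            h = bn(conv1d(h, w, b)).relu()
            maps.append(h)
        return tuple(maps)


class PyramidFuse(Module):
    """Align the three scale maps to the widest one, sum, refine.

    The 256- and 128-channel maps are projected to 512 channels by 1×1
    convolutions and summed with the 512-channel map; a depthwise-separable
    convolution followed by a 1×1 convolution refines the sum.
    """

    def __init__(self, rng: np.random.Generator,
                 channels: tuple[int, int, int] = (512, 256, 128), dw_kernel: int = 3):
        super().__init__()
        c0, c1, c2 = channels
        self.proj1_w = Tensor(rng.standard_normal((c0, c1, 1)) / np.sqrt(c1), requires_grad=True)
        self.proj2_w = Tensor(rng.standard_normal((c0, c2, 1)) / np.sqrt(c2), requires_grad=True)
        self.dw_w = Tensor(rng.standard_normal((c0, dw_kernel)) / np.sqrt(dw_kernel),
                           requires_grad=True)
        self.pw_w = Tensor(rng.standard_normal((c0, c0, 1)) / np.sqrt(c0), requires_grad=True)
        self.pw_b = Tensor(np.zeros(c0), requires_grad=True)

    def __call__(self, f0: Tensor, f1: Tensor, f2: Tensor) -> Tensor:
        if not (f0.shape[1] == f1.shape[1] == f2.shape[1]):
            raise ValueError("scale maps must share the position axis length")
        fused = f0 + conv1d(f1, self.proj1_w) + conv1d(f2, self.proj2_w)
        refined = conv1d(fused, self.dw_w, depthwise=True)
        return conv1d(refined, self.pw_w, self.pw_b)


class ChannelAttention(Module):
    """One channel-attention head with a shared 1-D convolution of kernel k.

    Per-channel average- and max-pooled statistics are each passed through
    the same bias-free 1-D convolution acting across the channel axis; the
    sum is squashed by a sigmoid into per-channel gates in [0, 1] that
    rescale the input map.
    """

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError("kernel size must be odd and positive")
        self.kernel = kernel
        self.weight = Tensor(rng.standard_normal((1, 1, kernel)) / np.sqrt(kernel),
                             requires_grad=True)

    def __call__(self, M: Tensor) -> tuple[Tensor, Tensor]:
        """Return (gated map W⊙M, gates W) for a (C, L) map."""
        m_avg = M.mean(axis=1).reshape(1, -1)  # (1, C): channel axis as positions
        m_max = M.max(axis=1).reshape(1, -1)
        gates = (conv1d(m_avg, self.weight) + conv1d(m_max, self.weight)).sigmoid()
        W = gates.reshape(-1, 1)  # (C, 1)
        return M * W, W.reshape(-1)


def mcam_mix(maps: list[Tensor], logits: Tensor) -> Tensor:
    """Softmax-weighted sum of the per-head maps: weights live on the simplex."""
    if len(maps) < 1:
        raise ValueError("need at least one head")
    if any(m.shape != maps[0].shape for m in maps):
        raise ValueError("head maps must share a shape")
    if logits.shape != (len(maps),):
        raise ValueError("one logit per head required")
    alphas = softmax(logits.reshape(1, -1), axis=-1).reshape(-1)
    out = maps[0] * alphas[0:1].reshape(1, 1)
    for i in range(1, len(maps)):
        out = out + maps[i] * alphas[i : i + 1].reshape(1, 1)
    return out


class MCAM(Module):
    """Multi-head channel attention: h heads with distinct kernel sizes."""

    def __init__(self, rng: np.random.Generator, kernels: tuple[int, ...] = (3, 5, 7, 9)):
        super().__init__()
        self.heads = [ChannelAttention(k, rng) for k in kernels]
        self.logits = Tensor(np.zeros(len(kernels)), requires_grad=True)

    @property
    def mixing_weights(self) -> np.ndarray:
        e = np.exp(self.logits.data - self.logits.data.max())
        return e / e.sum()

    def __call__(self, M: Tensor) -> Tensor:
        maps = [head(M)[0] for head in self.heads]
        return mcam_mix(maps, self.logits)


class MCNNBranch(Module):
    """Full convolutional branch over the concatenated residue channel."""

    def __init__(self, n_terms: int, lm_dim: int = 1280, onehot_dim: int = 96,
                 channels: tuple[int, int, int] = (512, 256, 128),
                 kernels: tuple[int, int, int] = (7, 5, 3),
                 cam_kernels: tuple[int, ...] = (3, 5, 7, 9),
                 dropout: float = 0.2, pool: str = "max", seed: int = 0):
        super().__init__()
        if pool not in ("max", "mean"):
            raise ValueError("pool must be 'max' or 'mean'")
        rng = np.random.default_rng(seed)
        self.pool = pool
        self.token_embedding = Embedding(21, onehot_dim, rng)
        self.cascade = ConvCascade(lm_dim + onehot_dim, rng, channels, kernels)
        self.pyramid = PyramidFuse(rng, channels)
        self.mcam = MCAM(rng, cam_kernels)
        self.head = Linear(channels[0], n_terms, rng, gain=np.sqrt(2.0))
        # positive bias keeps sigmoid(ReLU(.)) head units alive at init
        self.head.bias.data[:] = 0.5
        self.dropout = Dropout(dropout, rng)

    def __call__(self, lm: np.ndarray, tokens: np.ndarray) -> Tensor:
        from ._tensor import concat as _concat

        x = _concat([as_tensor(lm), self.token_embedding(tokens)], axis=1).T  # (1376, L)
        f0, f1, f2 = self.cascade(x)
        m_final = self.mcam(self.pyramid(f0, f1, f2))  # (512, L)
        if self.pool == "max":
            pooled = m_final.max(axis=1)
        else:
            pooled = m_final.mean(axis=1)
        z = self.head(pooled.reshape(1, -1)).relu()
        z = self.dropout(z)
        return z.sigmoid().reshape(-1)
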