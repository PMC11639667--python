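"""Neural-network building blocks on top of :mod:`funfuse._tensor`.

Layers follow the usual Module pattern: parameters are ``Tensor`` objects with
``requires_grad=True``, discovered recursively by :meth:`Module.parameters`.
The two sequence-heavy primitives — 1-D convolution and LSTM — carry
hand-written backward passes (checked against finite differences in the test
suite); everything else is composed from autodiff primitives.

Shape conventions: residue-major feature matrices are ``(L, D)``; convolutional
feature maps are channel-major ``(C, L)``.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._tensor import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "Dropout",
    "BatchNorm1d",
    "BiLSTM",
    "Adam",
    "conv1d",
    "lstm",
]


class Module:
    """Base class: parameter discovery plus a train/eval mode flag."""

    def __init__(self):
        self.training = True

    def _children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        for child in self._children():
            out.extend(child.parameters())
        return out

    def train(self) -> "Module":
        self.training = True
        for c in self._children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self._children():
            c.eval()
        return self

    # -- checkpointing ---------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.array(a, dtype=np.float64)


class Linear(Module):
    """Affine layer; use gain=sqrt(2) (He) when a ReLU follows."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True,
                 gain: float = 1.0):
        super().__init__()
        self.weight = Tensor(rng.standard_normal((n_in, n_out)) * (gain / np.sqrt(n_in)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    """Token → row lookup in a learnable table."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.table = Tensor(rng.standard_normal((n_tokens, dim)) / np.sqrt(dim), requires_grad=True)

    def __call__(self, tokens: np.ndarray) -> Tensor:
        tokens = np.asarray(tokens)
        if tokens.size and (tokens.min() < 0 or tokens.max() >= self.table.data.shape[0]):
            raise ValueError("token index out of range for embedding table")
        return self.table.take_rows(tokens)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class BatchNorm1d(Module):
    """Per-channel normalization of a ``(C, L)`` map over the position axis.

    Proteins are processed one at a time, so the "batch" statistics are the
    current protein's own position statistics — instance-normalization
    semantics, applied identically in training and inference (which keeps
    inference deterministic and independent of data ordering).
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((channels, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return self.gamma * xhat + self.beta


# ---------------------------------------------------------------------------
# 1-D convolution primitive
# ---------------------------------------------------------------------------


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None, depthwise: bool = False) -> Tensor:
    """Same-padding 1-D convolution (cross-correlation) over a ``(C_in, L)`` map.

    ``weight`` is ``(C_out, C_in, k)``; for ``depthwise=True`` it is ``(C, k)``
    and each channel is convolved with its own kernel.  ``k`` must be odd so
    the symmetric padding preserves length.
    """
    k = weight.data.shape[-1]
    if k % 2 == 0:
        raise ValueError("kernel size must be odd for symmetric same-padding")
    pad = k // 2
    L = x.data.shape[1]
    xpad = np.pad(x.data, ((0, 0), (pad, pad)))
    cols = np.lib.stride_tricks.sliding_window_view(xpad, k, axis=1)  # (C_in, L, k)

    if depthwise:
        out_data = np.einsum("ck,clk->cl", weight.data, cols)
    else:
        c_in = x.data.shape[0]
        cols2 = np.ascontiguousarray(cols.transpose(1, 0, 2)).reshape(L, c_in * k)
        out_data = (cols2 @ weight.data.reshape(-1, c_in * k).T).T  # (C_out, L)
    if bias is not None:
        out_data = out_data + bias.data[:, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        if depthwise:
            weight._accum(np.einsum("cl,clk->ck", g, cols))
            gcols = np.einsum("cl,ck->clk", g, weight.data)
        else:
            c_in = x.data.shape[0]
            w2 = weight.data.reshape(-1, c_in * k)
            weight._accum((g @ cols2).reshape(weight.data.shape))
            gcols = (g.T @ w2).reshape(L, c_in, k).transpose(1, 0, 2)
        dxpad = np.zeros_like(xpad)
        for j in range(k):
            dxpad[:, j : j + L] += gcols[:, :, j]
        x._accum(dxpad[:, pad : pad + L])
        if bias is not None:
            bias._accum(g.sum(axis=1))

    return Tensor._make(out_data, parents, bwd)


# ---------------------------------------------------------------------------
# LSTM primitive (single direction)
# ---------------------------------------------------------------------------


def lstm(x: Tensor, w_x: Tensor, w_h: Tensor, b: Tensor) -> Tensor:
    """Unidirectional LSTM over an ``(L, D_in)`` sequence, returning ``(L, H)``.

    Gate order in the ``4H`` axis is input, forget, cell, output.  The whole
    recurrence is a single autodiff node with a hand-written BPTT backward.
    """
    L = x.data.shape[0]
    H = w_h.data.shape[0]
    xw = x.data @ w_x.data + b.data  # (L, 4H), input contribution precomputed

    i_s = np.empty((L, H)); f_s = np.empty((L, H))
    g_s = np.empty((L, H)); o_s = np.empty((L, H))
    c_s = np.empty((L, H)); h_s = np.empty((L, H))
    c_prev_s = np.empty((L, H)); h_prev_s = np.empty((L, H))

    h = np.zeros(H); c = np.zeros(H)
    for t in range(L):
        h_prev_s[t] = h; c_prev_s[t] = c
        a = xw[t] + h @ w_h.data
        i = 1.0 / (1.0 + np.exp(-a[:H]))
        f = 1.0 / (1.0 + np.exp(-a[H : 2 * H]))
        g = np.tanh(a[2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-a[3 * H :]))
        c = f * c + i * g
        h = o * np.tanh(c)
        i_s[t], f_s[t], g_s[t], o_s[t], c_s[t], h_s[t] = i, f, g, o, c, h

    def bwd(gout):
        # Collect per-step gate gradients, then reduce with single matmuls.
        DA = np.empty((L, 4 * H))
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(L - 1, -1, -1):
            dh = gout[t] + dh_next
            tc = np.tanh(c_s[t])
            do = dh * tc
            dc = dh * o_s[t] * (1.0 - tc**2) + dc_next
            di = dc * g_s[t]
            dg = dc * i_s[t]
            df = dc * c_prev_s[t]
            dc_next = dc * f_s[t]
            da = DA[t]
            da[:H] = di * i_s[t] * (1.0 - i_s[t])
            da[H : 2 * H] = df * f_s[t] * (1.0 - f_s[t])
            da[2 * H : 3 * H] = dg * (1.0 - g_s[t] ** 2)
            da[3 * H :] = do * o_s[t] * (1.0 - o_s[t])
            dh_next = w_h.data @ da
        x._accum(DA @ w_x.data.T)
        w_x._accum(x.data.T @ DA)
        w_h._accum(h_prev_s.T @ DA)
        b._accum(DA.sum(axis=0))

    return Tensor._make(h_s, (x, w_x, w_h, b), bwd)


class BiLSTM(Module):
    """Bidirectional LSTM over residue order.

    By default the hidden size is ``d_model // 2`` per direction so the layer
    is width preserving (``d_model`` must then be even).  An explicit
    ``hidden`` (per direction) yields output width ``2 * hidden`` instead —
    used to scale the recurrent stage down for CPU-budget training runs.
    """

    def __init__(self, d_model: int, rng: np.random.Generator, hidden: int | None = None):
        super().__init__()
        if hidden is None:
            if d_model % 2:
                raise ValueError("d_model must be even for a width-preserving BiLSTM")
            hidden = d_model // 2
        H = hidden
        self.out_width = 2 * H

        def init(shape, fan_in):
            return Tensor(rng.standard_normal(shape) / np.sqrt(fan_in), requires_grad=True)

        self.wx_f = init((d_model, 4 * H), d_model)
        self.wh_f = init((H, 4 * H), H)
        self.b_f = Tensor(np.zeros(4 * H), requires_grad=True)
        self.wx_b = init((d_model, 4 * H), d_model)
        self.wh_b = init((H, 4 * H), H)
        self.b_b = Tensor(np.zeros(4 * H), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        fwd = lstm(x, self.wx_f, self.wh_f, self.b_f)
        rev = x[np.arange(x.shape[0] - 1, -1, -1)]
        bwd_out = lstm(rev, self.wx_b, self.wh_b, self.b_b)
        bwd_aligned = bwd_out[np.arange(x.shape[0] - 1, -1, -1)]
        return concat([fwd, bwd_aligned], axis=1)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of parameters."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
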