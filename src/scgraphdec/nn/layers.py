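"""Neural layers built on the autodiff engine.

All parameter initialization is driven by an explicit ``numpy`` Generator so
two models built from the same seed are bitwise identical.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, segment_softmax, segment_sum


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    """Minimal module base: parameter discovery by attribute walk."""

    training: bool = False

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]

        def walk(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        for v in vars(self).values():
            walk(v)
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading state")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch when loading state")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(glorot(rng, d_in, d_out))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        normed = centered / ((var + self.eps) ** 0.5)
        return normed * self.gain + self.shift


class Dropout(Module):
    """Seeded inverted dropout; identity outside training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        return x.dropout(self.p, self.rng)


class Conv1dSame(Module):
    """1-D convolution along the bin axis with zero same-padding.

    Input ``(n, c_in)`` -> output ``(n, c_out)``; the window is centered so
    each output bin stays aligned with its genomic locus.
    """

    def __init__(self, window: int, c_in: int, c_out: int, rng: np.random.Generator):
        self.window = window
        self.weight = Parameter(glorot(rng, window * c_in, c_out, shape=(window, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        from .tensor import conv1d_same

        return conv1d_same(x, self.weight, self.bias)


class Conv2dSame(Module):
    """3x3 (configurable, odd) 2-D convolution with zero same-padding.

    Input ``(h, w, c_in)`` -> output ``(h, w, c_out)``.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3):
        fan_in = kernel * kernel * c_in
        self.weight = Parameter(glorot(rng, fan_in, c_out, shape=(kernel, kernel, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        from .tensor import conv2d_same

        return conv2d_same(x, self.weight, self.bias)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention, Q/K/V projections per head.

    Attention logits are scaled by 1/sqrt(d_k) with d_k = d_model / heads;
    softmax rows sum to 1.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng, bias=False)
        self.wk = Linear(d_model, d_model, rng, bias=False)
        self.wv = Linear(d_model, d_model, rng, bias=False)
        self.wo = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        n, d = x.shape
        h, dk = self.n_heads, self.d_k

        def split(t: Tensor) -> Tensor:
            return t.reshape(n, h, dk).transpose(1, 0, 2)  # (h, n, dk)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        logits = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dk))
        attn = logits.softmax(axis=-1)
        self.last_attention = attn.data
        ctx = (attn @ v).transpose(1, 0, 2).reshape(n, d)
        return self.wo(ctx)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block: MHSA + position-wise FFN,
    residual connections and layer normalization around both sublayers."""

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        rng: np.random.Generator,
        d_ff: int | None = None,
        dropout: float = 0.0,
        dropout_rng: np.random.Generator | None = None,
    ):
        d_ff = d_ff or 2 * d_model
        self.norm1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.norm2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.drop = Dropout(dropout, dropout_rng or np.random.default_rng(0))

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.drop(self.attn(self.norm1(x)))
        return x + self.drop(self.ff2(self.ff1(self.norm2(x)).relu()))


class GATLayer(Module):
    """Graph attention with a scalar edge feature in the attention logit.

    Logits are additive: ``a^T LeakyReLU(W1 z_i + W2 z_j + W3 e_ij)`` for an
    edge from neighbor j into node i, normalized by softmax over each node's
    neighborhood N(i). The aggregate adds a learned self-projection
    ``W1 z_i`` (fixed unit coefficient) to the attention-weighted neighbor
    sum — self-loops never compete inside the softmax because the contact
    matrix diagonal is structurally uninformative.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, slope: float = 0.2):
        self.w_self = Linear(d_in, d_out, rng, bias=False)  # W1: source/self
        self.w_nbr = Linear(d_in, d_out, rng, bias=False)  # W2: neighbor
        self.w_edge = Parameter(glorot(rng, 1, d_out, shape=(d_out,)))  # W3: edge lift
        self.att = Parameter(glorot(rng, d_out, 1, shape=(d_out,)))
        self.bias = Parameter(np.zeros(d_out))
        self.slope = slope
        self.last_attention: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def __call__(
        self,
        z: Tensor,
        src: np.ndarray,
        dst: np.ndarray,
        edge_weight: np.ndarray,
    ) -> Tensor:
        """``src[e] -> dst[e]``: edge e carries neighbor src's message to dst."""
        n = z.shape[0]
        zs = self.w_self(z)
        zn = self.w_nbr(z)
        out = zs  # fixed-coefficient self term
        if len(src):
            from .tensor import gat_attention

            agg, alpha = gat_attention(
                zs, zn, edge_weight, self.w_edge, self.att, src, dst, n, self.slope
            )
            self.last_attention = (src.copy(), dst.copy(), alpha)
            out = out + agg
        else:
            self.last_attention = (src, dst, np.empty(0))
        return out + self.bias


class ResidualBlock2d(Module):
    """conv3x3 -> ReLU -> conv3x3 plus identity skip on an (h, w, c) plane."""

    def __init__(self, channels: int, hidden: int, rng: np.random.Generator):
        self.conv1 = Conv2dSame(channels, hidden, rng)
        self.conv2 = Conv2dSame(hidden, channels, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x).relu())
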