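"""A compact reverse-mode automatic-differentiation engine over numpy arrays.

Just enough machinery for the architecture in :mod:`scgraphdec.model`:
broadcasting arithmetic, (batched) matmul, reductions, stable softmax,
gather/scatter primitives for graph message passing, and segment softmax for
per-neighborhood attention normalization. Everything is float64 and fully
deterministic.
"""

from __future__ import annotations

import numpy as np

Arrayish = "np.ndarray | float | int | Tensor"


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev
        self._backward = _backward
        self._grad_borrowed = False

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        # copy-on-write: the first contribution is stored by reference (it may
        # alias another tensor's gradient or be a read-only broadcast view);
        # a second contribution forces an out-of-place add.
        if self.grad is None:
            self.grad = grad
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + grad
            self._grad_borrowed = False
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: all-ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_borrowed = False

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = _bw
        return out

    # -- shape manipulation ------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.shape)
        )
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.transpose(inv)
        )
        return out

    @property
    def T(self):
        return self.transpose()

    def take_rows(self, indices: np.ndarray):
        """Gather rows along axis 0; backward scatter-adds."""
        indices = np.asarray(indices, dtype=np.intp)
        out = Tensor(self.data[indices], _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, indices, g)
                self._accumulate(acc)

        out._backward = _bw
        return out

    def pad_rows(self, before: int, after: int):
        """Zero-pad along axis 0."""
        pad = [(before, after)] + [(0, 0)] * (self.ndim - 1)
        out = Tensor(np.pad(self.data, pad), _prev=(self,))
        n = self.shape[0]
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g[before : before + n]
        )
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    # -- elementwise nonlinearities ----------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.data)
        return out

    def sigmoid(self):
        x = self.data
        y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * out.data * (1.0 - out.data)
        )
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (self.data > 0)
        )
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * np.where(self.data > 0, 1.0, slope)
        )
        return out

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis``."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate((g - dot) * y)

        out._backward = _bw
        return out

    def dropout(self, p: float, rng: np.random.Generator):
        """Inverted dropout; identity when p == 0."""
        if p <= 0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = _bw
    return out


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """1-D convolution along axis 0 with zero same-padding (window centered).

    ``x``: (n, c_in); ``weight``: (w, c_in, c_out); ``bias``: (c_out,).
    """
    w, c_in, c_out = weight.shape
    n = x.shape[0]
    left = (w - 1) // 2
    right = w - 1 - left
    xp = np.pad(x.data, ((left, right), (0, 0)))
    patches = np.lib.stride_tricks.sliding_window_view(xp, w, axis=0)  # (n, c_in, w)
    out_data = np.einsum("ncw,wcd->nd", patches, weight.data) + bias.data
    out = Tensor(out_data, _prev=(x, weight, bias))

    def _bw(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("ncw,nd->wcd", patches, g))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=0))
        if x.requires_grad:
            gp = np.pad(g, ((right, left), (0, 0)))
            gpatches = np.lib.stride_tricks.sliding_window_view(gp, w, axis=0)
            x._accumulate(np.einsum("ndw,wcd->nc", gpatches, weight.data[::-1]))

    out._backward = _bw
    return out


def conv2d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """2-D convolution with zero same-padding over an (h, w, c_in) plane.

    ``weight``: (k, k, c_in, c_out) with odd k; ``bias``: (c_out,).
    """
    k = weight.shape[0]
    pad = (k - 1) // 2
    xp = np.pad(x.data, ((pad, pad), (pad, pad), (0, 0)))
    patches = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(0, 1))
    # patches: (h, w, c_in, k, k)
    out_data = np.einsum("hwcab,abcd->hwd", patches, weight.data) + bias.data
    out = Tensor(out_data, _prev=(x, weight, bias))

    def _bw(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("hwcab,hwd->abcd", patches, g))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            gp = np.pad(g, ((pad, pad), (pad, pad), (0, 0)))
            gpatches = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(0, 1))
            wflip = weight.data[::-1, ::-1]
            x._accumulate(np.einsum("hwdab,abcd->hwc", gpatches, wflip))

    out._backward = _bw
    return out


def segment_softmax(logits: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of 1-D ``logits`` within groups given by ``segment_ids``.

    Used to normalize graph-attention logits over each node's neighborhood;
    rows of the resulting coefficients sum to 1 within every segment.
    """
    seg = np.asarray(segment_ids, dtype=np.intp)
    x = logits.data
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, seg, x)
    e = np.exp(x - seg_max[seg])
    seg_sum = np.zeros(n_segments)
    np.add.at(seg_sum, seg, e)
    y = e / seg_sum[seg]
    out = Tensor(y, _prev=(logits,))

    def _bw(g):
        if logits.requires_grad:
            dot = np.zeros(n_segments)
            np.add.at(dot, seg, g * y)
            logits._accumulate((g - dot[seg]) * y)

    out._backward = _bw
    return out


def gat_attention(
    zs: Tensor,
    zn: Tensor,
    edge_weight: np.ndarray,
    w_edge: Tensor,
    att: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    n_nodes: int,
    slope: float = 0.2,
) -> tuple[Tensor, np.ndarray]:
    """Fused additive graph attention over an edge list.

    For each edge ``src[e] -> dst[e]`` with scalar weight ``edge_weight[e]``:

    * logit  ``l_e = att . LeakyReLU(zs[dst_e] + zn[src_e] + edge_weight_e * w_edge)``
    * coefficient ``alpha_e`` = softmax of ``l_e`` over each destination's
      incoming edges,
    * output row i = sum over incoming edges of ``alpha_e * zn[src_e]``.

    Returns the (n_nodes, d) neighbor aggregate and the attention
    coefficients. One primitive with a hand-written backward: the (E, d)
    intermediates are large enough that fusing the chain matters.
    """
    src = np.asarray(src, dtype=np.intp)
    dst = np.asarray(dst, dtype=np.intp)
    e = np.asarray(edge_weight, dtype=np.float64)
    raw = zs.data[dst] + zn.data[src] + e[:, None] * w_edge.data
    pos = raw > 0
    h = np.where(pos, raw, slope * raw)
    logits = h @ att.data
    seg_max = np.full(n_nodes, -np.inf)
    np.maximum.at(seg_max, dst, logits)
    ex = np.exp(logits - seg_max[dst])
    seg_sum = np.zeros(n_nodes)
    np.add.at(seg_sum, dst, ex)
    alpha = ex / seg_sum[dst]
    zn_src = zn.data[src]
    out_data = np.zeros((n_nodes, zs.shape[1]))
    np.add.at(out_data, dst, alpha[:, None] * zn_src)
    out = Tensor(out_data, _prev=(zs, zn, w_edge, att))

    def _bw(g):
        g_msg = g[dst]
        g_alpha = (g_msg * zn_src).sum(axis=1)
        dot = np.zeros(n_nodes)
        np.add.at(dot, dst, alpha * g_alpha)
        g_logit = (g_alpha - dot[dst]) * alpha
        if att.requires_grad:
            att._accumulate(h.T @ g_logit)
        g_raw = (g_logit[:, None] * att.data) * np.where(pos, 1.0, slope)
        if w_edge.requires_grad:
            w_edge._accumulate(e @ g_raw)
        if zs.requires_grad:
            acc = np.zeros_like(zs.data)
            np.add.at(acc, dst, g_raw)
            zs._accumulate(acc)
        if zn.requires_grad:
            acc = np.zeros_like(zn.data)
            np.add.at(acc, src, g_raw + alpha[:, None] * g_msg)
            zn._accumulate(acc)

    out._backward = _bw
    return out, alpha


def segment_sum(values: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Scatter-add rows of ``values`` into ``n_segments`` output rows."""
    seg = np.asarray(segment_ids, dtype=np.intp)
    acc = np.zeros((n_segments,) + values.shape[1:])
    np.add.at(acc, seg, values.data)
    out = Tensor(acc, _prev=(values,))
    out._backward = lambda g: values.requires_grad and values._accumulate(g[seg])
    return out
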