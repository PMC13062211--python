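"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the segmentation models need: broadcasted
arithmetic, matmul, softmax/log-softmax, 2-D convolution (im2col), 2x max
pooling, nearest-neighbour 2x upsampling, concatenation and slicing.
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _conv_raw(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """Plain NCHW correlation of a pre-padded input (no autograd)."""
    n, c, h, wd = x.shape
    co, ci, kh, kw = w.shape
    s = stride
    ho = (h - kh) // s + 1
    wo = (wd - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    out = cols @ w.reshape(co, -1).T
    return np.ascontiguousarray(out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2))


class Tensor:
    """A numpy array with an optional gradient and a backward graph edge."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        # parents: sequence of (parent_tensor, fn mapping out-grad -> parent-grad)
        self._parents = tuple(parents)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in self._parents
        )

    # ---- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the subgraph that requires grad
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): grad.astype(self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, fn in node._parents:
                if not parent.requires_grad:
                    continue
                pg = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # ---- arithmetic -----------------------------------------------------
    def _lift(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data
        return Tensor(out_data, parents=(
            (self, lambda g: _unbroadcast(g, self.shape)),
            (other, lambda g: _unbroadcast(g, other.shape)),
        ))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(self.data * other.data, parents=(
            (self, lambda g: _unbroadcast(g * other.data, self.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.shape)),
        ))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor(self.data / other.data, parents=(
            (self, lambda g: _unbroadcast(g / other.data, self.shape)),
            (other, lambda g: _unbroadcast(-g * self.data / other.data**2, other.shape)),
        ))

    def __pow__(self, exponent: float):
        out = self.data**exponent
        return Tensor(out, parents=(
            (self, lambda g: g * exponent * self.data ** (exponent - 1)),
        ))

    def __matmul__(self, other):
        other = self._lift(other)
        out = self.data @ other.data

        def grad_a(g, a=self, b=other):
            ga = g @ np.swapaxes(b.data, -1, -2)
            return _unbroadcast(ga, a.shape)

        def grad_b(g, a=self, b=other):
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(gb, b.shape)

        return Tensor(out, parents=((self, grad_a), (other, grad_b)))

    def __getitem__(self, idx):
        out = self.data[idx]

        def grad_fn(g, idx=idx, shape=self.shape, dtype=self.data.dtype):
            full = np.zeros(shape, dtype=dtype)
            full[idx] = g
            return full

        return Tensor(out, parents=((self, grad_fn),))

    # ---- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(self.data.reshape(shape), parents=(
            (self, lambda g: g.reshape(old)),
        ))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor(self.data.transpose(axes), parents=(
            (self, lambda g: g.transpose(inv)),
        ))

    # ---- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g, axis=axis, keepdims=keepdims, shape=self.shape):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Tensor(out, parents=((self, grad_fn),))

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- pointwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=((self, lambda g: g * mask),))

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        out = x * cdf
        return Tensor(out, parents=((self, lambda g: g * (cdf + x * pdf)),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=((self, lambda g: g * out),))

    def log(self):
        return Tensor(np.log(self.data), parents=((self, lambda g: g / self.data),))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, parents=((self, lambda g: g * 0.5 / out),))

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def grad_fn(g, s=s, axis=axis):
            return s * (g - (g * s).sum(axis=axis, keepdims=True))

        return Tensor(s, parents=((self, grad_fn),))

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        s = np.exp(out)

        def grad_fn(g, s=s, axis=axis):
            return g - s * g.sum(axis=axis, keepdims=True)

        return Tensor(out, parents=((self, grad_fn),))

    # ---- structured ops --------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """NCHW convolution via im2col; kernels are (Cout, Cin, kh, kw)."""
        x = self.data
        n, c, h, w = x.shape
        co, ci, kh, kw = weight.shape
        if ci != c:
            raise ValueError(f"conv2d channel mismatch: input {c}, kernel {ci}")
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - kh) // s + 1
        wo = (w + 2 * p - kw) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::s, ::s]                      # (n, c, ho, wo, kh, kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
        w2 = weight.data.reshape(co, -1)
        out = cols @ w2.T                              # (n, ho*wo, co)
        out = out.transpose(0, 2, 1).reshape(n, co, ho, wo)
        if bias is not None:
            out = out + bias.data.reshape(1, co, 1, 1)

        def grad_x(g):
            # dx = (stride-dilated g, padded by k-1) conv flipped/transposed w
            hp, wp = xp.shape[2], xp.shape[3]
            gd = np.zeros((n, co, hp + kh - 1, wp + kw - 1), dtype=x.dtype)
            gd[:, :, kh - 1:kh - 1 + s * (ho - 1) + 1:s,
               kw - 1:kw - 1 + s * (wo - 1) + 1:s] = g
            wflip = np.ascontiguousarray(weight.data[:, :, ::-1, ::-1].swapaxes(0, 1))
            dxp = _conv_raw(gd, wflip, stride=1)
            return dxp[:, :, p:p + h, p:p + w] if p else dxp

        def grad_w(g):
            gt = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(co, n * ho * wo)
            cols_again = (
                np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
                [:, :, ::s, ::s].transpose(0, 2, 3, 1, 4, 5)
                .reshape(n * ho * wo, c * kh * kw)
            )
            return (gt @ cols_again).reshape(co, c, kh, kw)

        parents = [(self, grad_x), (weight, grad_w)]
        if bias is not None:
            parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
        return Tensor(out, parents=parents)

    def maxpool2x2(self) -> "Tensor":
        x = self.data
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def grad_fn(g, idx=idx):
            gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=x.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            return gr.reshape(n, c, h, w)

        return Tensor(out, parents=((self, grad_fn),))

    def upsample2x(self) -> "Tensor":
        """Nearest-neighbour x2 upsampling of an NCHW tensor."""
        x = self.data
        n, c, h, w = x.shape
        out = x.repeat(2, axis=2).repeat(2, axis=3)

        def grad_fn(g):
            return g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))

        return Tensor(out, parents=((self, grad_fn),))


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        size = t.shape[axis]
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(start, start + size)
        sl = tuple(sl)
        parents.append((t, lambda g, sl=sl: g[sl]))
        start += size
    return Tensor(out, parents=parents)
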