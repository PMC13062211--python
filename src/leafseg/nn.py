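"""Small neural-network layer library on top of :mod:`leafseg.autograd`.

Modules hold named :class:`~leafseg.autograd.Tensor` parameters; all weight
initialisation is driven by an explicit ``numpy.random.Generator`` so model
construction is fully deterministic given a seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .autograd import Tensor, concat

DTYPE = np.float32


class Module:
    """Base class: children and parameters are discovered via attributes."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                params[key] = value
            elif isinstance(value, Module):
                params.update(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(prefix=f"{key}.{i}."))
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def freeze(self) -> None:
        for p in self.named_parameters().values():
            p.requires_grad = False

    def state_dict(self) -> dict[str, np.ndarray]:
        # include frozen parameters too: collect ignoring requires_grad
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                state[name] = value.data
            elif isinstance(value, Module):
                for k, v in value.state_dict().items():
                    state[f"{name}.{k}"] = v
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for k, v in item.state_dict().items():
                            state[f"{name}.{i}.{k}"] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self._all_tensors()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)[:5]}")
        for name, tensor in own.items():
            arr = np.asarray(state[name], dtype=tensor.data.dtype)
            if arr.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {tensor.data.shape}")
            tensor.data = arr

    def _all_tensors(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value._all_tensors(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item._all_tensors(prefix=f"{key}.{i}."))
        return out

    def checksum(self) -> str:
        """SHA-256 over all parameter bytes, in sorted name order."""
        h = hashlib.sha256()
        state = self.state_dict()
        for name in sorted(state):
            h.update(name.encode())
            h.update(np.ascontiguousarray(state[name]).tobytes())
        return h.hexdigest()


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape).astype(DTYPE), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.weight = _param(rng, (cout, cin, k, k), fan_in=cin * k * k)
        self.bias = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        self.weight = _param(rng, (din, dout), fan_in=din)
        self.bias = Tensor(np.zeros(dout, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Normalisation over the last axis (transformer-token convention)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gain = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gain + self.bias


class ChannelNorm(Module):
    """Per-location normalisation over the channel axis of NCHW maps."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gain = Tensor(np.ones((1, channels, 1, 1), dtype=DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros((1, channels, 1, 1), dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gain + self.bias


class ConvBlock(Module):
    """Conv3x3 -> channel norm -> ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, stride: int = 1):
        self.conv = Conv2d(cin, cout, 3, rng, stride=stride, padding=1)
        self.norm = ChannelNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).relu()


class SelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.dim = dim
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, t, c = x.shape
        h, dh = self.heads, c // self.heads
        qkv = self.qkv(x)                                  # (n, t, 3c)
        q = qkv[:, :, :c].reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        k = qkv[:, :, c:2 * c].reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * c:].reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, c)
        return self.proj(out)


class TransformerBlock(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator, mlp_ratio: int = 4):
        self.norm1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


def sincos_position_grid(h: int, w: int, dim: int) -> np.ndarray:
    """2-D sine-cosine positional encoding, (h*w, dim); size-agnostic."""
    if dim % 4:
        raise ValueError("positional dim must be divisible by 4")
    d4 = dim // 4
    omega = 1.0 / (100.0 ** (np.arange(d4) / max(d4 - 1, 1)))
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    parts = []
    for coord in (ys.ravel(), xs.ravel()):
        ang = coord[:, None] * omega[None, :]
        parts.extend([np.sin(ang), np.cos(ang)])
    return np.concatenate(parts, axis=1).astype(DTYPE)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


__all__ = [
    "Module", "Conv2d", "Linear", "LayerNorm", "ChannelNorm", "ConvBlock",
    "SelfAttention", "TransformerBlock", "sincos_position_grid", "Adam",
    "Tensor", "concat", "DTYPE",
]
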