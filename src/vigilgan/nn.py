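"""Neural-network layers on top of the autodiff engine.

Layout conventions
------------------
Frame-wise convolutional layers operate on ``(N, H, W, C)`` arrays where the
leading axis folds batch and time frames together (the spatial stack shares
weights across the 2T half-second frames; temporal mixing is the Transformer's
job).  Token layers operate on ``(B, T, D)``.

All randomness is injected through a ``numpy.random.Generator`` so model
construction is fully seeded.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny torch-like module: parameter discovery, train/eval, state dicts."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def _submodules(self) -> Iterator["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for name, arr in state.items():
            if own[name].shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            own[name].data = np.asarray(arr, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu6(x: Tensor) -> Tensor:
    return ad.clamp(x, 0.0, 6.0)


def sigmoid(x: Tensor) -> Tensor:
    # clamp keeps exp in range; gates are fully saturated beyond +-30 anyway
    return 1.0 / (1.0 + ad.texp(ad.clamp(-x, -30.0, 30.0)))


def gelu(x: Tensor) -> Tensor:
    # tanh approximation
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + ad.ttanh(c * (x + 0.044715 * x * x * x)))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = ad.texp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    return shifted - ad.tlog(ad.texp(shifted).sum(axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (n_in + n_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        flat = x.reshape((-1, x.shape[-1])) if x.ndim != 2 else x
        out = flat @ self.weight + self.bias
        if x.ndim != 2:
            out = out.reshape(lead + (self.weight.shape[1],))
        return out


class PointwiseConv(Module):
    """1x1 convolution over the channel axis of (N, H, W, C)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (c_in + c_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        out = x.reshape((n * h * w, c)) @ self.weight + self.bias
        return out.reshape((n, h, w, self.weight.shape[1]))


_PATCH_IDX_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _patch_indices(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column gather indices of 3x3 same-padding patches on a padded map."""
    key = (h, w)
    if key not in _PATCH_IDX_CACHE:
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        ri = rr.reshape(-1, 1) + np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        ci = cc.reshape(-1, 1) + np.array([0, 1, 2, 0, 1, 2, 0, 1, 2])
        _PATCH_IDX_CACHE[key] = (ri, ci)
    return _PATCH_IDX_CACHE[key]


class DepthwiseConv3x3(Module):
    """3x3 depthwise convolution, stride 1, zero same-padding, on (N, H, W, C)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (9 + 1))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(9, channels)))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return ad.dwconv3x3(x, self.weight) + self.bias


class StandardConv3x3(Module):
    """Plain dense 3x3 convolution (the standard-convolution ablation)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan = 9 * c_in
        bound = math.sqrt(6.0 / (fan + c_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(fan, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        padded = ad.pad2d(x, 1)
        ri, ci = _patch_indices(h, w)
        patches = padded[:, ri, ci, :]                # (N, L, 9, C)
        flat = patches.reshape((n * h * w, 9 * c))
        out = flat @ self.weight + self.bias
        return out.reshape((n, h, w, self.weight.shape[1]))


class AvgPool(Module):
    """Non-overlapping average pooling with a (kh, kw) window on (N, H, W, C).

    Trailing rows/columns that do not fill a window are discarded.
    """

    def __init__(self, kh: int, kw: int):
        super().__init__()
        self.kh, self.kw = kh, kw

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        oh, ow = h // self.kh, w // self.kw
        x = x[:, : oh * self.kh, : ow * self.kw, :]
        x = x.reshape((n, oh, self.kh, ow * self.kw, c)).mean(axis=2)
        x = x.reshape((n, oh, ow, self.kw, c)).mean(axis=3)
        return x


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"token width {dim} not divisible by {n_heads} heads")
        self.dim, self.n_heads = dim, n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        hd = d // self.n_heads
        qkv = self.qkv(x).reshape((b, t, 3, self.n_heads, hd))
        qkv = qkv.transpose((2, 0, 3, 1, 4))          # (3, B, H, T, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(hd))
        attn = softmax(scores, axis=-1)
        out = attn @ v                                 # (B, H, T, hd)
        out = out.transpose((0, 2, 1, 3)).reshape((b, t, d))
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm block: LN -> MHSA -> dropout -> residual, LN -> MLP(GELU) -> dropout -> residual."""

    def __init__(self, dim: int, n_heads: int, mlp_hidden: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.drop1 = Dropout(dropout, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_hidden, rng)
        self.fc2 = Linear(mlp_hidden, dim, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop1(self.attn(self.norm1(x)))
        x = x + self.drop2(self.fc2(gelu(self.fc1(self.norm2(x)))))
        return x


class TransformerEncoder(Module):
    """Stack of Transformer blocks with optional learned positional embedding."""

    def __init__(
        self,
        dim: int,
        n_tokens: int,
        n_blocks: int,
        n_heads: int,
        mlp_hidden: int,
        dropout: float,
        rng: np.random.Generator,
        positional: bool = True,
    ):
        super().__init__()
        self.blocks = [
            TransformerBlock(dim, n_heads, mlp_hidden, dropout, rng) for _ in range(n_blocks)
        ]
        self.positional = positional
        if positional:
            self.pos = Parameter(rng.normal(scale=0.02, size=(n_tokens, dim)))

    def forward(self, x: Tensor) -> Tensor:
        if self.positional:
            x = x + self.pos
        for block in self.blocks:
            x = block(x)
        return x


class AdamW:
    """Decoupled weight-decay Adam on a parameter list."""

    def __init__(self, params, lr: float, weight_decay: float = 0.02,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
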