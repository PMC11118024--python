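"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists to train the adversarial model in this package: every
vector-Jacobian product (VJP) is itself expressed in traced primitive
operations, so :func:`grad` with ``create_graph=True`` yields gradients that
can be differentiated again.  That second order is exactly what the
WGAN gradient penalty needs (the penalty is a function of ``dD/dx`` and is
minimized with respect to the critic's weights).

Only the primitives the networks use are implemented: broadcasting
arithmetic, (batched) matmul, reductions, reshaping/transposition, advanced
indexing with its scatter-add adjoint, zero padding, and the clamp used by
ReLU6.  Everything else (sigmoid, softmax, GELU, layer norm, convolutions)
is composed from these in :mod:`vigilgan.nn`.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "no_grad",
    "flop_counter",
    "is_grad_enabled",
    "set_default_dtype",
    "default_dtype",
]

_GRAD_ENABLED = True
_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the dtype every new Tensor is cast to (float32 by default)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily switch the engine's working precision."""
    global _DTYPE
    prev = _DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        _DTYPE = prev


class _FlopCounter:
    """Accumulates multiply-accumulate counts reported by ``matmul``."""

    def __init__(self) -> None:
        self.macs = 0

    @property
    def gflops(self) -> float:
        # multiply-accumulate convention (one MAC = one FLOP), as reported
        # by the common profilers for convolutional models
        return self.macs / 1e9


_ACTIVE_COUNTERS: list[_FlopCounter] = []


@contextlib.contextmanager
def flop_counter():
    """Context manager counting matmul MACs of every traced forward inside."""
    counter = _FlopCounter()
    _ACTIVE_COUNTERS.append(counter)
    try:
        yield counter
    finally:
        _ACTIVE_COUNTERS.remove(counter)


def add_macs(n: int) -> None:
    """Report multiply-accumulates performed outside the matmul primitive
    (used by layers whose inner loop is expressed as shifted elementwise ops)."""
    for c in _ACTIVE_COUNTERS:
        c.macs += int(n)


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array plus the tape needed for reverse-mode differentiation."""

    __slots__ = ("data", "requires_grad", "grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        # sequence of (parent Tensor, vjp callable) pairs
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    # -- autodiff entry points ------------------------------------------------
    def backward(self, gradient: np.ndarray | None = None) -> None:
        """Accumulate ``.grad`` (numpy) on every reachable requires-grad leaf."""
        if gradient is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            gradient = np.ones_like(self.data)
        leaves = [t for t in _toposort(self) if t.requires_grad and not t._parents]
        grads = _backprop(self, Tensor(gradient), create_graph=False)
        for t in leaves:
            g = grads.get(id(t))
            if g is None:
                continue
            arr = np.broadcast_to(g.data, t.shape).copy() if g.shape != t.shape else g.data
            t.grad = arr if t.grad is None else t.grad + arr


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitive machinery
# ---------------------------------------------------------------------------

def _make(data: np.ndarray, parents: Sequence[tuple]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        tracked = tuple((p, vjp) for p, vjp in parents if p.requires_grad or p._parents)
        if tracked:
            out._parents = tracked
            out.requires_grad = True
    return out


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data + b.data,
        [
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(g, b.shape)),
        ],
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, [(a, lambda g: neg(g))])


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data * b.data,
        [
            (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
            (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
        ],
    )


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    return _make(a.data**p, [(a, lambda g: mul(g, mul(power(a, p - 1.0), p)))])


# NOTE: vjps must never close over the op's own output tensor — that would
# create child->parent->child reference cycles and defer all graph memory to
# the cyclic garbage collector.  exp/tanh therefore recompute in their vjp.

def texp(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.exp(a.data), [(a, lambda g: mul(g, texp(a)))])


def tlog(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), [(a, lambda g: mul(g, power(a, -1.0)))])


def ttanh(a) -> Tensor:
    a = as_tensor(a)

    def vjp(g: Tensor) -> Tensor:
        t = ttanh(a)
        return mul(g, add(1.0, neg(mul(t, t))))

    return _make(np.tanh(a.data), [(a, vjp)])


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data
    if _ACTIVE_COUNTERS:
        batch = int(np.prod(data.shape[:-2])) if data.ndim > 2 else 1
        if a.data.ndim == 1 or b.data.ndim == 1:
            macs = int(np.prod(data.shape)) * (a.shape[-1] if a.ndim > 1 else a.shape[0])
        else:
            macs = batch * data.shape[-2] * data.shape[-1] * a.shape[-1]
        for c in _ACTIVE_COUNTERS:
            c.macs += macs

    def _swap(t: Tensor) -> Tensor:
        axes = list(range(t.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return transpose(t, tuple(axes))

    if a.data.ndim == 1 or b.data.ndim == 1:
        raise ValueError("matmul requires operands with ndim >= 2")

    return _make(
        data,
        [
            (a, lambda g: _unbroadcast(matmul(g, _swap(b)), a.shape)),
            (b, lambda g: _unbroadcast(matmul(_swap(a), g), b.shape)),
        ],
    )


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g: Tensor) -> Tensor:
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % a.ndim for ax in axes)
        if not keepdims:
            shape = tuple(1 if i in axes else s for i, s in enumerate(a.shape))
            g = reshape(g, shape)
        return broadcast_to(g, a.shape)

    return _make(data, [(a, vjp)])


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def broadcast_to(a, shape: tuple) -> Tensor:
    a = as_tensor(a)
    return _make(np.broadcast_to(a.data, shape), [(a, lambda g: _unbroadcast(g, a.shape))])


def reshape(a, shape: tuple) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, a.shape))])


def transpose(a, axes: tuple | None = None) -> Tensor:
    a = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), [(a, lambda g: transpose(g, inv))])


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    shape = a.shape
    return _make(a.data[idx], [(a, lambda g: scatter_add(shape, idx, g))])


def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (slice, int, np.integer)) or i is Ellipsis for i in items)


def scatter_add(shape: tuple, idx, src) -> Tensor:
    """Zeros of ``shape`` with ``src`` added at ``idx`` (adjoint of getitem)."""
    src = as_tensor(src)
    out = np.zeros(shape, dtype=src.data.dtype)
    if _is_basic_index(idx):
        out[idx] += src.data  # basic indices never alias; += is much faster
    else:
        np.add.at(out, idx, src.data)
    return _make(out, [(src, lambda g: getitem(g, idx))])


_DW_OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]


def _dw_apply(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 depthwise correlation, stride 1, same zero padding.

    ``x`` is (N, H, W, C), ``w`` is (9, C) in row-major kernel order.
    """
    n, h, wd, c = x.shape
    xpad = np.zeros((n, h + 2, wd + 2, c), dtype=x.dtype)
    xpad[:, 1:-1, 1:-1, :] = x
    out = np.zeros_like(x)
    for k, (di, dj) in enumerate(_DW_OFFSETS):
        out += xpad[:, di : di + h, dj : dj + wd, :] * w[k]
    return out


def dwconv3x3(x, w) -> Tensor:
    """Depthwise 3x3 convolution primitive; ``w`` has shape (9, C).

    Registered as a primitive (rather than composed from nine shifted
    multiplies) to keep tape length short; its vector-Jacobian products are
    themselves primitives, so the gradient penalty's second-order pass
    works through it.
    """
    x, w = as_tensor(x), as_tensor(w)
    if _ACTIVE_COUNTERS:
        add_macs(x.size * 9)
    return _make(
        _dw_apply(x.data, w.data),
        [
            (x, lambda g: dwconv3x3(g, _flipk(w))),
            (w, lambda g: dwgrad3x3(x, g)),
        ],
    )


def _flipk(w: Tensor) -> Tensor:
    return getitem(w, (slice(None, None, -1), slice(None)))


def dwgrad3x3(x, g) -> Tensor:
    """Kernel gradient of dwconv3x3: (9, C) from input x and upstream g."""
    x, g = as_tensor(x), as_tensor(g)
    n, h, wd, c = x.shape
    xpad = np.zeros((n, h + 2, wd + 2, c), dtype=x.data.dtype)
    xpad[:, 1:-1, 1:-1, :] = x.data
    out = np.empty((9, c), dtype=x.data.dtype)
    for k, (di, dj) in enumerate(_DW_OFFSETS):
        out[k] = np.einsum("nijc,nijc->c", xpad[:, di : di + h, dj : dj + wd, :], g.data)
    return _make(
        out,
        [
            (x, lambda s: dwconv3x3(g, _flipk(s))),
            (g, lambda s: dwconv3x3(x, s)),
        ],
    )


def clamp(a, lo: float | None = None, hi: float | None = None) -> Tensor:
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask = mask * (a.data > lo)
    if hi is not None:
        mask = mask * (a.data < hi)
    return _make(data, [(a, lambda g: mul(g, Tensor(mask)))])


def pad2d(a, pad: int) -> Tensor:
    """Zero-pad the two middle axes of an (N, H, W, C) tensor."""
    a = as_tensor(a)
    width = ((0, 0), (pad, pad), (pad, pad), (0, 0))
    sl = (slice(None), slice(pad, a.shape[1] + pad), slice(pad, a.shape[2] + pad), slice(None))
    return _make(np.pad(a.data, width), [(a, lambda g: getitem(g, sl))])


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        n = t.shape[axis]
        sl = tuple(
            slice(start, start + n) if i == axis % data.ndim else slice(None)
            for i in range(data.ndim)
        )
        parents.append((t, (lambda s: (lambda g: getitem(g, s)))(sl)))
        start += n
    return _make(data, parents)


# ---------------------------------------------------------------------------
# backpropagation
# ---------------------------------------------------------------------------

def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order


def _backprop(
    root: Tensor,
    seed: Tensor,
    create_graph: bool,
    needed: set[int] | None = None,
) -> dict:
    """Reverse sweep.  Retains gradients only for ids in ``needed`` (or for
    every requires-grad leaf when ``needed`` is None) so intermediate grads
    are freed as soon as their node has been processed."""
    grads: dict[int, Tensor] = {id(root): seed}
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    result: dict[int, Tensor] = {}
    with ctx:
        for node in reversed(_toposort(root)):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            keep = (
                id(node) in needed
                if needed is not None
                else (node.requires_grad and not node._parents)
            )
            if keep:
                result[id(node)] = g
            for parent, vjp in node._parents:
                pg = vjp(g)
                pid = id(parent)
                if pid in grads:
                    grads[pid] = add(grads[pid], pg)
                else:
                    grads[pid] = pg
    return result


def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own tape and
    can be differentiated again (used by the gradient penalty).
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    inputs = list(inputs)
    seed = Tensor(np.ones_like(output.data))
    grads = _backprop(output, seed, create_graph=create_graph, needed={id(t) for t in inputs})
    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        elif g.shape != t.shape:
            g = broadcast_to(g, t.shape) if create_graph else Tensor(np.broadcast_to(g.data, t.shape))
        out.append(g)
    return out
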