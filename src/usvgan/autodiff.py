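"""Minimal reverse-mode automatic differentiation on numpy arrays.

The adversarial training loop needs gradients of network outputs with
respect to both parameters and *inputs*, and the gradient penalty needs
derivatives of those input-gradients with respect to the parameters
(second-order, mixed).  To support this, every vector-Jacobian product
below is itself composed of primitive operations on :class:`Tensor`, so
:func:`grad` can be applied to the output of :func:`grad`.

Only the operations the networks require are provided: elementwise
arithmetic, matmul, reshaping, gather/scatter along the time axis (the
building blocks of 1-D convolution), and the activations.  Arrays keep
whatever dtype they are given; the networks use float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "concat",
    "conv1d",
    "conv1d_transpose",
    "dense",
    "exp",
    "leaky_relu",
    "matmul",
    "dilate",
    "narrow",
    "pad_zeros",
    "patch_gather",
    "patch_scatter",
    "relu",
    "scatter_last",
    "scatter_per_sample",
    "sqrt",
    "take_last",
    "take_per_sample",
    "tanh",
]


class Tensor:
    """A numpy array plus the graph edge that produced it.

    ``parents`` is a tuple of input Tensors and ``_vjp`` maps the
    cotangent (gradient of the final scalar with respect to this node)
    to cotangents of each parent.  Leaf tensors have no parents.
    """

    __slots__ = ("data", "parents", "_vjp")

    def __init__(self, data, parents=(), vjp=None):
        if isinstance(data, Tensor):
            raise TypeError("Tensor cannot wrap a Tensor")
        self.data = np.asarray(data)
        self.parents = parents
        self._vjp = vjp

    # -- array-like properties ------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def __repr__(self):  # pragma: no cover - debugging aid
        leaf = "leaf" if not self.parents else "node"
        return f"Tensor({leaf}, shape={self.shape}, dtype={self.dtype})"

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other, like=self))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other, like=self))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __truediv__(self, other):
        return self * (as_tensor(other, like=self) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) * (self ** -1.0)

    def __pow__(self, p):
        return pow_const(self, float(p))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other, like=self))

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x, like=None):
    """Wrap ``x`` as a constant leaf Tensor (no-op on Tensors)."""
    if isinstance(x, Tensor):
        return x
    dtype = like.dtype if isinstance(like, Tensor) else None
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and arr.dtype.kind == "f":
        arr = arr.astype(dtype)
    return Tensor(arr)


# ---------------------------------------------------------------------
# broadcasting helper (built from primitives, so it is differentiable)
# ---------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(
        i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1
    )
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = g.reshape(shape)
    return g


# ---------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out._vjp = lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    out._vjp = lambda g: (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))
    return out


def pow_const(a: Tensor, p: float) -> Tensor:
    out = Tensor(a.data ** p, (a,))
    out._vjp = lambda g: (g * (a ** (p - 1.0)) * p,)
    return out


def sqrt(a: Tensor) -> Tensor:
    return pow_const(a, 0.5)


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), (a,))
    out._vjp = lambda g: (g * out,)
    return out


def tanh(a: Tensor) -> Tensor:
    out = Tensor(np.tanh(a.data), (a,))
    out._vjp = lambda g: (g * (1.0 - out * out),)
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    # The slope mask is constant w.r.t. differentiation (exact a.e.).
    mask = np.where(a.data > 0, 1.0, slope).astype(a.dtype, copy=False)
    out = Tensor(a.data * mask, (a,))
    out._vjp = lambda g: (g * Tensor(mask),)
    return out


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))
    out._vjp = lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g))
    return out


def transpose(a: Tensor, axes=None) -> Tensor:
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = Tensor(a.data.transpose(axes), (a,))
    out._vjp = lambda g: (transpose(g, inv),)
    return out


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape
    out = Tensor(a.data.reshape(shape), (a,))
    out._vjp = lambda g: (reshape(g, old),)
    return out


def broadcast_to(a: Tensor, shape) -> Tensor:
    old = a.shape
    out = Tensor(np.broadcast_to(a.data, shape), (a,))
    out._vjp = lambda g: (_unbroadcast(g, old),)
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        axis_t = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axis_t = (axis % a.ndim,)
    else:
        axis_t = tuple(ax % a.ndim for ax in axis)
    shape = a.shape
    out = Tensor(a.data.sum(axis=axis_t, keepdims=keepdims), (a,))

    def vjp(g):
        if not keepdims:
            kshape = tuple(1 if i in axis_t else s for i, s in enumerate(shape))
            g = g.reshape(kshape)
        return (broadcast_to(g, shape),)

    out._vjp = vjp
    return out


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.size
    elif isinstance(axis, int):
        n = a.shape[axis]
    else:
        n = int(np.prod([a.shape[ax] for ax in axis]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors, axis=0) -> Tensor:
    tensors = tuple(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.shape[axis] for t in tensors]
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).tolist()

    def vjp(g):
        return tuple(
            narrow(g, axis, int(s), int(n)) for s, n in zip(starts, sizes)
        )

    out._vjp = vjp
    return out


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    axis = axis % a.ndim
    sl = tuple(
        slice(start, start + length) if i == axis else slice(None)
        for i in range(a.ndim)
    )
    total = a.shape[axis]
    out = Tensor(a.data[sl], (a,))
    out._vjp = lambda g: (pad_zeros(g, axis, start, total - start - length),)
    return out


def pad_zeros(a: Tensor, axis: int, before: int, after: int) -> Tensor:
    axis = axis % a.ndim
    width = [(0, 0)] * a.ndim
    width[axis] = (before, after)
    new_len = a.shape[axis]
    out = Tensor(np.pad(a.data, width), (a,))
    out._vjp = lambda g: (narrow(g, axis, before, new_len),)
    return out


def take_last(a: Tensor, idx) -> Tensor:
    """Gather ``a[..., idx]`` with a flat integer index array."""
    idx = np.asarray(idx, dtype=np.intp)
    size = a.shape[-1]
    out = Tensor(a.data[..., idx], (a,))
    out._vjp = lambda g: (scatter_last(g, idx, size),)
    return out


def scatter_last(a: Tensor, idx, size: int) -> Tensor:
    """Scatter-add along the last axis: ``out[..., idx[j]] += a[..., j]``."""
    idx = np.asarray(idx, dtype=np.intp)
    flat = a.data.reshape(-1, a.shape[-1])
    out_t = np.zeros((size, flat.shape[0]), dtype=a.dtype)
    np.add.at(out_t, idx, flat.T)
    out_data = out_t.T.reshape(a.shape[:-1] + (size,))
    out = Tensor(out_data, (a,))
    out._vjp = lambda g: (take_last(g, idx),)
    return out


def patch_gather(a: Tensor, k: int, stride: int) -> Tensor:
    """All length-k windows at the given stride: (m, c, L) -> (m, c, l_out, k)."""
    view = np.lib.stride_tricks.sliding_window_view(a.data, k, axis=2)
    data = view[:, :, ::stride]
    l_in = a.shape[-1]
    out = Tensor(data, (a,))
    out._vjp = lambda g: (patch_scatter(g, l_in, stride),)
    return out


def patch_scatter(a: Tensor, size: int, stride: int) -> Tensor:
    """Overlap-add transpose of :func:`patch_gather` (col2im)."""
    m, c, l_out, k = a.shape
    out_data = np.zeros((m, c, size), dtype=a.dtype)
    for kk in range(k):
        out_data[:, :, kk:kk + stride * l_out:stride] += a.data[:, :, :, kk]
    out = Tensor(out_data, (a,))
    out._vjp = lambda g: (patch_gather(g, k, stride),)
    return out


def dilate(a: Tensor, stride: int) -> Tensor:
    """Zero-stuffing upsample: out[..., i*stride] = a[..., i], length L*stride."""
    length = a.shape[-1]
    out_data = np.zeros(a.shape[:-1] + (length * stride,), dtype=a.dtype)
    out_data[..., ::stride] = a.data
    out = Tensor(out_data, (a,))
    out._vjp = lambda g: (_strided_pick(g, stride, length),)
    return out


def _strided_pick(a: Tensor, stride: int, length: int) -> Tensor:
    out = Tensor(a.data[..., ::stride][..., :length], (a,))
    out._vjp = lambda g: (dilate(g, stride),)
    return out


def take_per_sample(a: Tensor, idx) -> Tensor:
    """Per-sample gather on (m, c, t): ``out[i, :, t] = a[i, :, idx[i, t]]``."""
    idx = np.asarray(idx, dtype=np.intp)
    size = a.shape[-1]
    out = Tensor(np.take_along_axis(a.data, idx[:, None, :], axis=2), (a,))
    out._vjp = lambda g: (scatter_per_sample(g, idx, size),)
    return out


def scatter_per_sample(a: Tensor, idx, size: int) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)
    m, c, t = a.shape
    out_data = np.zeros((m, c, size), dtype=a.dtype)
    ii = np.arange(m)[:, None, None]
    cc = np.arange(c)[None, :, None]
    np.add.at(out_data, (ii, cc, idx[:, None, :]), a.data)
    out = Tensor(out_data, (a,))
    out._vjp = lambda g: (take_per_sample(g, idx),)
    return out


# ---------------------------------------------------------------------
# composite layers
# ---------------------------------------------------------------------

def dense(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = matmul(x, w)
    if b is not None:
        out = out + b
    return out


def conv1d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    pad: tuple[int, int] = (0, 0),
) -> Tensor:
    """Cross-correlation of (m, C, L) with kernels (O, C, K)."""
    m, c, length = x.shape
    o, c2, k = w.shape
    if c2 != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    pl, pr = pad
    if pl or pr:
        x = pad_zeros(x, 2, pl, pr)
    lp = length + pl + pr
    l_out = (lp - k) // stride + 1
    patches = patch_gather(x, k, stride)              # (m, C, L_out, K)
    patches = patches.transpose(0, 2, 1, 3).reshape(m * l_out, c * k)
    out = matmul(patches, transpose(w.reshape(o, c * k)))   # (m*L_out, O)
    out = out.reshape(m, l_out, o).transpose(0, 2, 1)
    if b is not None:
        out = out + b.reshape(1, o, 1)
    return out


def conv1d_transpose(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 4,
) -> Tensor:
    """Upsample by zero-stuffing (factor ``stride``), then same-pad conv.

    Output length is exactly ``stride`` times the input length, matching
    the length-doubling/quadrupling arithmetic of the generator stack.
    """
    m, c, length = x.shape
    k = w.shape[2]
    stuffed = dilate(x, stride)
    pl = (k - 1) // 2
    pr = k - 1 - pl
    return conv1d(stuffed, w, b, stride=1, pad=(pl, pr))


# ---------------------------------------------------------------------
# reverse-mode driver
# ---------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, wrt, cotangent: Tensor | None = None):
    """Gradients of ``output`` with respect to each tensor in ``wrt``.

    The returned gradients are Tensors wired into the graph, so they can
    themselves be differentiated (used by the gradient penalty).
    """
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)
    if cotangent is None:
        cotangent = Tensor(np.ones(output.shape, dtype=output.dtype))
    order = _toposort(output)
    cot: dict[int, Tensor] = {id(output): cotangent}
    for node in reversed(order):
        g = cot.get(id(node))
        if g is None or node._vjp is None:
            continue
        for parent, pg in zip(node.parents, node._vjp(g)):
            if pg is None:
                continue
            prev = cot.get(id(parent))
            cot[id(parent)] = pg if prev is None else prev + pg
    grads = [
        cot.get(id(w)) if cot.get(id(w)) is not None else Tensor(np.zeros(w.shape, dtype=w.dtype))
        for w in wrt_list
    ]
    return grads[0] if single else grads
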