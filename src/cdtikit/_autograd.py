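"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine used by the tensor de-noising
networks.  Backward rules are themselves expressed in terms of traced
primitives, so gradients of gradients are exact — this is what makes the
Wasserstein gradient penalty (a loss on the norm of an input gradient)
trainable with ordinary backpropagation.

Only the operations the de-noising stack needs are implemented: elementwise
arithmetic, matmul, reductions, shape ops, im2col/col2im for convolution,
and a handful of nonlinearities.  Everything runs in single precision
and is fully deterministic given seeded initializers.
"""

from __future__ import annotations

import numpy as np

#: Network dtype: single precision is ample for de-noising and twice as fast.
DTYPE = np.float32

__all__ = ["Tensor", "grad", "concatenate", "Parameter"]


class Tensor:
    """A numpy array with an autograd tape entry."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp", "grad")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), vjp=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._vjp = vjp if self.requires_grad else None
        self.grad: "Tensor | None" = None

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, pow_const(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), pow_const(self, -1.0))

    def __pow__(self, p):
        return pow_const(self, p)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a gradient back to the shape it was broadcast from."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)), keepdims=False)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return reshape(g, shape)


# ---------------------------------------------------------------------------
# Primitives.  Each returns a Tensor whose vjp maps the output cotangent
# (a Tensor) to parent cotangents (Tensors), using traced ops throughout.
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b),
                 vjp=lambda g: (_unbroadcast(g, a.shape),
                                _unbroadcast(g, b.shape)))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data * b.data, parents=(a, b),
                  vjp=lambda g: (_unbroadcast(mul(g, b), a.shape),
                                 _unbroadcast(mul(g, a), b.shape)))


def pow_const(a: Tensor, p: float) -> Tensor:
    p = float(p)
    return Tensor(
        a.data ** p, parents=(a,),
        vjp=lambda g: (mul(g, mul(Tensor(p), pow_const(a, p - 1.0))),),
    )


def sqrt(a: Tensor) -> Tensor:
    return pow_const(a, 0.5)


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), parents=(a,), vjp=None)
    out._vjp = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.data), parents=(a,),
                  vjp=lambda g: (mul(g, pow_const(a, -1.0)),))


def absolute(a: Tensor) -> Tensor:
    sign = Tensor(np.sign(a.data))
    return Tensor(np.abs(a.data), parents=(a,),
                  vjp=lambda g: (mul(g, sign),))


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    slope = Tensor(np.where(a.data > 0, 1.0, alpha))
    return Tensor(np.where(a.data > 0, a.data, alpha * a.data),
                  parents=(a,), vjp=lambda g: (mul(g, slope),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g: Tensor):
        ga = matmul(g, _swap_last(b))
        gb = matmul(_swap_last(a), g)
        return (_unbroadcast_mat(ga, a.shape), _unbroadcast_mat(gb, b.shape))

    return Tensor(a.data @ b.data, parents=(a, b), vjp=vjp)


def _swap_last(a: Tensor) -> Tensor:
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def _unbroadcast_mat(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)), keepdims=False)
    axes = tuple(i for i in range(len(shape) - 2) if shape[i] == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        axis_t = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axis_t = (axis % a.ndim,)
    else:
        axis_t = tuple(ax % a.ndim for ax in axis)

    def vjp(g: Tensor):
        gd = g
        if not keepdims:
            kshape = tuple(1 if i in axis_t else s for i, s in enumerate(a.shape))
            gd = reshape(gd, kshape)
        return (broadcast_to(gd, a.shape),)

    return Tensor(a.data.sum(axis=axis_t, keepdims=keepdims),
                  parents=(a,), vjp=vjp)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    elif isinstance(axis, int):
        n = a.shape[axis]
    else:
        n = int(np.prod([a.shape[ax] for ax in axis]))
    return mul(tsum(a, axis, keepdims), Tensor(1.0 / n))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    return Tensor(np.broadcast_to(a.data, shape), parents=(a,),
                  vjp=lambda g: (_unbroadcast(g, a.shape),))


def reshape(a: Tensor, shape: tuple) -> Tensor:
    return Tensor(a.data.reshape(shape), parents=(a,),
                  vjp=lambda g: (reshape(g, a.shape),))


def transpose(a: Tensor, axes: tuple) -> Tensor:
    inv = tuple(np.argsort(axes))
    return Tensor(a.data.transpose(axes), parents=(a,),
                  vjp=lambda g: (transpose(g, inv),))


def getitem(a: Tensor, idx) -> Tensor:
    def vjp(g: Tensor):
        return (scatter(g, a.shape, idx),)

    return Tensor(a.data[idx], parents=(a,), vjp=vjp)


def scatter(g: Tensor, shape: tuple, idx) -> Tensor:
    """Embed ``g`` into zeros of ``shape`` at ``idx`` (adjoint of getitem)."""
    out = np.zeros(shape, dtype=DTYPE)
    out[idx] = g.data
    return Tensor(out, parents=(g,), vjp=lambda gg: (getitem(gg, idx),))


def concatenate(tensors: list, axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g: Tensor):
        grads = []
        for i, t in enumerate(tensors):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            grads.append(getitem(g, tuple(idx)))
        return tuple(grads)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), vjp=vjp)


def pad2d(a: Tensor, pad: int) -> Tensor:
    """Zero-pad the trailing two axes symmetrically."""
    if pad == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    idx = tuple([slice(None)] * (a.ndim - 2)
                + [slice(pad, -pad), slice(pad, -pad)])
    return Tensor(np.pad(a.data, width), parents=(a,),
                  vjp=lambda g: (getitem(g, idx),))


# -- im2col / col2im (convolution backbone) ---------------------------------

def _unfold_np(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]              # (n, c, ho, wo, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols)


def _fold_np(cols: np.ndarray, x_shape: tuple, k: int, stride: int) -> np.ndarray:
    n, c, h, w = x_shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    win = cols.reshape(n, c, k, k, ho, wo)
    out = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                win[:, :, i, j]
    return out


def unfold(a: Tensor, k: int, stride: int) -> Tensor:
    """im2col: (N, C, H, W) -> (N, C*k*k, L) patches; adjoint is ``fold``."""
    shape = a.shape

    def vjp(g: Tensor):
        return (fold(g, shape, k, stride),)

    return Tensor(_unfold_np(a.data, k, stride), parents=(a,), vjp=vjp)


def fold(cols: Tensor, x_shape: tuple, k: int, stride: int) -> Tensor:
    """col2im with overlap-add: exact adjoint of ``unfold``."""

    def vjp(g: Tensor):
        return (unfold(g, k, stride),)

    return Tensor(_fold_np(cols.data, x_shape, k, stride),
                  parents=(cols,), vjp=vjp)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with a fused vjp.

    Backward: g_a = s * (g - sum(g * s)), expressed in traced ops on the
    saved output so second derivatives remain exact.
    """
    e = np.exp(a.data - a.data.max(axis=axis, keepdims=True))
    s_data = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s_data, parents=(a,), vjp=None)

    def vjp(g: Tensor):
        gs = mul(g, out)
        return (add(gs, mul(out, -tsum(gs, axis=axis, keepdims=True))),)

    out._vjp = vjp
    return out


# ---------------------------------------------------------------------------
# Backward pass
# ---------------------------------------------------------------------------

def grad(output: Tensor, inputs: list, grad_output: Tensor | None = None,
         accumulate: bool = False) -> list:
    """Cotangents of ``output`` with respect to ``inputs``.

    The returned gradients are Tensors built with traced ops, so they can be
    differentiated again (double backprop).  With ``accumulate=True`` the
    gradients are also added into each leaf's ``.grad`` slot (as plain
    constants) for optimizer use.
    """
    if grad_output is None:
        grad_output = Tensor(np.ones(output.shape, dtype=DTYPE))

    result = []
    collected = _collect_input_grads(output, inputs, grad_output)
    for x, gx in zip(inputs, collected):
        if gx is None:
            gx = Tensor(np.zeros(x.shape, dtype=DTYPE))
        result.append(gx)
        if accumulate:
            if x.grad is None:
                x.grad = Tensor(gx.data.copy())
            else:
                x.grad.data += gx.data
    return result


def _collect_input_grads(output: Tensor, inputs: list,
                         grad_output: Tensor) -> list:
    """Single clean reverse sweep retaining cotangents of ``inputs``."""
    topo: list[Tensor] = []
    seen = set()
    stack = [(output, False)]
    while stack:
        t, done = stack.pop()
        if done:
            topo.append(t)
            continue
        if id(t) in seen or not t.requires_grad:
            continue
        seen.add(id(t))
        stack.append((t, True))
        for p in t._parents:
            stack.append((p, False))

    wanted = {id(x) for x in inputs}
    cot: dict[int, Tensor] = {id(output): grad_output}
    saved: dict[int, Tensor] = {}
    for node in reversed(topo):
        g = cot.pop(id(node), None)
        if g is None:
            continue
        if id(node) in wanted:
            saved[id(node)] = g
        if node._vjp is None:
            continue
        for p, pg in zip(node._parents, node._vjp(g)):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in cot:
                cot[id(p)] = add(cot[id(p)], pg)
            else:
                cot[id(p)] = pg
    return [saved.get(id(x)) for x in inputs]


class Parameter(Tensor):
    """A trainable leaf tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
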