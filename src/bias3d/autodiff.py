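"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ndarray and records, for every operation executed
while gradients are enabled, a closure that maps the output gradient to
gradient contributions on the operation's inputs.  Calling
:meth:`Tensor.backward` on a scalar loss walks the recorded tape in reverse
topological order and accumulates gradients on every tensor created with
``requires_grad=True``.

Only the operations the search model needs are provided: elementwise
arithmetic, matmul, the activations, softmax, 2-D same-padded convolution,
2x2 max-pooling, local response normalization, concatenation, reshape,
reductions and single-element gather.  All operations are batched over a
leading sample axis where that is meaningful.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import expit

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable tape recording inside the block (e.g. target-network forwards)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def grad_enabled():
    return _grad_enabled


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        # first contribution adopts the array; later ones add out-of-place so
        # a gradient shared between parents is never mutated
        self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        # iterative topological sort: recursion would overflow on long BPTT tapes
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()
                node.grad = None  # free intermediate grads; leaves keep theirs

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division not supported")
        return mul(self, 1.0 / other)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def astensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward):
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Sum gradient g down to `shape` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- arithmetic ------------------------------------------------------------

def add(a, b):
    if not isinstance(b, Tensor) and not isinstance(a, Tensor):
        raise TypeError("at least one Tensor operand required")
    if not isinstance(b, Tensor):
        a = astensor(a)
        c = b

        def bw(g, a=a):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))

        return _make(a.data + c, (a,), bw)
    if not isinstance(a, Tensor):
        return add(b, a)

    def bw(g, a=a, b=b):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), bw)


def sub(a, b):
    if isinstance(b, Tensor):
        return add(a, mul(b, -1.0))
    return add(a, -b)


def mul(a, b):
    if not isinstance(b, Tensor):
        a = astensor(a)
        c = b

        def bw(g, a=a, c=c):
            if a.requires_grad:
                a._accum(_unbroadcast(g * c, a.data.shape))

        return _make(a.data * c, (a,), bw)
    if not isinstance(a, Tensor):
        return mul(b, a)

    def bw(g, a=a, b=b):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), bw)


def matmul(a, b):
    a, b = astensor(a), astensor(b)

    def bw(g, a=a, b=b):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), bw)


# -- activations -----------------------------------------------------------

def relu(x):
    x = astensor(x)
    mask = x.data > 0

    def bw(g, x=x, mask=mask):
        x._accum(g * mask)

    return _make(x.data * mask, (x,), bw)


def sigmoid(x):
    x = astensor(x)
    s = expit(x.data)

    def bw(g, x=x, s=s):
        x._accum(g * s * (1.0 - s))

    return _make(s, (x,), bw)


def tanh(x):
    x = astensor(x)
    t = np.tanh(x.data)

    def bw(g, x=x, t=t):
        x._accum(g * (1.0 - t * t))

    return _make(t, (x,), bw)


def log(x):
    x = astensor(x)

    def bw(g, x=x):
        x._accum(g / x.data)

    return _make(np.log(x.data), (x,), bw)


def softmax(x, axis=-1):
    x = astensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def bw(g, x=x, p=p, axis=axis):
        inner = (g * p).sum(axis=axis, keepdims=True)
        x._accum(p * (g - inner))

    return _make(p, (x,), bw)


# -- shape ops -------------------------------------------------------------

def reshape(x, shape):
    x = astensor(x)
    old = x.data.shape

    def bw(g, x=x, old=old):
        x._accum(g.reshape(old))

    return _make(x.data.reshape(shape), (x,), bw)


def concat(tensors, axis=-1):
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g, tensors=tensors, sizes=sizes, axis=axis):
        splits = np.cumsum(sizes[:-1])
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def tsum(x, axis=None, keepdims=False):
    x = astensor(x)

    def bw(g, x=x, axis=axis, keepdims=keepdims):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(np.broadcast_to(g, x.data.shape).copy())

    return _make(x.data.sum(axis=axis, keepdims=keepdims), (x,), bw)


def tmean(x, axis=None, keepdims=False):
    x = astensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def narrow(x, lo, hi):
    """Slice [lo, hi) along the last axis."""
    x = astensor(x)

    def bw(g, x=x, lo=lo, hi=hi):
        gx = np.zeros_like(x.data)
        gx[..., lo:hi] = g
        x._accum(gx)

    return _make(x.data[..., lo:hi], (x,), bw)


def pick(x, index):
    """Select a single element of a 1-D tensor (keeps the graph connected)."""
    x = astensor(x)
    flat = x.data.reshape(-1)
    index = int(index)

    def bw(g, x=x, index=index):
        gx = np.zeros_like(x.data).reshape(-1)
        gx[index] = g
        x._accum(gx.reshape(x.data.shape))

    return _make(flat[index], (x,), bw)


# -- fused layer ops -------------------------------------------------------
# These collapse common layer patterns into single tape nodes; at the tiny
# per-sample array sizes of this model the tape bookkeeping, not the FLOPs,
# dominates runtime.

def linear(x, w, b=None, act=None):
    """y = act(x @ w + b) with act in {None, 'relu', 'tanh'}."""
    x, w = astensor(x), astensor(w)
    if b is not None:
        b = astensor(b)
    y = x.data @ w.data
    if b is not None:
        y = y + b.data
    if act == "relu":
        y = np.maximum(y, 0.0)
    elif act == "tanh":
        y = np.tanh(y)
    elif act is not None:
        raise ValueError(f"unknown activation {act!r}")
    parents = (x, w) if b is None else (x, w, b)

    def bw(g, x=x, w=w, b=b, y=y, act=act):
        if act == "relu":
            g = g * (y > 0)
        elif act == "tanh":
            g = g * (1.0 - y * y)
        if x.requires_grad:
            x._accum(g @ w.data.T)
        if w.requires_grad:
            w._accum(x.data.T @ g)
        if b is not None and b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(y, parents, bw)


def fcej(x, e, j, w_in, w_e, w_j, b):
    """relu(x @ w_in + e @ w_e [+ j @ w_j] + b) as one node.

    `j`/`w_j` may be None for an Elman-only layer.
    """
    x, e, w_in, w_e, b = map(astensor, (x, e, w_in, w_e, b))
    has_j = w_j is not None
    if has_j:
        j, w_j = astensor(j), astensor(w_j)
    pre = x.data @ w_in.data + e.data @ w_e.data + b.data
    if has_j:
        pre = pre + j.data @ w_j.data
    y = np.maximum(pre, 0.0)
    parents = (x, e, j, w_in, w_e, w_j, b) if has_j else (x, e, w_in, w_e, b)

    def bw(g, y=y):
        g = g * (y > 0)
        for inp, wt in ((x, w_in), (e, w_e)) + (((j, w_j),) if has_j else ()):
            if inp.requires_grad:
                inp._accum(g @ wt.data.T)
            if wt.requires_grad:
                wt._accum(inp.data.T @ g)
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(y, parents, bw)


def jkff_hidden(x, h_prev, w_j, w_k):
    """Dense flip-flop state update as one node.

    In = [x, H_prev]; J = sigmoid(In @ W_j); K = sigmoid(In @ W_k);
    H = J * (1 - H_prev) + (1 - K) * H_prev.
    """
    x, h_prev, w_j, w_k = map(astensor, (x, h_prev, w_j, w_k))
    inp = np.concatenate([x.data, h_prev.data], axis=-1)
    J = expit(inp @ w_j.data)
    K = expit(inp @ w_k.data)
    hp = h_prev.data
    H = J * (1.0 - hp) + (1.0 - K) * hp
    dx = x.data.shape[-1]

    def bw(g, J=J, K=K, hp=hp, inp=inp, dx=dx):
        gaj = (g * (1.0 - hp)) * J * (1.0 - J)
        gak = (-g * hp) * K * (1.0 - K)
        if x.requires_grad or h_prev.requires_grad:
            gin = gaj @ w_j.data.T + gak @ w_k.data.T
            if x.requires_grad:
                x._accum(gin[..., :dx])
            if h_prev.requires_grad:
                h_prev._accum(gin[..., dx:] + g * (1.0 - K - J))
        if w_j.requires_grad:
            w_j._accum(inp.T @ gaj)
        if w_k.requires_grad:
            w_k._accum(inp.T @ gak)

    return _make(H, (x, h_prev, w_j, w_k), bw)


def ff_from_gates(gate_pre, h_prev):
    """Flip-flop update from stacked pre-sigmoid gate maps [J_pre | K_pre]
    (last axis twice the width of h_prev)."""
    gate_pre, h_prev = astensor(gate_pre), astensor(h_prev)
    U = h_prev.data.shape[-1]
    J = expit(gate_pre.data[..., :U])
    K = expit(gate_pre.data[..., U:])
    hp = h_prev.data
    H = J * (1.0 - hp) + (1.0 - K) * hp

    def bw(g, J=J, K=K, hp=hp):
        if gate_pre.requires_grad:
            gaj = (g * (1.0 - hp)) * J * (1.0 - J)
            gak = (-g * hp) * K * (1.0 - K)
            gate_pre._accum(np.concatenate([gaj, gak], axis=-1))
        if h_prev.requires_grad:
            h_prev._accum(g * (1.0 - K - J))

    return _make(H, (gate_pre, h_prev), bw)


# -- structured ops --------------------------------------------------------

def conv2d(x, w, b=None, act=None):
    """Same-padded stride-1 2-D convolution.

    x: (N, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,) or None.
    Implemented by im2col: one matmul of the unrolled patch matrix against
    the flattened kernel, with an exactly mirrored backward pass.
    """
    x, w = astensor(x), astensor(w)
    if b is not None:
        b = astensor(b)
    N, H, W, Cin = x.data.shape
    kh, kw, wc_in, Cout = w.data.shape
    if wc_in != Cin:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {wc_in}")
    ph, pw = kh // 2, kw // 2
    if kh == kw == 1:  # pointwise convolution: plain matmul, no unrolling
        cols = x.data.reshape(N * H * W, Cin)
    else:
        xp = np.zeros((N, H + 2 * ph, W + 2 * pw, Cin), dtype=x.data.dtype)
        xp[:, ph:ph + H, pw:pw + W, :] = x.data
        # (N, H, W, Cin, kh, kw) view -> (N*H*W, kh*kw*Cin) patch matrix
        sw = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        cols = np.ascontiguousarray(sw.transpose(0, 1, 2, 4, 5, 3)).reshape(
            N * H * W, kh * kw * Cin
        )
    wmat = w.data.reshape(kh * kw * Cin, Cout)
    y = (cols @ wmat).reshape(N, H, W, Cout)
    if b is not None:
        y = y + b.data
    if act == "tanh":
        y = np.tanh(y)
    elif act == "relu":
        y = np.maximum(y, 0.0)
    elif act is not None:
        raise ValueError(f"unknown activation {act!r}")

    parents = (x, w) if b is None else (x, w, b)

    def bw(g, x=x, w=w, b=b, cols=cols, wmat=wmat, y=y, act=act,
           dims=(N, H, W, Cin, kh, kw, Cout, ph, pw)):
        N, H, W, Cin, kh, kw, Cout, ph, pw = dims
        if act == "tanh":
            g = g * (1.0 - y * y)
        elif act == "relu":
            g = g * (y > 0)
        g2 = g.reshape(N * H * W, Cout)
        if x.requires_grad:
            if kh == kw == 1:
                x._accum((g2 @ wmat.T).reshape(N, H, W, Cin))
            else:
                dcols = (g2 @ wmat.T).reshape(N, H, W, kh, kw, Cin)
                gxp = np.zeros((N, H + 2 * ph, W + 2 * pw, Cin), dtype=g.dtype)
                for di in range(kh):
                    for dj in range(kw):
                        gxp[:, di:di + H, dj:dj + W, :] += dcols[:, :, :, di, dj, :]
                x._accum(gxp[:, ph:ph + H, pw:pw + W, :])
        if w.requires_grad:
            w._accum((cols.T @ g2).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))

    return _make(y, parents, bw)


def ff_update(J, K, H_prev):
    """Fused JK flip-flop state update H = J*(1-H_prev) + (1-K)*H_prev."""
    J, K, H_prev = astensor(J), astensor(K), astensor(H_prev)
    h = H_prev.data
    out = J.data * (1.0 - h) + (1.0 - K.data) * h

    def bw(g, J=J, K=K, H_prev=H_prev, h=h):
        if J.requires_grad:
            J._accum(_unbroadcast(g * (1.0 - h), J.data.shape))
        if K.requires_grad:
            K._accum(_unbroadcast(-g * h, K.data.shape))
        if H_prev.requires_grad:
            H_prev._accum(_unbroadcast(g * (1.0 - K.data - J.data), h.shape))

    return _make(out, (J, K, H_prev), bw)


def maxpool2(x):
    """2x2 max pooling with stride 2; gradient routed to the first max."""
    x = astensor(x)
    N, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    x6 = x.data.reshape(N, H // 2, 2, W // 2, 2, C)
    x4 = x6.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, C, 4)
    y = x4.max(axis=-1)

    def bw(g, x=x, x4=x4, y=y, dims=(N, H, W, C)):
        N, H, W, C = dims
        hit = x4 == y[..., None]
        # ties resolved to the first maximum so the route is deterministic
        first = hit & (np.cumsum(hit, axis=-1) == 1)
        gx = (
            (first * g[..., None])
            .reshape(N, H // 2, W // 2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(N, H, W, C)
        )
        x._accum(np.ascontiguousarray(gx))

    return _make(y, (x,), bw)


def conv_lrn_relu_pool(x, w, b, k, alpha, beta, c):
    """Fused conv2d -> LRN -> ReLU -> 2x2 maxpool block (one tape node).

    Semantically identical to composing the four primitive ops; used on the
    hot path where tape bookkeeping would otherwise dominate.
    """
    x, w, b = astensor(x), astensor(w), astensor(b)
    N, H, W, Cin = x.data.shape
    kh, kw, _, Cout = w.data.shape
    ph, pw = kh // 2, kw // 2
    xp = np.zeros((N, H + 2 * ph, W + 2 * pw, Cin), dtype=x.data.dtype)
    xp[:, ph:ph + H, pw:pw + W, :] = x.data
    sw = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = np.ascontiguousarray(sw.transpose(0, 1, 2, 4, 5, 3)).reshape(
        N * H * W, kh * kw * Cin
    )
    wmat = w.data.reshape(kh * kw * Cin, Cout)
    y1 = (cols @ wmat).reshape(N, H, W, Cout) + b.data

    c_half = int(c) // 2
    full = c_half >= Cout - 1  # window covers all channels at every f
    wsum = (
        (lambda t: t.sum(axis=-1, keepdims=True))
        if full
        else (lambda t: _window_sum(t, c_half))
    )
    base = k + alpha * wsum(y1 * y1)
    if k == 0:
        base = base + 1e-8
    denom = base ** (-float(beta))
    y3 = np.maximum(y1 * denom, 0.0)

    x6 = y3.reshape(N, H // 2, 2, W // 2, 2, Cout)
    x4 = x6.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, Cout, 4)
    y = x4.max(axis=-1)

    def bw(g):
        hit = x4 == y[..., None]
        first = hit & (np.cumsum(hit, axis=-1) == 1)
        g3 = (
            (first * g[..., None])
            .reshape(N, H // 2, W // 2, Cout, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(N, H, W, Cout)
        )
        g2 = g3 * (y3 > 0)
        t = g2 * y1 * base ** (-float(beta) - 1.0)
        g1 = g2 * denom - 2.0 * alpha * beta * y1 * wsum(t)
        g1_2d = g1.reshape(N * H * W, Cout)
        if x.requires_grad:
            dcols = (g1_2d @ wmat.T).reshape(N, H, W, kh, kw, Cin)
            gxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    gxp[:, di:di + H, dj:dj + W, :] += dcols[:, :, :, di, dj, :]
            x._accum(gxp[:, ph:ph + H, pw:pw + W, :])
        if w.requires_grad:
            w._accum((cols.T @ g1_2d).reshape(w.data.shape))
        if b.requires_grad:
            b._accum(g1.sum(axis=(0, 1, 2)))

    return _make(y, (x, w, b), bw)


def lrn_relu_pool(x, k, alpha, beta, c):
    """Fused LRN -> ReLU -> 2x2 maxpool (one tape node)."""
    x = astensor(x)
    N, H, W, C = x.data.shape
    c_half = int(c) // 2
    full = c_half >= C - 1  # window covers all channels at every f
    wsum = (
        (lambda t: t.sum(axis=-1, keepdims=True))
        if full
        else (lambda t: _window_sum(t, c_half))
    )
    xd = x.data
    base = k + alpha * wsum(xd * xd)
    if k == 0:
        base = base + 1e-8
    denom = base ** (-float(beta))
    y3 = np.maximum(xd * denom, 0.0)
    x6 = y3.reshape(N, H // 2, 2, W // 2, 2, C)
    x4 = x6.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, C, 4)
    y = x4.max(axis=-1)

    def bw(g):
        hit = x4 == y[..., None]
        first = hit & (np.cumsum(hit, axis=-1) == 1)
        g3 = (
            (first * g[..., None])
            .reshape(N, H // 2, W // 2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(N, H, W, C)
        )
        g2 = g3 * (y3 > 0)
        t = g2 * xd * base ** (-float(beta) - 1.0)
        x._accum(g2 * denom - 2.0 * alpha * beta * xd * wsum(t))

    return _make(y, (x,), bw)


def _window_sum(t, c_half):
    """Sliding inclusive-window sum over the channel axis with edge clipping."""
    out = t.copy()
    for d in range(1, min(c_half, t.shape[-1] - 1) + 1):
        out[..., d:] += t[..., :-d]
        out[..., :-d] += t[..., d:]
    return out


def lrn(x, k, alpha, beta, c):
    """Local response normalization across channels (lateral inhibition).

    N_f = x_f / (k + alpha * sum_{|j-f| <= c//2} x_j^2)^beta, the window
    clipped to valid channel indices.  When k == 0 an epsilon guard keeps the
    denominator positive.
    """
    x = astensor(x)
    C = x.data.shape[-1]
    c_half = int(c) // 2
    full = c_half >= C - 1  # window covers all channels at every f
    wsum = (
        (lambda t: t.sum(axis=-1, keepdims=True))
        if full
        else (lambda t: _window_sum(t, c_half))
    )
    sq = x.data * x.data
    base = k + alpha * wsum(sq)
    if k == 0:
        base = base + 1e-8
    denom = base ** (-float(beta))
    y = x.data * denom

    def bw(g, x=x, base=base, denom=denom, wsum=wsum, alpha=alpha, beta=beta):
        t = g * x.data * base ** (-float(beta) - 1.0)
        gx = g * denom - 2.0 * alpha * beta * x.data * wsum(t)
        x._accum(gx)

    return _make(y, (x,), bw)
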