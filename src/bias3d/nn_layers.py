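"""Network building blocks: convolution, LRN, pooling, Elman-Jordan fully
connected layers, and JK flip-flop recurrent layers (dense and convolutional).

All functions accept either ndarrays or autodiff :class:`~bias3d.autodiff.Tensor`
objects and return Tensors, so the same code path serves inference and
backpropagation-through-time.

The JK flip-flop neuron is the package's working-memory primitive: two sigmoid
gates J (set) and K (reset) drive a bounded hidden state

    H_t = J * (1 - H_{t-1}) + (1 - K) * H_{t-1},

which holds when J = K = 0, toggles when J = K = 1, and stays in [0, 1]
whenever the gates and the previous state do.  The layer output is
O_t = tanh(H_t @ W_out); the gates see the concatenation (x_t, H_{t-1}).
No bias terms appear anywhere in the flip-flop layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor


@dataclass
class LRNParams:
    """Hyperparameters of local response normalization.

    ``c`` is the channel-neighbourhood length; ``c=None`` means "all
    channels", the standard-normalization setting (k, alpha, beta, c) =
    (0, 1, 1, C).
    """

    k: float = 0.0
    alpha: float = 1.0
    beta: float = 1.0
    c: int | None = None

    def __post_init__(self):
        if self.c is not None and self.c < 1:
            raise ValueError("neighbourhood length c must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def conv2d(x, w, b=None, act=None):
    """Same-padded stride-1 convolution; x (N,H,W,Cin), w (kh,kw,Cin,Cout)."""
    x, w = astensor(x), astensor(w)
    if x.ndim != 4 or w.ndim != 4:
        raise ValueError("conv2d expects x (N,H,W,Cin) and w (kh,kw,Cin,Cout)")
    if x.shape[-1] != w.shape[2]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[-1]}, kernel expects {w.shape[2]}"
        )
    return ad.conv2d(x, w, b, act=act)


def relu(x):
    return ad.relu(astensor(x))


def lrn(x, params: LRNParams):
    x = astensor(x)
    c = x.shape[-1] if params.c is None else params.c
    return ad.lrn(x, params.k, params.alpha, params.beta, c)


def maxpool(x):
    """2x2 window, stride 2.  Requires even spatial dimensions."""
    return ad.maxpool2(astensor(x))


def conv_block(x, w, b, params: LRNParams):
    """conv2d -> LRN -> ReLU -> maxpool as a single fused operation."""
    w = astensor(w)
    c = w.shape[-1] if params.c is None else params.c
    return ad.conv_lrn_relu_pool(x, w, b, params.k, params.alpha, params.beta, c)


def lrn_relu_pool(x, params: LRNParams):
    """LRN -> ReLU -> maxpool as a single fused operation."""
    x = astensor(x)
    c = x.shape[-1] if params.c is None else params.c
    return ad.lrn_relu_pool(x, params.k, params.alpha, params.beta, c)


def fcej_forward(x, elman, jordan, weights, bias):
    """Fully connected Elman-Jordan layer.

    out = relu(x @ W_in + elman @ W_elman + jordan @ W_jordan + b)

    ``weights`` is the triple (W_in, W_elman, W_jordan); W_jordan may be None
    for an Elman-only (FCE) layer.  The contexts are read-only here -- the
    caller stores the new activations after the step.
    """
    w_in, w_elman, w_jordan = weights
    return ad.fcej(x, elman, jordan, w_in, w_elman, w_jordan, bias)


def flipflop_update(J, K, H_prev):
    """The JK flip-flop state equation H_t = J(1-H_prev) + (1-K)H_prev."""
    return ad.ff_update(J, K, H_prev)


def jkff_step(x, state, w_j, w_k, w_out):
    """One step of a dense JK flip-flop layer.

    x (N, Din), state H_prev (N, U); gate weights (Din+U, U), W_out (U, U).
    Returns (O_t, H_t).
    """
    x, H_prev = astensor(x), astensor(state)
    w_j, w_k, w_out = astensor(w_j), astensor(w_k), astensor(w_out)
    if x.shape[-1] + H_prev.shape[-1] != w_j.shape[0]:
        raise ValueError(
            f"gate weight rows {w_j.shape[0]} != input {x.shape[-1]} + state {H_prev.shape[-1]}"
        )
    H = ad.jkff_hidden(x, H_prev, w_j, w_k)
    O = ad.linear(H, w_out, act="tanh")
    return O, H


def conv_jkff_step(x, state, kernels):
    """One step of a convolutional JK flip-flop layer.

    Gates are 3x3 same-padded convolutions over the channel concatenation of
    x (N,H,W,Cin) and H_prev (N,H,W,U), sigmoid-squashed; the state equation
    is applied elementwise and the output is tanh of a 1x1 convolution of H_t.
    ``kernels`` maps {"w_j","w_k","w_out"} to arrays of shape
    (3,3,Cin+U,U), (3,3,Cin+U,U) and (1,1,U,U).
    """
    x, H_prev = astensor(x), astensor(state)
    if x.shape[:3] != H_prev.shape[:3]:
        raise ValueError("x and state must share batch and spatial dims")
    inp = ad.concat([x, H_prev], axis=-1)
    # one convolution computes both pre-sigmoid gate maps (shared unrolling)
    w_jk = ad.concat([astensor(kernels["w_j"]), astensor(kernels["w_k"])], axis=-1)
    H = ad.ff_from_gates(conv2d(inp, w_jk), H_prev)
    O = conv2d(H, astensor(kernels["w_out"]), act="tanh")
    return O, H


def xavier_init(m_in, m_out, seed, shape=None, dtype=np.float64):
    """I.i.d. normal weights with mean 0 and variance 2 / (m_in + m_out).

    ``shape`` defaults to (m_in, m_out); convolution kernels pass their full
    kernel shape with receptive-field-scaled fan counts.
    """
    if m_in <= 0 or m_out <= 0:
        raise ValueError("fan counts must be positive")
    rng = np.random.default_rng(seed)
    std = np.sqrt(2.0 / (m_in + m_out))
    if shape is None:
        shape = (m_in, m_out)
    return rng.normal(0.0, std, size=shape).astype(dtype)


def jkff_gradcheck(x, H_prev, w_j, w_k, w_out, eps=1e-6):
    """Max relative deviation between analytic and central-difference grads
    of sum(O_t) w.r.t. every weight of a dense flip-flop layer."""
    params = {"w_j": np.array(w_j, float), "w_k": np.array(w_k, float),
              "w_out": np.array(w_out, float)}

    def loss(p):
        O, _ = jkff_step(x, H_prev, p["w_j"], p["w_k"], p["w_out"])
        return float(O.data.sum())

    tensors = {k: Tensor(v, requires_grad=True) for k, v in params.items()}
    O, _ = jkff_step(x, H_prev, tensors["w_j"], tensors["w_k"], tensors["w_out"])
    O.sum().backward()

    worst = 0.0
    for name, arr in params.items():
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            pp = {k: v.copy() for k, v in params.items()}
            pp[name][idx] += eps
            up = loss(pp)
            pp[name][idx] -= 2 * eps
            down = loss(pp)
            num[idx] = (up - down) / (2 * eps)
        ana = tensors[name].grad
        scale = np.maximum(np.abs(num), np.abs(ana))
        dev = np.abs(num - ana) / np.maximum(scale, 1.0)
        worst = max(worst, float(dev.max()))
    return worst
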