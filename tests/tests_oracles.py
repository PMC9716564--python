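"""Brute-force reference implementations used as independent oracles."""

import numpy as np


def conv_reference(x, w, b):
    """Nested-loop same-padded stride-1 convolution."""
    N, H, W, Cin = x.shape
    kh, kw, _, Cout = w.shape
    ph, pw = kh // 2, kw // 2
    y = np.zeros((N, H, W, Cout))
    for n in range(N):
        for i in range(H):
            for j in range(W):
                for co in range(Cout):
                    acc = b[co]
                    for di in range(kh):
                        for dj in range(kw):
                            ii, jj = i + di - ph, j + dj - pw
                            if 0 <= ii < H and 0 <= jj < W:
                                for ci in range(Cin):
                                    acc += x[n, ii, jj, ci] * w[di, dj, ci, co]
                    y[n, i, j, co] = acc
    return y


def lrn_reference(x, k, alpha, beta, c):
    """Direct-summation local response normalization with window clipping."""
    out = np.zeros_like(x)
    C = x.shape[-1]
    for idx in np.ndindex(x.shape[:-1]):
        for f in range(C):
            lo, hi = max(0, f - c // 2), min(C - 1, f + c // 2)
            s = sum(x[idx][j] ** 2 for j in range(lo, hi + 1))
            kk = k if k != 0 else 1e-8
            out[idx + (f,)] = x[idx][f] / (kk + alpha * s) ** beta
    return out
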