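"""Numba-compiled direct 3D convolution kernels.

Dense volumetric convolutions at small channel counts are memory-bound when
expressed as im2col + BLAS (the column matrix is ~k³ times the input), so
the hot path uses direct loop kernels instead: the innermost loop runs
along the contiguous W axis and the per-(n, c) slabs fit in L2 cache. The
pure-numpy fallback in :mod:`voxhazard.autodiff` remains the reference
implementation; these kernels are verified against it in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAS_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAS_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def conv3d_forward(xp, w):
    """xp: padded input (N, C, Dp, Hp, Wp); w: (F, C, k, k, k) → (N, F, D, H, W)."""
    N, C, Dp, Hp, Wp = xp.shape
    F, _, k, _, _ = w.shape
    D, H, W = Dp - k + 1, Hp - k + 1, Wp - k + 1
    out = np.zeros((N, F, D, H, W), dtype=xp.dtype)
    for n in range(N):
        for f in range(F):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            wv = w[f, c, i, j, l]
                            for d in range(D):
                                for h in range(H):
                                    for x in range(W):
                                        out[n, f, d, h, x] += wv * xp[n, c, d + i, h + j, x + l]
    return out


@njit(cache=True, fastmath=True)
def conv3d_backward_dx(g, w, Dp, Hp, Wp):
    """Gradient w.r.t. the padded input. g: (N, F, D, H, W) → (N, C, Dp, Hp, Wp)."""
    N, F, D, H, W = g.shape
    _, C, k, _, _ = w.shape
    dxp = np.zeros((N, C, Dp, Hp, Wp), dtype=g.dtype)
    for n in range(N):
        for f in range(F):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            wv = w[f, c, i, j, l]
                            for d in range(D):
                                for h in range(H):
                                    for x in range(W):
                                        dxp[n, c, d + i, h + j, x + l] += wv * g[n, f, d, h, x]
    return dxp


@njit(cache=True, fastmath=True)
def conv3d_backward_dw(g, xp, k):
    """Gradient w.r.t. the weights. → (F, C, k, k, k)."""
    N, F, D, H, W = g.shape
    C = xp.shape[1]
    dw = np.zeros((F, C, k, k, k), dtype=g.dtype)
    for n in range(N):
        for f in range(F):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            acc = 0.0
                            for d in range(D):
                                for h in range(H):
                                    for x in range(W):
                                        acc += g[n, f, d, h, x] * xp[n, c, d + i, h + j, x + l]
                            dw[f, c, i, j, l] += acc
    return dw
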