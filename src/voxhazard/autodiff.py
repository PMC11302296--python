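"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the micrograd style, but on whole arrays: each
``Tensor`` wraps an ndarray, remembers its parent tensors and a closure that
accumulates gradients into them. ``backward()`` topologically sorts the
tape, runs the closures once each and then releases the tape. Only the
operations the volumetric network needs are implemented — elementwise
arithmetic, matmul, reductions, shape ops, 3D convolution (compiled
direct-loop kernels with a pure-numpy fallback; see :func:`conv3d`), 2× max
pooling, nearest-neighbor 2× upsampling, adaptive max pooling, batch
normalization and log-softmax.

dtype follows the input arrays: training uses float32, while gradient
checks against finite differences run in float64.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "max_pool2x", "upsample2x",
           "adaptive_max_pool", "batch_norm", "log_softmax", "relu", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager suppressing tape construction (inference passes)."""

    def __enter__(self):
        global _grad_enabled
        self._saved = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._saved
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = _grad_enabled and (
            requires_grad or any(p.requires_grad for p in _prev)
        )
        self._prev = tuple(p for p in _prev if p.requires_grad) \
            if self.requires_grad else ()
        self._backward = None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None):
        """Run reverse-mode accumulation, then free the tape.

        Non-leaf nodes drop their closures, parent links and gradients as
        soon as they have propagated: the graph holds large volumetric
        arrays in reference cycles that Python's count-based collector is
        slow to reclaim, so a training loop would otherwise balloon by
        hundreds of MB per step. A graph can therefore be traversed once.
        """
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs would blow the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._prev or node._backward is not None:  # non-leaf: release
                node._backward = None
                node._prev = ()
                node.grad = None

    # -- arithmetic -------------------------------------------------------
    # Python scalars take a dedicated path (not wrapped into 0-d arrays) so
    # numpy's weak scalar promotion applies and float32 graphs stay float32.
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data + other, _prev=(self,))
            if self.requires_grad:
                out._backward = lambda g: self._accum(g)
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        if out.requires_grad:
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return (-self) + other if isinstance(other, (int, float)) \
            else Tensor._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, _prev=(self,))
            if self.requires_grad:
                out._backward = lambda g: self._accum(g * other)
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        if out.requires_grad:
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        return self * Tensor._lift(other) ** -1.0

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            return self**-1.0 * other
        return Tensor._lift(other) * self**-1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _prev=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(
                g * exponent * self.data ** (exponent - 1)
            )
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        if out.requires_grad:
            out._backward = _bw
        return out

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        out = Tensor(out_data, _prev=(self,))
        if self.requires_grad:
            # capture the array, not the Tensor: a self-referential closure
            # would create an uncollectable-until-GC reference cycle
            out._backward = lambda g: self._accum(g * out_data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _prev=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions and shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        if out.requires_grad:
            def _bw(g):
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def relu(x: Tensor) -> Tensor:
    return x.relu()


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    if out.requires_grad:
        out._backward = _bw
    return out


# -- volumetric operations ------------------------------------------------

try:
    from . import _kernels

    USE_NUMBA_CONV = _kernels.HAS_NUMBA
except ImportError:  # pragma: no cover
    USE_NUMBA_CONV = False


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same'-padded 3D convolution (cross-correlation), stride 1.

    x: (N, C, D, H, W); w: (F, C, k, k, k); b: (F,). Even kernels pad one
    voxel less on the low side, as is conventional.

    Two interchangeable implementations: compiled direct-loop kernels
    (:mod:`voxhazard._kernels`, the fast path) and a pure-numpy sum over
    the k³ kernel offsets of channel-contracting matmuls on a channel-last
    copy (the reference path, also the fallback without numba). The test
    suite asserts their agreement.
    """
    N, C, D, H, W = x.data.shape
    F, Cw, k, _, _ = w.data.shape
    if Cw != C:
        raise ValueError(f"input has {C} channels but weight expects {Cw}")
    pl, pr = (k - 1) // 2, k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr), (pl, pr), (pl, pr)))
    use_numba = USE_NUMBA_CONV
    if use_numba:
        out_data = _kernels.conv3d_forward(xp, w.data)
        if b is not None:
            out_data += b.data.reshape(1, F, 1, 1, 1)
        xpl = None
    else:
        xpl = np.ascontiguousarray(xp.transpose(0, 2, 3, 4, 1))  # (N,Dp,Hp,Wp,C)
        out_l = np.zeros((N, D, H, W, F), dtype=x.data.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xpl[:, i : i + D, j : j + H, l : l + W, :]
                    out_l += xs @ w.data[:, :, i, j, l].T
        if b is not None:
            out_l += b.data
        out_data = np.ascontiguousarray(out_l.transpose(0, 4, 1, 2, 3))
        del out_l
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def _bw(g):
        # keep gradients in the parameter dtype: a float64 gradient leaking
        # into the float32 kernels would silently double the memory traffic
        g = np.ascontiguousarray(g, dtype=x.data.dtype)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if use_numba:
            if w.requires_grad:
                w._accum(_kernels.conv3d_backward_dw(g, xp, k))
            if x.requires_grad:
                # dx is itself a convolution: pad the output gradient by
                # (pr, pl) and run the forward kernel with the spatially
                # flipped, channel-transposed weights
                gp = np.pad(g, ((0, 0), (0, 0), (pr, pl), (pr, pl), (pr, pl)))
                wflip = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                )
                x._accum(_kernels.conv3d_forward(gp, wflip))
            return
        gl = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1))  # (N, D, H, W, F)
        need_dx = x.requires_grad
        dxpl = np.zeros_like(xpl) if need_dx else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xpl[:, i : i + D, j : j + H, l : l + W, :]
                    if dw is not None:
                        dw[:, :, i, j, l] = np.tensordot(
                            gl, xs, axes=([0, 1, 2, 3], [0, 1, 2, 3])
                        )
                    if need_dx:
                        dxpl[:, i : i + D, j : j + H, l : l + W, :] += (
                            gl @ w.data[:, :, i, j, l]
                        )
        if dw is not None:
            w._accum(dw)
        if need_dx:
            dxp = dxpl.transpose(0, 4, 1, 2, 3)
            x._accum(
                np.ascontiguousarray(
                    dxp[:, :, pl : pl + D, pl : pl + H, pl : pl + W]
                )
            )

    if out.requires_grad:
        out._backward = _bw
    return out


def max_pool2x(x: Tensor) -> Tensor:
    """2×2×2 max pooling, stride 2; spatial dims must be even."""
    N, C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"spatial dims must be even for 2x pooling, got {(D, H, W)}")
    d, h, w_ = D // 2, H // 2, W // 2
    win = x.data.reshape(N, C, d, 2, h, 2, w_, 2).transpose(
        0, 1, 2, 4, 6, 3, 5, 7
    ).reshape(N, C, d, h, w_, 8)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            dwin = np.zeros((N, C, d, h, w_, 8), dtype=g.dtype)
            np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
            dx = dwin.reshape(N, C, d, h, w_, 2, 2, 2).transpose(
                0, 1, 2, 5, 3, 6, 4, 7
            ).reshape(N, C, D, H, W)
            x._accum(dx)

    if out.requires_grad:
        out._backward = _bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbor ×2 upsampling of all three spatial dims."""
    N, C, D, H, W = x.data.shape
    out_data = (
        x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
    )
    out = Tensor(out_data, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(
                g.reshape(N, C, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7))
            )

    if out.requires_grad:
        out._backward = _bw
    return out


def adaptive_max_pool(x: Tensor, out_size: int) -> Tensor:
    """Adaptive max pooling to (out_size,)*3 using floor-spaced bin edges."""
    N, C, D, H, W = x.data.shape
    p = out_size

    def edges(n):
        return [int(np.floor(i * n / p)) for i in range(p + 1)]

    ed, eh, ew = edges(D), edges(H), edges(W)
    out_data = np.empty((N, C, p, p, p), dtype=x.data.dtype)
    argmaxes = {}
    for a in range(p):
        for bb in range(p):
            for c in range(p):
                block = x.data[:, :, ed[a]:ed[a + 1], eh[bb]:eh[bb + 1], ew[c]:ew[c + 1]]
                flat = block.reshape(N, C, -1)
                am = flat.argmax(axis=-1)
                out_data[:, :, a, bb, c] = np.take_along_axis(
                    flat, am[..., None], axis=-1
                )[..., 0]
                argmaxes[(a, bb, c)] = am
    out = Tensor(out_data, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            ni, ci = np.indices((N, C))
            for (a, bb, c), am in argmaxes.items():
                bd = ed[a + 1] - ed[a]
                bh = eh[bb + 1] - eh[bb]
                bw_ = ew[c + 1] - ew[c]
                di = am // (bh * bw_)
                hi = (am // bw_) % bh
                wi = am % bw_
                dx[ni, ci, ed[a] + di, eh[bb] + hi, ew[c] + wi] += g[:, :, a, bb, c]
            x._accum(dx)

    if out.requires_grad:
        out._backward = _bw
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, C, D, H, W) with per-channel affine.

    In training mode the batch statistics are used and the running buffers
    updated in place (biased variance for normalization, unbiased for the
    running buffer, matching common deep-learning practice).
    """
    C = x.data.shape[1]
    axes = (0, 2, 3, 4)
    shape = (1, C, 1, 1, 1)
    if training:
        m = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
        n = x.data.size / C
        running_mean *= 1 - momentum
        running_mean += momentum * m
        running_var *= 1 - momentum
        running_var += momentum * (v * n / max(n - 1, 1))
    else:
        m, v = running_mean, running_var
    inv_std = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m.reshape(shape)) * inv_std.reshape(shape)
    out_data = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    out = Tensor(out_data, _prev=(x, gamma, beta))

    def _bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gs = gamma.data.reshape(shape) * inv_std.reshape(shape)
            if training:
                n = x.data.size / C
                dxhat = g * gamma.data.reshape(shape)
                t1 = dxhat
                t2 = dxhat.mean(axis=axes, keepdims=True)
                t3 = xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
                x._accum((t1 - t2 - t3) * inv_std.reshape(shape))
            else:
                x._accum(g * gs)

    if out.requires_grad:
        out._backward = _bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along `axis`."""
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    out = Tensor(out_data, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            sm = np.exp(out_data)
            x._accum(g - sm * g.sum(axis=axis, keepdims=True))

    if out.requires_grad:
        out._backward = _bw
    return out
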