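"""Neural-network building blocks on top of :mod:`tsfnet.autograd`.

Implements exactly the layer vocabulary the fusion network needs: 3D
convolution with adaptive ("same"-style) padding, batch normalization over the
channel axis, dropout, dense layers and the Adam optimizer.  The convolution
lowers to an im2col matmul; the patch gather/scatter is JIT-compiled with
numba because that data movement, not the GEMM, dominates on a CPU.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from numba import njit

from .autograd import Tensor, no_grad


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _im2col(xp, out, k1, k2, k3, s1, s2, s3, O1, O2, O3):  # pragma: no cover - jit
    # loop order chosen to stream writes and reuse source lines from cache
    N = xp.shape[0]
    C = xp.shape[4]
    kc = k3 * C
    o23 = O2 * O3
    for n in range(N):
        for a in range(O1):
            for i in range(k1):
                for b in range(O2):
                    for j in range(k2):
                        src = xp[n, a * s1 + i, b * s2 + j]
                        qbase = (i * k2 + j) * kc
                        pbase = a * o23 + b * O3
                        for c in range(O3):
                            c0 = c * s3
                            for u in range(k3):
                                for ch in range(C):
                                    out[n, pbase + c, qbase + u * C + ch] = src[c0 + u, ch]
    return out


@njit(cache=True)
def _col2im(gcols, N, P1, P2, P3, C, k1, k2, k3, s1, s2, s3, O1, O2, O3):  # pragma: no cover - jit
    gx = np.zeros((N, P1, P2, P3, C), dtype=gcols.dtype)
    kc = k3 * C
    o23 = O2 * O3
    for n in range(N):
        for a in range(O1):
            for i in range(k1):
                for b in range(O2):
                    for j in range(k2):
                        dst = gx[n, a * s1 + i, b * s2 + j]
                        qbase = (i * k2 + j) * kc
                        pbase = a * o23 + b * O3
                        for c in range(O3):
                            c0 = c * s3
                            for u in range(k3):
                                for ch in range(C):
                                    dst[c0 + u, ch] += gcols[n, pbase + c, qbase + u * C + ch]
    return gx


#: retain im2col patches for the backward pass below this size; above it they
#: are re-gathered chunkwise to bound peak memory
COLS_RETAIN_BYTES = 600 * 2**20


class _BufferPool:
    """Reusable array buffers for the large, short-lived conv intermediates.

    Freshly mmap'd pages cost a page fault per 4 KiB on first touch, which is
    a measurable fraction of conv time for ~300 MB patch matrices allocated
    every batch.  Buffers are keyed by (shape, dtype); ``release`` returns a
    buffer once its backward pass has consumed it.
    """

    def __init__(self):
        self._free: dict[tuple, list[np.ndarray]] = {}

    def acquire(self, shape: tuple, dtype) -> np.ndarray:
        key = (tuple(shape), np.dtype(dtype))
        stack = self._free.get(key)
        if stack:
            return stack.pop()
        return np.empty(shape, dtype=dtype)

    def release(self, arr: np.ndarray | None) -> None:
        if arr is None:
            return
        key = (arr.shape, arr.dtype)
        self._free.setdefault(key, []).append(arr)

    def clear(self) -> None:
        self._free.clear()


_pool = _BufferPool()


def same_pad_amounts(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Output extent and (before, after) padding for ceil(size/stride) output.

    The asymmetric extra sample is padded at the end of the axis.
    """
    out = math.ceil(size / stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return out, total // 2, total - total // 2


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: tuple[int, int, int]) -> Tensor:
    """3D convolution over (N, D1, D2, D3, Cin) with adaptive padding.

    ``w`` has shape (k1, k2, k3, Cin, Cout); each output extent is
    ``ceil(input extent / stride)``.
    """
    if x.ndim != 5:
        raise ValueError(f"conv3d expects a rank-5 input, got shape {x.shape}")
    k1, k2, k3, cin, cout = w.shape
    if x.shape[4] != cin:
        raise ValueError(f"input has {x.shape[4]} channels, kernel expects {cin}")
    s1, s2, s3 = stride
    N, D1, D2, D3, _ = x.shape
    O1, p1a, p1b = same_pad_amounts(D1, k1, s1)
    O2, p2a, p2b = same_pad_amounts(D2, k2, s2)
    O3, p3a, p3b = same_pad_amounts(D3, k3, s3)
    pads = ((0, 0), (p1a, p1b), (p2a, p2b), (p3a, p3b), (0, 0))
    wm = w.data.reshape(-1, cout)
    n_pos = O1 * O2 * O3
    patch = k1 * k2 * k3 * cin

    def _gather(chunk: np.ndarray) -> np.ndarray:
        xp = np.ascontiguousarray(np.pad(chunk, pads))
        buf = _pool.acquire((len(chunk), n_pos, patch), xp.dtype)
        return _im2col(xp, buf, k1, k2, k3, s1, s2, s3, O1, O2, O3)

    from . import autograd as _ag
    needs_grad = _ag._GRAD_ENABLED and (x.requires_grad or w.requires_grad
                                        or (b is not None and b.requires_grad))
    itemsize = x.data.dtype.itemsize
    retain = needs_grad and N * n_pos * patch * itemsize <= COLS_RETAIN_BYTES
    chunk = max(1, int(2**25 // max(n_pos * patch, 1)))
    if retain:
        cols = _gather(x.data)
        out_data = cols @ wm
    else:
        # gather in sample chunks: the im2col expansion (up to ~12x the input
        # volume) never fully materializes; backward re-gathers if needed
        cols = None
        out_data = np.empty((N, n_pos, cout), dtype=x.data.dtype)
        for i in range(0, N, chunk):
            c = _gather(x.data[i:i + chunk])
            np.matmul(c, wm, out=out_data[i:i + chunk])
            _pool.release(c)
    if b is not None:
        out_data += b.data
    out_data = out_data.reshape(N, O1, O2, O3, cout)

    def backward(g):
        nonlocal cols
        gmat = g.reshape(N, -1, cout)
        if w.requires_grad:
            if cols is not None:
                gw = np.einsum("npq,npc->qc", cols, gmat, optimize=True)
            else:
                gw = np.zeros((patch, cout), dtype=np.float64)
                for i in range(0, N, chunk):
                    c = _gather(x.data[i:i + chunk])
                    gw += np.einsum("npq,npc->qc", c, gmat[i:i + chunk], optimize=True)
                    _pool.release(c)
            w._accumulate(gw.reshape(w.shape))
        _pool.release(cols)
        cols = None
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = _pool.acquire((N, n_pos, patch), gmat.dtype)
            np.matmul(gmat, wm.T.astype(gmat.dtype, copy=False), out=gcols)
            P1 = D1 + p1a + p1b
            P2 = D2 + p2a + p2b
            P3 = D3 + p3a + p3b
            gxp = _col2im(gcols, N, P1, P2, P3,
                          cin, k1, k2, k3, s1, s2, s3, O1, O2, O3)
            _pool.release(gcols)
            x._accumulate(gxp[:, p1a:p1a + D1, p2a:p2a + D2, p3a:p3a + D3, :])

    return Tensor._make(out_data, (x, w) if b is None else (x, w, b), backward)


def gather_patches(x: np.ndarray, kernel: tuple[int, int, int],
                   stride: tuple[int, int, int]) -> np.ndarray:
    """im2col patch matrix (N, positions, patch) for a conv geometry.

    Used to precompute patches of fixed inputs once (they depend only on the
    data, not on the weights), so repeated epochs skip the gather.
    """
    k1, k2, k3 = kernel
    s1, s2, s3 = stride
    N, D1, D2, D3, C = x.shape
    O1, p1a, p1b = same_pad_amounts(D1, k1, s1)
    O2, p2a, p2b = same_pad_amounts(D2, k2, s2)
    O3, p3a, p3b = same_pad_amounts(D3, k3, s3)
    xp = np.ascontiguousarray(
        np.pad(x, ((0, 0), (p1a, p1b), (p2a, p2b), (p3a, p3b), (0, 0))))
    out = np.empty((N, O1 * O2 * O3, k1 * k2 * k3 * C), dtype=x.dtype)
    _im2col(xp, out, k1, k2, k3, s1, s2, s3, O1, O2, O3)
    return out


def conv3d_from_patches(cols: np.ndarray, w: Tensor, b: Tensor | None,
                        spatial_out: tuple[int, int, int],
                        release: bool = False) -> Tensor:
    """Convolution applied to a precomputed patch matrix (input is a leaf).

    ``cols`` is (N, positions, k1*k2*k3*Cin) float32; with ``release`` the
    buffer is returned to the pool once the backward pass has consumed it.
    """
    cout = w.shape[-1]
    wm = w.data.reshape(-1, cout)
    out_data = cols @ wm
    if b is not None:
        out_data += b.data
    N = cols.shape[0]
    out_data = out_data.reshape(N, *spatial_out, cout)

    def backward(g):
        gmat = g.reshape(N, -1, cout)
        if w.requires_grad:
            gw = np.einsum("npq,npc->qc", cols, gmat, optimize=True)
            w._accumulate(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=(0, 1)))
        if release:
            _pool.release(cols)

    return Tensor._make(out_data, (w,) if b is None else (w, b), backward)


def temporal_mean_conv(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Temporal mean of a stride-1 same-padded conv3d, computed exactly.

    For a stride-1 convolution along time followed by a global temporal mean,
    ``mean_t(conv(x)) = sum_u w[..., u, :, :] * M_u`` where ``M_u`` is the
    sliding mean of the zero-padded input — so the full-resolution temporal
    conv never needs to be materialized.  Returns (N, H, W) for a
    single-output-channel kernel (the EFGF attention convolutions).
    """
    from .autograd import pad as _pad, stack as _stack

    k1, k2, k3, cin, cout = w.shape
    n, h, wd, t, _ = x.shape
    before = (k3 - 1) // 2
    xp = _pad(x, ((0, 0), (0, 0), (0, 0), (before, k3 - 1 - before), (0, 0)))
    means = [xp[:, :, :, u:u + t, :].mean(axis=3) for u in range(k3)]
    m = _stack(means, axis=3)                    # (N, H, W, k3, Cin)
    out = conv3d(m, w, b, (1, 1, k3))            # (N, H, W, 1, Cout)
    return out.reshape(n, h, wd)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Container with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        object.__setattr__(self, "training", True)
        for m in self._modules.values():
            m.train()
        return self

    def eval(self):
        object.__setattr__(self, "training", False)
        for m in self._modules.values():
            m.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=params[name].data.dtype).copy()
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype=np.float32):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv3d(Module):
    """Conv -> optional ELU -> optional BatchNorm handled by callers."""

    def __init__(self, cin: int, cout: int, kernel: tuple[int, int, int],
                 stride: tuple[int, int, int], rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        k1, k2, k3 = kernel
        fan_in = k1 * k2 * k3 * cin
        fan_out = k1 * k2 * k3 * cout
        self.weight = Parameter(glorot_uniform(rng, (k1, k2, k3, cin, cout), fan_in, fan_out, dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype))
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = Parameter(glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype))
        self.bias = Parameter(np.zeros(n_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                     eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch normalization (training mode) with the closed-form
    gradient; statistics over every axis except the trailing channel axis.

    Returns (normalized tensor, batch mean, batch variance).
    """
    axes = tuple(range(x.ndim - 1))
    xd = x.data
    mean = xd.mean(axis=axes)
    var = xd.var(axis=axes)
    inv = (1.0 / np.sqrt(var + eps)).astype(xd.dtype)
    xhat = (xd - mean.astype(xd.dtype)) * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gm = g.mean(axis=axes)
            gxm = (g * xhat).mean(axis=axes)
            gx = (gamma.data * inv) * (g - gm - xhat * gxm)
            x._accumulate(gx)

    return Tensor._make(out, (x, gamma, beta), backward), mean, var


class BatchNorm(Module):
    """Batch normalization over the trailing channel axis.

    Statistics are taken over every non-channel axis of the batch in training
    mode; running averages (momentum 0.1) are used in evaluation mode, so a
    single-sample forward pass is well defined.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        object.__setattr__(self, "_buffer_names", ("running_mean", "running_var"))
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mean, var = batch_norm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
            return out
        mean = self.running_mean.astype(x.dtype)
        std = np.sqrt(self.running_var + self.eps).astype(x.dtype)
        xhat = (x - Tensor(mean)) * Tensor(1.0 / std)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0:
            return x
        keep = self.rng.random(x.shape, dtype=np.float32) >= self.rate
        mask = keep.astype(x.dtype)
        mask *= 1.0 / (1.0 - self.rate)
        return x * Tensor(mask)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = (p.data - update).astype(p.data.dtype)
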