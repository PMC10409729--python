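"""Compact reverse-mode automatic differentiation on numpy arrays.

The registration and feature networks in this package are small 3D CNNs
trained with first-order methods.  This module supplies the primitives they
need — broadcast-aware elementwise ops, dense and 3D convolution layers,
nearest-neighbour upsampling, and differentiable trilinear volume sampling
(the spatial-transformer contract) — together with an Adam optimiser.

Tensors wrap a numpy array; calling :meth:`Tensor.backward` on a scalar
result accumulates gradients into every reachable tensor created with
``requires_grad=True``.  Graphs are built dynamically and freed after the
backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "stack",
    "conv3d",
    "upsample_nearest3d",
    "trilinear_sample",
    "Adam",
]


def _as_array(x, dtype=None):
    if isinstance(x, Tensor):
        raise TypeError("expected a raw array, got a Tensor")
    return np.asarray(x, dtype=dtype)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            # release graph references as we go
            t._backward = None
            t._parents = ()

    @staticmethod
    def _make(data, parents, backward, requires_grad=None):
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._make(a.data ** p, (a,), bwd)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def sqrt(self, eps: float = 0.0):
        a = self
        out_data = np.sqrt(a.data + eps)

        def bwd(g):
            a._accumulate(g * 0.5 / np.maximum(out_data, 1e-30))

        return Tensor._make(out_data, (a,), bwd)

    def abs(self):
        a = self
        s = np.sign(a.data)

        def bwd(g):
            a._accumulate(g * s)

        return Tensor._make(np.abs(a.data), (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accumulate(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    def sin(self):
        a = self

        def bwd(g):
            a._accumulate(g * np.cos(a.data))

        return Tensor._make(np.sin(a.data), (a,), bwd)

    def cos(self):
        a = self

        def bwd(g):
            a._accumulate(-g * np.sin(a.data))

        return Tensor._make(np.cos(a.data), (a,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = a.data == out_data
        # ties: split gradient equally (keeps backward well defined)
        counts = mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(g * mask / counts)

        return Tensor._make(out_data if keepdims else out_data.squeeze(axis), (a,), bwd)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            a._accumulate(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros(a.shape, dtype=a.data.dtype)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bwd)

    def pad(self, pad_width):
        a = self

        def bwd(g):
            sl = tuple(slice(b, g.shape[i] - e if e else None) for i, (b, e) in enumerate(pad_width))
            a._accumulate(g[sl])

        return Tensor._make(np.pad(a.data, pad_width), (a,), bwd)

    def matmul(self, other):
        other = tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    __matmul__ = matmul

    def dropout(self, p: float, rng: np.random.Generator):
        if p <= 0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)
        return self * Tensor(mask.astype(self.dtype))


def tensor(x, requires_grad: bool = False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=requires_grad)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, b, e in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(b, e)
                t._accumulate(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tuple(tensors), bwd)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [tensor(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    data = np.stack([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# 3D convolution (channels-first, zero 'same' padding, odd kernels)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: tuple, stride: tuple) -> np.ndarray:
    """(Cin, Dp, Hp, Wp) -> (N, Cin*kd*kh*kw) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=(1, 2, 3))
    win = win[:, :: stride[0], :: stride[1], :: stride[2]]
    cin, do, ho, wo = win.shape[:4]
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(do * ho * wo, -1)
    return np.ascontiguousarray(cols), (do, ho, wo)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=(1, 1, 1)) -> Tensor:
    """3D convolution, input (Cin, D, H, W), weight (Cout, Cin, kd, kh, kw)."""
    x, w = tensor(x), tensor(w)
    cout, cin, kd, kh, kw = w.shape
    if x.shape[0] != cin:
        raise ValueError(f"channel mismatch: input {x.shape[0]} vs weight {cin}")
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    stride = tuple(stride)
    xp = np.pad(x.data, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
    cols, (do, ho, wo) = _im2col(xp, (kd, kh, kw), stride)
    wmat = w.data.reshape(cout, -1)
    out = cols @ wmat.T  # (N, Cout)
    if b is not None:
        out = out + b.data[None, :]
    out = out.T.reshape(cout, do, ho, wo)

    def bwd(g):
        gmat = g.reshape(cout, -1).T  # (N, Cout)
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(w.shape))
        if x.requires_grad:
            if stride == (1, 1, 1):
                # dx is the correlation of dout with channel-swapped,
                # spatially flipped kernels — one im2col + one matmul
                gp = np.pad(g, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
                gcols, _ = _im2col(gp, (kd, kh, kw), (1, 1, 1))
                wt = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4).reshape(cin, -1)
                x._accumulate((gcols @ wt.T).T.reshape(x.shape))
            else:
                dcols = (gmat @ wmat).reshape(do, ho, wo, cin, kd, kh, kw)
                dxp = np.zeros_like(xp)
                for i in range(kd):
                    for j in range(kh):
                        for l in range(kw):
                            dxp[:, i : i + stride[0] * do : stride[0],
                                j : j + stride[1] * ho : stride[1],
                                l : l + stride[2] * wo : stride[2]] += dcols[..., i, j, l].transpose(3, 0, 1, 2)
                x._accumulate(dxp[:, pd : pd + x.shape[1], ph : ph + x.shape[2], pw : pw + x.shape[3]])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bwd)


def upsample_nearest3d(x: Tensor, factors=(2, 2, 2)) -> Tensor:
    """Nearest-neighbour upsampling of a (C, D, H, W) tensor."""
    x = tensor(x)
    f = tuple(factors)
    data = x.data
    for ax, fi in enumerate(f, start=1):
        if fi != 1:
            data = np.repeat(data, fi, axis=ax)

    def bwd(g):
        c = g.shape[0]
        d, h, w = x.shape[1:]
        g = g.reshape(c, d, f[0], h, f[1], w, f[2])
        x._accumulate(g.sum(axis=(2, 4, 6)))

    return Tensor._make(data, (x,), bwd)


# ---------------------------------------------------------------------------
# Differentiable trilinear sampling (spatial-transformer resampling core)
# ---------------------------------------------------------------------------

def trilinear_sample(vol: Tensor, coords: Tensor) -> Tensor:
    """Sample `vol` (D, H, W) at fractional voxel `coords` (3, N).

    Out-of-volume samples evaluate to zero; the result is differentiable in
    both the coordinates and the volume.
    """
    vol, coords = tensor(vol), tensor(coords)
    D, H, W = vol.shape
    c = coords.data
    x0 = np.floor(c).astype(np.int64)
    fr = c - x0
    v = vol.data

    corner_vals = []  # indexed by (dx, dy, dz) bits
    corner_idx = []
    for bit in range(8):
        dx, dy, dz = (bit >> 2) & 1, (bit >> 1) & 1, bit & 1
        ix, iy, iz = x0[0] + dx, x0[1] + dy, x0[2] + dz
        valid = (ix >= 0) & (ix < D) & (iy >= 0) & (iy < H) & (iz >= 0) & (iz < W)
        ixc, iyc, izc = np.clip(ix, 0, D - 1), np.clip(iy, 0, H - 1), np.clip(iz, 0, W - 1)
        corner_vals.append(np.where(valid, v[ixc, iyc, izc], 0.0))
        corner_idx.append((ixc, iyc, izc, valid))

    fx, fy, fz = fr
    wx = [1.0 - fx, fx]
    wy = [1.0 - fy, fy]
    wz = [1.0 - fz, fz]
    out = np.zeros_like(fx)
    for bit in range(8):
        dx, dy, dz = (bit >> 2) & 1, (bit >> 1) & 1, bit & 1
        out += wx[dx] * wy[dy] * wz[dz] * corner_vals[bit]

    def bwd(g):
        if coords.requires_grad:
            dfx = np.zeros_like(fx)
            dfy = np.zeros_like(fy)
            dfz = np.zeros_like(fz)
            for bit in range(8):
                dx, dy, dz = (bit >> 2) & 1, (bit >> 1) & 1, bit & 1
                val = corner_vals[bit]
                sx = 1.0 if dx else -1.0
                sy = 1.0 if dy else -1.0
                sz = 1.0 if dz else -1.0
                dfx += sx * wy[dy] * wz[dz] * val
                dfy += wx[dx] * sy * wz[dz] * val
                dfz += wx[dx] * wy[dy] * sz * val
            coords._accumulate(np.stack([dfx * g, dfy * g, dfz * g]))
        if vol.requires_grad:
            dv = np.zeros_like(v)
            for bit in range(8):
                dx, dy, dz = (bit >> 2) & 1, (bit >> 1) & 1, bit & 1
                ixc, iyc, izc, valid = corner_idx[bit]
                wgt = wx[dx] * wy[dy] * wz[dz] * valid * g
                np.add.at(dv, (ixc, iyc, izc), wgt)
            vol._accumulate(dv)

    return Tensor._make(out, (vol, coords), bwd)


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; operates on a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
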