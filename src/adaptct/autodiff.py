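"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the CPU engine the synthesis network and its composite loss run on.
It implements exactly the primitives the UNet++ generator needs — 2-D
convolution (via im2col/BLAS), 2×2 max-pooling, bilinear ×2 upsampling,
separable Gaussian blur (for SSIM), channel concatenation, ReLU and
elementwise arithmetic with broadcasting — plus an Adam optimizer.

Gradients of every primitive are verified against finite differences in the
test suite. Arrays are float32 in training; the graph itself is
dtype-agnostic, so gradient checks can run in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "maxpool2",
    "upsample2_bilinear",
    "gaussian_blur2d",
    "concat",
    "relu",
    "mean",
    "total",
    "absolute",
    "gaussian_kernel1d",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    """Node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = parents
        self._backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # ---- graph traversal -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            grads = node._backward_fn(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g

    # ---- elementwise arithmetic -----------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            backward_fn=lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward_fn=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward_fn=lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            backward_fn=lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        return Tensor(
            self.data**exponent,
            parents=(self,),
            backward_fn=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )


# ---------------------------------------------------------------------------
# activation / reductions
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,), backward_fn=lambda g: (g * mask,))


def absolute(x: Tensor) -> Tensor:
    sign = np.sign(x.data)
    return Tensor(np.abs(x.data), parents=(x,), backward_fn=lambda g: (g * sign,))


def total(x: Tensor) -> Tensor:
    """Sum of all elements."""
    return Tensor(
        np.asarray(x.data.sum()),
        parents=(x,),
        backward_fn=lambda g: (np.broadcast_to(g, x.data.shape).copy(),),
    )


def mean(x: Tensor) -> Tensor:
    n = x.data.size
    return total(x) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward_fn=backward,
    )


# ---------------------------------------------------------------------------
# convolution (stride 1, odd kernel, 'same' zero padding)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2-D convolution in channel-first layout: x is (Cin, N, H, W), w is
    (Cout, Cin, k, k), bias (Cout, 1, 1, 1); stride 1, zero 'same' padding.

    The channel-leading layout makes im2col a contiguous (Cin·k², N·H·W)
    matrix, so forward, weight-gradient and input-gradient passes are each a
    single BLAS GEMM without transposed copies.
    """
    xd, wd = x.data, w.data
    cin, n, h, wth = xd.shape
    cout, cin2, k, k2 = wd.shape
    assert cin == cin2 and k == k2 and k % 2 == 1
    nhw = n * h * wth
    xf = xd.reshape(cin, nhw)

    if k == 1:
        wmat = wd.reshape(cout, cin)
        out = (wmat @ xf).reshape(cout, n, h, wth)
        if b is not None:
            out += b.data

        def backward(g):
            gmat = np.ascontiguousarray(g).reshape(cout, nhw)
            dw = (gmat @ xf.T).reshape(wd.shape)
            dx = (wmat.T @ gmat).reshape(cin, n, h, wth)
            db = g.sum(axis=(1, 2, 3)).reshape(cout, 1, 1, 1) if b is not None else None
            return (dx, dw, db) if b is not None else (dx, dw)

        parents = (x, w, b) if b is not None else (x, w)
        return Tensor(out, parents=parents, backward_fn=backward)

    # k x k conv as shift-GEMM: one GEMM over all kernel taps, then k² shifted
    # slice-adds — avoids materializing an im2col matrix (k² x the input size)
    p = k // 2
    w9 = np.ascontiguousarray(wd.transpose(2, 3, 0, 1)).reshape(k * k * cout, cin)
    p9 = (w9 @ xf).reshape(k, k, cout, n, h, wth)
    out = np.zeros((cout, n, h, wth), dtype=xd.dtype)
    for u in range(k):
        for v in range(k):
            du, dv = u - p, v - p
            ys_o = slice(max(0, -du), h - max(0, du))
            xs_o = slice(max(0, -dv), wth - max(0, dv))
            ys_i = slice(max(0, du), h - max(0, -du))
            xs_i = slice(max(0, dv), wth - max(0, -dv))
            out[:, :, ys_o, xs_o] += p9[u, v][:, :, ys_i, xs_i]
    if b is not None:
        out += b.data

    def backward(g):
        # G9[u, v] is g shifted by the tap offset with zero fill; then both the
        # weight and input gradients are single GEMMs against it
        g9 = np.zeros((k, k, cout, n, h, wth), dtype=g.dtype)
        for u in range(k):
            for v in range(k):
                du, dv = u - p, v - p
                ys_o = slice(max(0, -du), h - max(0, du))
                xs_o = slice(max(0, -dv), wth - max(0, dv))
                ys_i = slice(max(0, du), h - max(0, -du))
                xs_i = slice(max(0, dv), wth - max(0, -dv))
                g9[u, v][:, :, ys_i, xs_i] = g[:, :, ys_o, xs_o]
        gf = g9.reshape(k * k * cout, nhw)
        dw = (gf @ xf.T).reshape(k, k, cout, cin).transpose(2, 3, 0, 1)
        dx = (w9.T @ gf).reshape(cin, n, h, wth)
        db = g.sum(axis=(1, 2, 3)).reshape(cout, 1, 1, 1) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, parents=parents, backward_fn=backward)


# ---------------------------------------------------------------------------
# pooling / upsampling
# ---------------------------------------------------------------------------

def maxpool2(x: Tensor) -> Tensor:
    """2×2 max pooling, stride 2, over the last two axes; H and W must be even."""
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dx = (
            dr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        return (dx,)

    return Tensor(out, parents=(x,), backward_fn=backward)


def _linear_upsample_indices(n_in: int):
    """Gather indices/weights for ×2 bilinear upsampling (align_corners=False)."""
    src = (np.arange(2 * n_in) + 0.5) / 2.0 - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    return i0, i1, w1


def _upsample_axis(arr: np.ndarray, axis: int):
    i0, i1, w1 = _linear_upsample_indices(arr.shape[axis])
    shape = [1] * arr.ndim
    shape[axis] = len(w1)
    w1b = w1.reshape(shape)
    out = np.take(arr, i0, axis=axis) * (1 - w1b) + np.take(arr, i1, axis=axis) * w1b
    return out, (i0, i1, w1b)


def _upsample_axis_backward(g: np.ndarray, n_in: int, axis: int, meta=None) -> np.ndarray:
    """Adjoint of ×2 bilinear upsampling along ``axis`` (slice-based scatter).

    Forward weights (align_corners=False): even output 2m = 0.25·x[m-1] +
    0.75·x[m] (m >= 1, out 0 = x[0]); odd output 2m+1 = 0.75·x[m] +
    0.25·x[m+1] (m <= n-2, last = x[n-1]).
    """
    shape = list(g.shape)
    shape[axis] = n_in
    dx = np.zeros(shape, dtype=g.dtype)
    gm = np.moveaxis(g, axis, 0)
    dxm = np.moveaxis(dx, axis, 0)
    ge, go = gm[0::2], gm[1::2]
    n = n_in
    dxm[0] += ge[0]
    dxm[0 : n - 1] += 0.25 * ge[1:n]
    dxm[1:n] += 0.75 * ge[1:n]
    dxm[0 : n - 1] += 0.75 * go[0 : n - 1]
    dxm[1:n] += 0.25 * go[0 : n - 1]
    dxm[n - 1] += go[n - 1]
    return dx


def upsample2_bilinear(x: Tensor) -> Tensor:
    """Bilinear ×2 upsampling along the last two (spatial) axes."""
    n_h, n_w = x.data.shape[2], x.data.shape[3]
    yh, meta_h = _upsample_axis(x.data, axis=2)
    y, meta_w = _upsample_axis(yh, axis=3)

    def backward(g):
        gh = _upsample_axis_backward(g, n_w, 3, meta_w)
        return (_upsample_axis_backward(gh, n_h, 2, meta_h),)

    return Tensor(y, parents=(x,), backward_fn=backward)


# ---------------------------------------------------------------------------
# separable Gaussian blur (self-adjoint: symmetric kernel + zero padding)
# ---------------------------------------------------------------------------

def gaussian_kernel1d(sigma: float = 1.5, radius: int = 5) -> np.ndarray:
    t = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def _correlate_sep(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    from scipy.ndimage import correlate1d

    out = correlate1d(arr, kernel.astype(arr.dtype), axis=-2, mode="constant", cval=0.0)
    return correlate1d(out, kernel.astype(arr.dtype), axis=-1, mode="constant", cval=0.0)


def gaussian_blur2d(x: Tensor, kernel: np.ndarray) -> Tensor:
    """Depthwise separable blur over the last two axes. The kernel is
    symmetric and padding is zero, so the operator is self-adjoint and the
    backward pass is the same correlation applied to the gradient."""
    out = _correlate_sep(x.data, kernel)
    return Tensor(out, parents=(x,), backward_fn=lambda g: (_correlate_sep(g, kernel),))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
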