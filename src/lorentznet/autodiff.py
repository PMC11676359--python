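"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small convolutional classifiers and differentiates
hyperbolic-geometry expressions (exp-map, Lorentz inner products, signed
distances to hyperplanes) both with respect to parameters and with respect
to input images (for gradient-based adversarial attacks).  This module
provides exactly the operator set those computations need: broadcasting
arithmetic, matmul, reductions, elementwise transcendentals, 2-D
convolution/pooling via im2col, and a fused log-sum-exp.

Gradients follow the usual conventions: ``Tensor.backward()`` seeds the
output with ones (the output must be scalar for training losses) and
accumulates ``.grad`` arrays on every tensor created with
``requires_grad=True``.  All computation is float64 for reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # Sum over leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
            if self.grad.shape != self.data.shape:  # scalar seed broadcast
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)

        out._backward = backward
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = backward
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise ----------------------------------------------------
    def _unary(self, value: np.ndarray, dval: np.ndarray) -> "Tensor":
        out = Tensor(value, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * dval)

        out._backward = backward
        return out

    def exp(self):
        v = np.exp(self.data)
        return self._unary(v, v)

    def log(self):
        return self._unary(np.log(self.data), 1.0 / self.data)

    def sqrt(self):
        v = np.sqrt(self.data)
        return self._unary(v, 0.5 / v)

    def sinh(self):
        return self._unary(np.sinh(self.data), np.cosh(self.data))

    def cosh(self):
        return self._unary(np.cosh(self.data), np.sinh(self.data))

    def tanh(self):
        v = np.tanh(self.data)
        return self._unary(v, 1.0 - v**2)

    def arcsinh(self):
        return self._unary(np.arcsinh(self.data), 1.0 / np.sqrt(self.data**2 + 1.0))

    def relu(self):
        mask = self.data > 0
        return self._unary(np.where(mask, self.data, 0.0), mask.astype(np.float64))

    def maximum(self, c: float):
        """Elementwise max with a constant; subgradient 1 where data > c."""
        mask = (self.data > c).astype(np.float64)
        return self._unary(np.maximum(self.data, c), mask)

    def minimum(self, c: float):
        mask = (self.data < c).astype(np.float64)
        return self._unary(np.minimum(self.data, c), mask)

    # -- fused numerics -------------------------------------------------
    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        s = np.exp(self.data - m).sum(axis=axis, keepdims=True)
        val = m + np.log(s)
        soft = np.exp(self.data - val)  # softmax along axis
        if not keepdims:
            val = np.squeeze(val, axis=axis)
        out = Tensor(val, parents=(self,))

        def backward(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(gg * soft)

        out._backward = backward
        return out

    # -- convolution / pooling ------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """NCHW 2-D cross-correlation with square stride/padding."""
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        Co, Ci, kh, kw = w.shape
        if Ci != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x
        Ho = (xp.shape[2] - kh) // stride + 1
        Wo = (xp.shape[3] - kw) // stride + 1
        # im2col in (C*kh*kw, B*Ho*Wo) layout: built by kh*kw block copies so
        # both the GEMM below and the col2im scatter stay cache-friendly.
        cols = np.empty((C, kh, kw, B, Ho, Wo))
        for i in range(kh):
            for j in range(kw):
                cols[:, i, j] = xp[:, :, i:i + stride * Ho:stride,
                                   j:j + stride * Wo:stride].transpose(1, 0, 2, 3)
        cols2 = cols.reshape(C * kh * kw, B * Ho * Wo)
        wf = w.reshape(Co, C * kh * kw)
        out_data = np.ascontiguousarray(
            (wf @ cols2).reshape(Co, B, Ho, Wo).transpose(1, 0, 2, 3)
        )
        if bias is not None:
            out_data += bias.data.reshape(1, Co, 1, 1)
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = Tensor(out_data, parents=parents)

        def backward(g):
            gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(Co, B * Ho * Wo)
            if bias is not None and bias.requires_grad:
                bias._accumulate(gmat.sum(axis=1))
            if weight.requires_grad:
                weight._accumulate((gmat @ cols2.T).reshape(w.shape))
            if self.requires_grad:
                dcols = (wf.T @ gmat).reshape(C, kh, kw, B, Ho, Wo)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + stride * Ho:stride,
                            j:j + stride * Wo:stride] += dcols[:, i, j].transpose(1, 0, 2, 3)
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                self._accumulate(dxp)

        out._backward = backward
        return out

    def maxpool2d(self, size: int = 2, stride: int | None = None):
        stride = stride or size
        x = self.data
        B, C, H, W = x.shape
        Ho = (H - size) // stride + 1
        Wo = (W - size) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (size, size), axis=(2, 3))
        win = win[:, :, ::stride, ::stride].reshape(B, C, Ho, Wo, size * size)
        arg = win.argmax(axis=-1)
        out = Tensor(win.max(axis=-1), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            dx = np.zeros_like(x)
            ii, jj = np.divmod(arg, size)
            b, c, oi, oj = np.indices(arg.shape)
            np.add.at(dx, (b, c, oi * stride + ii, oj * stride + jj), g)
            self._accumulate(dx)

        out._backward = backward
        return out


class Parameter(Tensor):
    """A trainable tensor, optionally attached to a manifold.

    ``manifold`` is None for ordinary Euclidean parameters; a
    ``LorentzManifold`` instance marks the parameter as a point on the
    hyperboloid, so the Riemannian optimizer applies the metric correction
    and an exp-map retraction instead of a flat update.
    """

    __slots__ = ("name", "manifold", "lr_scale")

    def __init__(self, data, name: str = "", manifold=None, lr_scale: float = 1.0):
        super().__init__(data, requires_grad=True)
        self.name = name
        self.manifold = manifold
        self.lr_scale = lr_scale


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out
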