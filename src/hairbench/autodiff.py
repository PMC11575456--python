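"""Minimal reverse-mode automatic differentiation on numpy arrays.

The hair-removal network is trained with an explicit custom loop (forward
pass, backpropagation, Adam update), so the package carries its own small
tape-based autodiff engine rather than a deep-learning framework.  Only the
operations the U-Net and the composite loss need are implemented: dense 2-D
convolution, 2x2 transposed convolution, 2x2 max/average pooling, channel
concatenation, fixed-kernel depthwise convolution (for windowed SSIM
statistics), and elementwise arithmetic with broadcasting.

All values are float64; gradients are checked against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "as_tensor", "concat_channels"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached backward function."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep ndarray.__op__ from hijacking mixed ops

    def __init__(self, value, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value + other.value, parents=(self, other))

        def backward(go):
            return (_unbroadcast(go, self.shape), _unbroadcast(go, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, parents=(self,))
        out._backward = (lambda go: (-go,)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def backward(go):
            return (_unbroadcast(go * other.value, self.shape),
                    _unbroadcast(go * self.value, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value / other.value, parents=(self, other))

        def backward(go):
            return (_unbroadcast(go / other.value, self.shape),
                    _unbroadcast(-go * self.value / other.value ** 2, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    # ------------------------------------------------------------ elementwise
    def square(self):
        out = Tensor(self.value ** 2, parents=(self,))
        out._backward = (lambda go: (2.0 * self.value * go,)) if out.requires_grad else None
        return out

    def abs(self):
        out = Tensor(np.abs(self.value), parents=(self,))
        # subgradient 0 at zero
        out._backward = (lambda go: (np.sign(self.value) * go,)) if out.requires_grad else None
        return out

    def relu(self):
        out = Tensor(np.maximum(self.value, 0.0), parents=(self,))
        out._backward = (lambda go: ((self.value > 0) * go,)) if out.requires_grad else None
        return out

    def sigmoid(self):
        s = expit(self.value)
        out = Tensor(s, parents=(self,))
        out._backward = (lambda go: (s * (1.0 - s) * go,)) if out.requires_grad else None
        return out

    # -------------------------------------------------------------- reductions
    def sum(self):
        out = Tensor(self.value.sum(), parents=(self,))
        out._backward = (lambda go: (np.broadcast_to(go, self.shape).copy(),)) \
            if out.requires_grad else None
        return out

    def mean(self):
        n = self.value.size
        out = Tensor(self.value.mean(), parents=(self,))
        out._backward = (lambda go: (np.broadcast_to(go / n, self.shape).copy(),)) \
            if out.requires_grad else None
        return out

    # ------------------------------------------------------------- structured
    def reshape(self, *shape):
        out = Tensor(self.value.reshape(*shape), parents=(self,))
        out._backward = (lambda go: (go.reshape(self.shape),)) if out.requires_grad else None
        return out

    def slice_rows(self, axis: int, start: int, stop: int, step: int = 1):
        """Static strided slice along one axis (used by total-variation loss)."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, stop, step)
        idx = tuple(idx)
        out = Tensor(self.value[idx], parents=(self,))

        def backward(go):
            g = np.zeros_like(self.value)
            g[idx] = go
            return (g,)

        out._backward = backward if out.requires_grad else None
        return out

    # ---------------------------------------------------------- convolutions
    def conv2d(self, weight: "Tensor", bias: "Tensor", padding: int = 1):
        """Cross-correlation of an (N,C,H,W) input with (F,C,k,k) weights."""
        x, w, b = self.value, weight.value, bias.value
        n, c, h, wid = x.shape
        f, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"channel mismatch: input {c}, weight {c2}")
        p = padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho, wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * kh * kw)
        wmat = w.reshape(f, c * kh * kw).T
        out_v = (cols @ wmat).reshape(n, ho, wo, f).transpose(0, 3, 1, 2) \
            + b[None, :, None, None]
        out = Tensor(out_v, parents=(self, weight, bias))

        def backward(go):
            go_m = np.ascontiguousarray(go.transpose(0, 2, 3, 1)).reshape(n * ho * wo, f)
            gw = (go_m.T @ cols).reshape(f, c, kh, kw)
            gb = go_m.sum(axis=0)
            gcols = (go_m @ wmat.T).reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + ho, j:j + wo] += gcols[:, :, :, :, i, j]
            gx = gxp[:, :, p:p + h, p:p + wid] if p else gxp
            return (gx, gw, gb)

        out._backward = backward if out.requires_grad else None
        return out

    def conv_transpose2x2(self, weight: "Tensor", bias: "Tensor"):
        """2x upsampling: transposed convolution, 2x2 kernel, stride 2.

        weight has shape (C_in, C_out, 2, 2); output is (N, C_out, 2H, 2W).
        """
        x, w, b = self.value, weight.value, bias.value
        n, c, h, wid = x.shape
        c2, f = w.shape[:2]
        if c != c2:
            raise ValueError(f"channel mismatch: input {c}, weight {c2}")
        out_v = np.empty((n, f, 2 * h, 2 * wid))
        for i in (0, 1):
            for j in (0, 1):
                out_v[:, :, i::2, j::2] = np.tensordot(
                    x, w[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
        out_v += b[None, :, None, None]
        out = Tensor(out_v, parents=(self, weight, bias))

        def backward(go):
            gx = np.zeros_like(x)
            gw = np.zeros_like(w)
            for i in (0, 1):
                for j in (0, 1):
                    sub = go[:, :, i::2, j::2]          # (N,F,H,W)
                    gx += np.tensordot(sub, w[:, :, i, j], axes=([1], [1])
                                       ).transpose(0, 3, 1, 2)
                    gw[:, :, i, j] = np.tensordot(x, sub, axes=([0, 2, 3], [0, 2, 3]))
            gb = go.sum(axis=(0, 2, 3))
            return (gx, gw, gb)

        out._backward = backward if out.requires_grad else None
        return out

    def maxpool2(self):
        x = self.value
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2 needs even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out_v = xr.max(axis=(3, 5))
        out = Tensor(out_v, parents=(self,))

        def backward(go):
            mask = xr == out_v[:, :, :, None, :, None]
            # split gradient among ties (measure-zero event for real data)
            cnt = mask.sum(axis=(3, 5), keepdims=True)
            g = mask * (go[:, :, :, None, :, None] / cnt)
            return (g.reshape(n, c, h, w),)

        out._backward = backward if out.requires_grad else None
        return out

    def avgpool2(self):
        x = self.value
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("avgpool2 needs even spatial dimensions")
        out_v = x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        out = Tensor(out_v, parents=(self,))

        def backward(go):
            g = np.broadcast_to(go[:, :, :, None, :, None] / 4.0,
                                (n, c, h // 2, 2, w // 2, 2))
            return (g.reshape(n, c, h, w).copy(),)

        out._backward = backward if out.requires_grad else None
        return out

    def depthwise_valid_conv(self, kernel: np.ndarray):
        """Valid-mode correlation of every channel with one fixed 2-D kernel.

        The kernel is a constant (no gradient); used for Gaussian-windowed
        local statistics inside SSIM.
        """
        x = self.value
        kh, kw = kernel.shape
        win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
        out_v = np.tensordot(win, kernel, axes=([4, 5], [0, 1]))
        out = Tensor(out_v, parents=(self,))

        def backward(go):
            gop = np.pad(go, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            winb = np.lib.stride_tricks.sliding_window_view(gop, (kh, kw), axis=(2, 3))
            gx = np.tensordot(winb, kernel[::-1, ::-1], axes=([4, 5], [0, 1]))
            return (gx,)

        out._backward = backward if out.requires_grad else None
        return out

    # --------------------------------------------------------------- autodiff
    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order: graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        for t in order:
            t.grad = np.zeros_like(t.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    parent.grad = parent.grad + g if parent.grad is not None else g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two (N,C,H,W) tensors along the channel axis."""
    ca = a.shape[1]
    out = Tensor(np.concatenate([a.value, b.value], axis=1), parents=(a, b))

    def backward(go):
        return (go[:, :ca], go[:, ca:])

    out._backward = backward if out.requires_grad else None
    return out
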