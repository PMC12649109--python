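"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the segmentation network needs are implemented:
elementwise arithmetic with broadcasting, matmul, reductions, the usual
activations, 2-D convolution (with dilation), 2x2 stride-2 transposed
convolution, 2x2 max-pooling, channel concatenation and embedding lookup.
Everything is float64 and runs on the CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                if not keepdims:
                    for ax in sorted(a % self.data.ndim for a in axes):
                        g = np.expand_dims(g, ax)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in ((axis,) if np.isscalar(axis) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    # -- activations ---------------------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only through the unclipped range."""
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            if self.requires_grad:
                inside = (self.data >= lo) & (self.data <= hi)
                self._accum(g * inside)

        return Tensor._make(out_data, (self,), backward)

    # -- network-specific primitives -----------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", padding: int = 1,
               dilation: int = 1) -> "Tensor":
        """3x3 (or kxk) stride-1 convolution, NCHW layout.

        weight: (C_out, C_in, k, k); `padding` is applied on both sides.
        """
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        Cout, Cin, k, _ = w.shape
        if Cin != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cin}")
        p = padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = xp.shape[2] - dilation * (k - 1)
        Wo = xp.shape[3] - dilation * (k - 1)
        out = np.zeros((B, Cout, Ho, Wo))
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * dilation:i * dilation + Ho,
                        j * dilation:j * dilation + Wo]
                out += np.einsum("bchw,oc->bohw", xs, w[:, :, i, j], optimize=True)
        out += bias.data[None, :, None, None]

        def backward(g):
            if weight.requires_grad or self.requires_grad:
                gxp = np.zeros_like(xp) if self.requires_grad else None
                gw = np.zeros_like(w) if weight.requires_grad else None
                for i in range(k):
                    for j in range(k):
                        sl_h = slice(i * dilation, i * dilation + Ho)
                        sl_w = slice(j * dilation, j * dilation + Wo)
                        if gw is not None:
                            gw[:, :, i, j] = np.einsum(
                                "bohw,bchw->oc", g, xp[:, :, sl_h, sl_w],
                                optimize=True)
                        if gxp is not None:
                            gxp[:, :, sl_h, sl_w] += np.einsum(
                                "bohw,oc->bchw", g, w[:, :, i, j], optimize=True)
                if gw is not None:
                    weight._accum(gw)
                if gxp is not None:
                    self._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))

        return Tensor._make(out, (self, weight, bias), backward)

    def conv_transpose2x2(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """2x2 stride-2 transposed convolution (exact 2x upsampling).

        weight: (C_in, C_out, 2, 2).
        """
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        Cin, Cout, _, _ = w.shape
        if Cin != C:
            raise ValueError(f"conv_transpose channel mismatch: {C} vs {Cin}")
        out = np.empty((B, Cout, 2 * H, 2 * W))
        for i in range(2):
            for j in range(2):
                out[:, :, i::2, j::2] = np.einsum(
                    "bchw,co->bohw", x, w[:, :, i, j], optimize=True)
        out += bias.data[None, :, None, None]

        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(x)
                for i in range(2):
                    for j in range(2):
                        gx += np.einsum("bohw,co->bchw", g[:, :, i::2, j::2],
                                        w[:, :, i, j], optimize=True)
                self._accum(gx)
            if weight.requires_grad:
                gw = np.zeros_like(w)
                for i in range(2):
                    for j in range(2):
                        gw[:, :, i, j] = np.einsum(
                            "bchw,bohw->co", x, g[:, :, i::2, j::2], optimize=True)
                weight._accum(gw)
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))

        return Tensor._make(out, (self, weight, bias), backward)

    def maxpool2x2(self) -> "Tensor":
        x = self.data
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {H}x{W}")
        windows = x.reshape(B, C, H // 2, 2, W // 2, 2)
        windows = windows.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            if not self.requires_grad:
                return
            gwin = np.zeros((B, C, H // 2, W // 2, 4))
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
            gx = gwin.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gx.reshape(B, C, H, W))

        return Tensor._make(out, (self,), backward)

    def embedding_lookup(self, idx: np.ndarray) -> "Tensor":
        """Row lookup: self is a (K, d) table, idx a (B,) int array of rows."""
        idx = np.asarray(idx, dtype=np.int64)
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, idx, g)
                self._accum(grad)

        return Tensor._make(out_data, (self,), backward)

    # -- backward ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep at 224x224
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
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)
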