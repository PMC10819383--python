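"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: every operation on :class:`Tensor` records a
closure that propagates gradients to its inputs.  Broadcasting follows NumPy
semantics; gradients flowing into a broadcast operand are summed over the
broadcast axes.  Only the primitives needed by the network family live here
(elementwise arithmetic, matmul, reductions, shape moves, a grouped 2-D
convolution, softmax).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "softmax", "log_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev",
                 "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self._grad_shared = False
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    def _lift(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    @staticmethod
    def _result(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        # first contribution is stored by reference (it may alias another
        # node's gradient); a second contribution allocates a fresh array, so
        # shared arrays are never mutated in place
        if self.grad is None:
            self.grad = grad
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + grad
            self._grad_shared = False
        else:
            self.grad += grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return self._result(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._result(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._result(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return self._result(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._result(out_data, (self,), backward)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (sig * (1.0 + self.data * (1.0 - sig))))

        return self._result(out_data, (self,), backward)

    # -- reductions and shape moves -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return self._result(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        return self._result(self.data.transpose(axes), (self,), backward)

    # -- backward driver -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
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
            for parent in node._prev:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def softmax(x: Tensor, axis: int) -> Tensor:
    """Numerically stable softmax along ``axis`` (max-shift is gradient-free)."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def conv2d(x: Tensor, weight: Tensor, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation.

    ``x``: (B, Cin, H, W); ``weight``: (Cout, Cin/groups, kh, kw).  Bias-free by
    convention; the forward/backward pair loops over the (small) kernel
    support and lets BLAS handle the channel contractions.
    """
    B, Cin, H, W = x.shape
    Cout, Cg, kh, kw = weight.shape
    if Cin != Cg * groups:
        raise ValueError(f"channel mismatch: input has {Cin}, weight expects {Cg * groups}")
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data

    og = Cout // groups
    out_data = np.zeros((B, Cout, Ho, Wo), dtype=x.data.dtype)
    # cache strided input views per kernel offset for the backward pass
    views = {}
    for ki in range(kh):
        for kj in range(kw):
            xs = xp[:, :, ki:ki + stride * Ho:stride, kj:kj + stride * Wo:stride]
            views[(ki, kj)] = xs
            if groups == 1:
                out_data += np.einsum("oc,bchw->bohw", weight.data[:, :, ki, kj], xs,
                                      optimize=True)
            else:
                xg = xs.reshape(B, groups, Cg, Ho, Wo)
                wg = weight.data[:, :, ki, kj].reshape(groups, og, Cg)
                out_data += np.einsum("goc,bgchw->bgohw", wg, xg,
                                      optimize=True).reshape(B, Cout, Ho, Wo)

    def backward(g):
        if weight.requires_grad:
            dw = np.zeros_like(weight.data)
            for (ki, kj), xs in views.items():
                if groups == 1:
                    dw[:, :, ki, kj] = np.einsum("bohw,bchw->oc", g, xs, optimize=True)
                else:
                    xg = xs.reshape(B, groups, Cg, Ho, Wo)
                    gg = g.reshape(B, groups, og, Ho, Wo)
                    dw[:, :, ki, kj] = np.einsum("bgohw,bgchw->goc", gg, xg,
                                                 optimize=True).reshape(Cout, Cg)
            weight._accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros((B, Cin, H + 2 * padding, W + 2 * padding), dtype=g.dtype)
            for (ki, kj) in views:
                sl = np.s_[:, :, ki:ki + stride * Ho:stride, kj:kj + stride * Wo:stride]
                if groups == 1:
                    dxp[sl] += np.einsum("oc,bohw->bchw", weight.data[:, :, ki, kj], g,
                                         optimize=True)
                else:
                    wg = weight.data[:, :, ki, kj].reshape(groups, og, Cg)
                    gg = g.reshape(B, groups, og, Ho, Wo)
                    dxp[sl] += np.einsum("goc,bgohw->bgchw", wg, gg,
                                         optimize=True).reshape(B, Cin, Ho, Wo)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor._result(out_data, (x, weight), backward)
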