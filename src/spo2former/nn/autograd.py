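"""Reverse-mode automatic differentiation on numpy arrays.

A compact tape-based autodiff engine sufficient for the models in this
package: dense layers, layer normalization, softmax attention, 1-D
(transposed) convolutions, dropout and a numerically stable binary
cross-entropy. Tensors wrap ``numpy.ndarray`` data; operations build a
DAG and :meth:`Tensor.backward` accumulates gradients by reverse
topological traversal. All computation is float64.

Gradient correctness of every primitive is exercised by central
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "bce_with_logits", "softmax", "conv1d", "conv_transpose1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph holding a float64 array and its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backward pass -------------------------------------------------------

    def backward(self, grad=None) -> None:
        """Accumulate gradients of this (typically scalar) tensor's parents."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        exponent = float(exponent)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._from_op(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
                )
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
                )

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions and shape ops ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes: tuple[int, ...]):
        inverse = tuple(np.argsort(axes))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            # ds = s * (g - sum(g * s))
            inner = (g * out_data).sum(axis=axis, keepdims=True)
            x._accumulate(out_data * (g - inner))

    return Tensor._from_op(out_data, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    ``loss = mean(max(z, 0) - z * y + log(1 + exp(-|z|)))``, optionally a
    weighted mean with per-element ``weights``.
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    elem = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    if weights is None:
        loss = elem.mean()
        scale = 1.0 / elem.size
        w = None
    else:
        w = np.asarray(weights, dtype=np.float64)
        wsum = w.sum()
        loss = float((w * elem).sum() / wsum)
        scale = None

    def backward(g):
        if logits.requires_grad:
            p = 0.5 * (1.0 + np.tanh(0.5 * z))
            if w is None:
                logits._accumulate(g * (p - y) * scale)
            else:
                logits._accumulate(g * w * (p - y) / w.sum())

    return Tensor._from_op(loss, (logits,), backward)


# -- 1-D convolutions ---------------------------------------------------------
#
# Channels-last layout: inputs are (batch, time, channels); weights are
# (kernel, in_channels, out_channels). "Same" padding: a stride-s layer maps
# length T to ceil(T / s); the transposed layer takes an explicit output
# length and is the exact adjoint of the corresponding forward convolution.


def _same_pad(t_in: int, t_out: int, kernel: int, stride: int) -> tuple[int, int]:
    total = max((t_out - 1) * stride + kernel - t_in, 0)
    left = total // 2
    return left, total - left


def _conv_cols(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    # (B, L, C) -> (B, T_out, C, kernel) sliding windows
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)
    return win[:, ::stride]


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int) -> Tensor:
    """Same-padded 1-D convolution; output length is ``ceil(T / stride)``."""
    batch, t_in, _ = x.shape
    kernel = w.shape[0]
    t_out = -(-t_in // stride)
    pl, pr = _same_pad(t_in, t_out, kernel, stride)
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    cols = _conv_cols(xp, kernel, stride)  # (B, T_out, C_in, K)
    out_data = np.einsum("bock,kcd->bod", cols, w.data) + b.data

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bock,bod->kcd", cols, g))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            t = np.einsum("bod,kcd->bokc", g, w.data)
            gxp = np.zeros_like(xp)
            span = (t_out - 1) * stride + 1
            for k in range(kernel):
                gxp[:, k : k + span : stride, :] += t[:, :, k, :]
            x._accumulate(gxp[:, pl : pl + t_in, :])

    return Tensor._from_op(out_data, (x, w, b), backward)


def conv_transpose1d(x: Tensor, w: Tensor, b: Tensor, stride: int, output_length: int) -> Tensor:
    """Transposed 1-D convolution restoring an explicit ``output_length``.

    Exact adjoint of :func:`conv1d` with the same kernel/stride mapping
    ``output_length -> ceil(output_length / stride)``, so stride-2 encoder
    layers can be mirrored for any input length, odd or even.
    """
    batch, t_in, _ = x.shape
    kernel = w.shape[0]
    if -(-output_length // stride) != t_in:
        raise ValueError(
            f"output_length {output_length} is incompatible with input length "
            f"{t_in} at stride {stride}"
        )
    pl, pr = _same_pad(output_length, t_in, kernel, stride)
    full = (t_in - 1) * stride + kernel
    span = (t_in - 1) * stride + 1

    t = np.einsum("bic,kcd->bikd", x.data, w.data)
    zp = np.zeros((batch, full, w.shape[2]))
    for k in range(kernel):
        zp[:, k : k + span : stride, :] += t[:, :, k, :]
    out_data = zp[:, pl : pl + output_length, :] + b.data

    def backward(g):
        gp = np.pad(g, ((0, 0), (pl, max(full - pl - output_length, 0)), (0, 0)))
        gp = gp[:, :full, :]
        win = _conv_cols(gp, kernel, stride)  # (B, T_in, C_out, K)
        if x.requires_grad:
            x._accumulate(np.einsum("bidk,kcd->bic", win, w.data))
        if w.requires_grad:
            w._accumulate(np.einsum("bic,bidk->kcd", x.data, win))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))

    return Tensor._from_op(out_data, (x, w, b), backward)
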