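"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and
the closure needed to push gradients to its parents.  The op set is exactly
what the bridge transformer needs: broadcast arithmetic, batched matmul,
reductions, gather, stable log-softmax and layer normalisation.  Everything
runs in float32 by default (float64 upcasts are preserved).

Gradients of broadcast ops are un-broadcast by summing over the expanded
axes, matching the usual convention.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._backward = backward
        self._parents = tuple(parents)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if g.dtype == self.data.dtype else g.astype(self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    # python scalars stay "weak" (numpy promotion keeps the array dtype and
    # rounds the scalar at that precision), so float64 math stays exact and
    # float32 activations are never silently upcast
    def __add__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        if isinstance(other, (int, float)):
            out = Tensor(self.data + other, parents=(self,))
            out._backward = (
                (lambda g: self._accum(_unbroadcast(g, self.shape)))
                if self.requires_grad else None
            )
            return out
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g) if self.requires_grad else None
        return out

    def __sub__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-_as_tensor(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        if isinstance(other, (int, float)):
            return (-self) + other
        return _as_tensor(other) + (-self)

    def __mul__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, parents=(self,))
            out._backward = (
                (lambda g: self._accum(_unbroadcast(g * other, self.shape)))
                if self.requires_grad else None
            )
            return out
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bwd
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bwd
        return out

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, parents=(self,))
        out._backward = (
            (lambda g: self._accum(g * p * self.data ** (p - 1)))
            if self.requires_grad
            else None
        )
        return out

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = (
            (lambda g: self._accum(g.reshape(orig))) if self.requires_grad else None
        )
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))
        out._backward = (
            (lambda g: self._accum(np.swapaxes(g, a, b))) if self.requires_grad else None
        )
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd if self.requires_grad else None
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd if self.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max over one axis; gradient routed to (first) argmax entries."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            expanded = out_data if keepdims else np.expand_dims(out_data, axis)
            mask = self.data == expanded
            # split gradient among ties (ties are measure-zero in practice)
            counts = mask.sum(axis=axis, keepdims=True)
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * (gg / counts))

        out._backward = bwd if self.requires_grad else None
        return out

    # ------------------------------------------------------------ elementwise
    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = (
            (lambda g: self._accum(g * (1 - t * t))) if self.requires_grad else None
        )
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = (lambda g: self._accum(g * e)) if self.requires_grad else None
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = (
            (lambda g: self._accum(g / self.data)) if self.requires_grad else None
        )
        return out

    def gelu(self) -> "Tensor":
        # tanh approximation of GELU
        x = self.data
        c = x.dtype.type(np.sqrt(2.0 / np.pi))
        a = x.dtype.type(0.044715)
        x2 = x * x
        t = np.tanh(c * (x + a * (x2 * x)))
        out = Tensor(x.dtype.type(0.5) * x * (1 + t), parents=(self,))

        def bwd(g: np.ndarray) -> None:
            half = x.dtype.type(0.5)
            dinner = c * (1 + x.dtype.type(3) * a * x2)
            dgelu = half * (1 + t) + half * x * (1 - t * t) * dinner
            self._accum(g * dgelu)

        out._backward = bwd if self.requires_grad else None
        return out

    # --------------------------------------------------------- composite prims
    def log_softmax(self, axis: int = -1) -> "Tensor":
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        shifted = x - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        ls = shifted - lse
        out = Tensor(ls, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            softmax = np.exp(ls)
            self._accum(g - softmax * g.sum(axis=axis, keepdims=True))

        out._backward = bwd if self.requires_grad else None
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        return self.log_softmax(axis=axis).exp()

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-5) -> "Tensor":
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * weight.data + bias.data, parents=(self, weight, bias))

        def bwd(g: np.ndarray) -> None:
            d = x.shape[-1]
            if weight.requires_grad:
                weight._accum(_unbroadcast(g * xhat, weight.shape))
            if bias.requires_grad:
                bias._accum(_unbroadcast(g, bias.shape))
            if self.requires_grad:
                gx = g * weight.data
                term1 = gx
                term2 = gx.mean(axis=-1, keepdims=True)
                term3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                self._accum((term1 - term2 - term3) * inv)

        out._backward = bwd
        return out


def _as_tensor(x: Union[Tensor, ArrayLike]) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather with scatter-add gradient."""
    idx = np.asarray(idx)
    out = Tensor(weight.data[idx], parents=(weight,))

    def bwd(g: np.ndarray) -> None:
        full = np.zeros_like(weight.data)
        np.add.at(full, idx.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
        weight._accum(full)

    out._backward = bwd if weight.requires_grad else None
    return out


def add_const(x: Tensor, const: np.ndarray) -> Tensor:
    """Add a non-differentiable array (e.g. an attention mask)."""
    out = Tensor(x.data + const, parents=(x,))
    out._backward = (lambda g: x._accum(_unbroadcast(g, x.shape))) if x.requires_grad else None
    return out


def cross_entropy_with_logits(logits: Tensor, targets: np.ndarray, mask: Optional[np.ndarray] = None) -> Tensor:
    """Mean token-level cross entropy.

    ``logits``: (..., V); ``targets``: integer array broadcastable to the
    leading shape; ``mask``: optional boolean weighting (True = count).
    """
    ls = logits.log_softmax(axis=-1)
    flat = ls.reshape(-1, ls.shape[-1])
    t = np.asarray(targets).reshape(-1)
    picked = flat[np.arange(t.size), t]
    if mask is None:
        return -picked.mean()
    m = np.asarray(mask, dtype=flat.data.dtype).reshape(-1)
    total = m.sum()
    if total == 0:
        raise ValueError("cross entropy over an all-masked target set")
    return -(picked * Tensor(m)).sum() * (1.0 / float(total))
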