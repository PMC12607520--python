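"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run engine: every operation builds a node holding its
inputs and a closure that maps the output gradient to input gradients.
``Tensor.backward`` runs the closures in reverse topological order.

All arithmetic is float64.  The op set is exactly what the convolutional
mixture-of-experts model needs: broadcast arithmetic, matmul, basic slicing,
reshape/concat, reductions, ReLU/sigmoid/exp/log/sqrt, 2-D (grouped)
convolution, max/average pooling, and a fused softmax cross-entropy loss.
Convolution uses im2col backed by ``sliding_window_view`` so the inner loop
is a BLAS matmul.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "mean",
    "tsum",
    "reshape",
    "transpose",
    "concat",
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "global_avg_pool",
    "softmax_cross_entropy",
    "same_padding",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- introspection -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autograd ------------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep models overflow recursion limits
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

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), back)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        a = self

        def back(g):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), back)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def back(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), back)

    def __getitem__(self, key):
        a = self

        def back(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accumulate(full)

        return Tensor._make(a.data[key], (a,), back)


# -- elementwise nonlinearities ---------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def back(g):
        x._accumulate(g * mask)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), back)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def back(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), back)


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def back(g):
        x._accumulate(g * out_data)

    return Tensor._make(out_data, (x,), back)


def log(x: Tensor) -> Tensor:
    def back(g):
        x._accumulate(g / x.data)

    return Tensor._make(np.log(x.data), (x,), back)


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)

    def back(g):
        x._accumulate(g * 0.5 / out_data)

    return Tensor._make(out_data, (x,), back)


# -- shape ops ---------------------------------------------------------------


def reshape(x: Tensor, shape) -> Tensor:
    old = x.shape

    def back(g):
        x._accumulate(g.reshape(old))

    return Tensor._make(x.data.reshape(shape), (x,), back)


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def back(g):
        x._accumulate(g.transpose(inv))

    return Tensor._make(x.data.transpose(axes), (x,), back)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), back
    )


# -- reductions --------------------------------------------------------------


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def back(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.shape).copy())

    return Tensor._make(x.data.sum(axis=axis, keepdims=keepdims), (x,), back)


def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        count = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([x.shape[a] for a in axes]))

    def back(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.shape) / count)

    return Tensor._make(x.data.mean(axis=axis, keepdims=keepdims), (x,), back)


# -- convolution and pooling -------------------------------------------------


def same_padding(size: int, kernel: int, stride: int) -> tuple[int, int]:
    """TensorFlow-style 'same' padding (before, after) for one spatial axis."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


def _pad_hw(x: np.ndarray, pads, fill: float = 0.0) -> np.ndarray:
    (pt, pb), (pl, pr) = pads
    if pt == pb == pl == pr == 0:
        return x
    return np.pad(
        x, ((0, 0), (0, 0), (pt, pb), (pl, pr)), constant_values=fill
    )


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: str | int = "same",
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation. ``x``: (N, C, H, W); ``weight``: (K, C/groups, kh, kw)."""
    N, C, H, W = x.shape
    K, Cg, kh, kw = weight.shape
    if C != Cg * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {C} channels, "
            f"kernel expects {Cg * groups} (groups={groups})"
        )
    if K % groups:
        raise ValueError("output channels must divide evenly into groups")
    if padding == "same":
        pads = (same_padding(H, kh, stride), same_padding(W, kw, stride))
    else:
        p = int(padding)
        pads = ((p, p), (p, p))
    xp = _pad_hw(x.data, pads)
    Hp, Wp = xp.shape[2], xp.shape[3]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (N, C, OH, OW, kh, kw)
    Kg = K // groups
    out = np.empty((N, K, OH, OW))
    cols_cache = []
    for g in range(groups):
        wg = weight.data[g * Kg : (g + 1) * Kg].reshape(Kg, -1)
        cols = (
            win[:, g * Cg : (g + 1) * Cg]
            .transpose(0, 2, 3, 1, 4, 5)
            .reshape(N * OH * OW, Cg * kh * kw)
        )
        cols_cache.append(cols)
        out[:, g * Kg : (g + 1) * Kg] = (
            (cols @ wg.T).reshape(N, OH, OW, Kg).transpose(0, 3, 1, 2)
        )
    if bias is not None:
        out += bias.data.reshape(1, K, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def back(g_out):
        # g_out: (N, K, OH, OW)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g_out.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        if need_x:
            dxp = np.zeros((N, C, Hp, Wp))
        for g in range(groups):
            go = (
                g_out[:, g * Kg : (g + 1) * Kg]
                .transpose(0, 2, 3, 1)
                .reshape(N * OH * OW, Kg)
            )
            if weight.requires_grad:
                dw = (go.T @ cols_cache[g]).reshape(Kg, Cg, kh, kw)
                wslice = slice(g * Kg, (g + 1) * Kg)
                if weight.grad is None:
                    weight.grad = np.zeros_like(weight.data)
                weight.grad[wslice] += dw
            if need_x:
                wg = weight.data[g * Kg : (g + 1) * Kg].reshape(Kg, -1)
                dcols = (go @ wg).reshape(N, OH, OW, Cg, kh, kw)
                dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # N,Cg,OH,OW,kh,kw
                cs = slice(g * Cg, (g + 1) * Cg)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, cs, i : i + stride * OH : stride,
                            j : j + stride * OW : stride] += dcols[..., i, j]
        if need_x:
            (pt, pb), (pl, pr) = pads
            x._accumulate(dxp[:, :, pt : Hp - pb or None, pl : Wp - pr or None])

    return Tensor._make(out, parents, back)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2,
               padding: str = "same") -> Tensor:
    N, C, H, W = x.shape
    if padding == "same":
        pads = (same_padding(H, kernel, stride), same_padding(W, kernel, stride))
    else:
        pads = ((0, 0), (0, 0))
    xp = _pad_hw(x.data, pads, fill=-np.inf)
    Hp, Wp = xp.shape[2], xp.shape[3]
    OH = (Hp - kernel) // stride + 1
    OW = (Wp - kernel) // stride + 1
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(N, C, OH, OW, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def back(g):
        dxp = np.zeros((N, C, Hp, Wp))
        n_i, c_i, oh_i, ow_i = np.indices(idx.shape)
        h_pos = oh_i * stride + idx // kernel
        w_pos = ow_i * stride + idx % kernel
        np.add.at(dxp, (n_i, c_i, h_pos, w_pos), g)
        (pt, pb), (pl, pr) = pads
        x._accumulate(dxp[:, :, pt : Hp - pb or None, pl : Wp - pr or None])

    return Tensor._make(out, (x,), back)


def avg_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None) -> Tensor:
    """Non-overlapping average pooling; trailing rows/cols beyond a full
    window are dropped (floor behaviour)."""
    if stride is not None and stride != kernel:
        raise ValueError("avg_pool2d supports stride == kernel only")
    N, C, H, W = x.shape
    OH, OW = H // kernel, W // kernel
    trimmed = x.data[:, :, : OH * kernel, : OW * kernel]
    out = trimmed.reshape(N, C, OH, kernel, OW, kernel).mean(axis=(3, 5))

    def back(g):
        dx = np.zeros((N, C, H, W))
        g_exp = np.repeat(np.repeat(g, kernel, axis=2), kernel, axis=3)
        dx[:, :, : OH * kernel, : OW * kernel] = g_exp / (kernel * kernel)
        x._accumulate(dx)

    return Tensor._make(out, (x,), back)


def global_avg_pool(x: Tensor, keepdims: bool = True) -> Tensor:
    """Spatial global average pooling of an (N, C, H, W) tensor."""
    return mean(x, axis=(2, 3), keepdims=keepdims)


# -- loss --------------------------------------------------------------------


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer ``labels``."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    nll = -np.log(probs[np.arange(n), labels] + 1e-300)

    def back(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        logits._accumulate(g * d / n)

    return Tensor._make(nll.mean(), (logits,), back)
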