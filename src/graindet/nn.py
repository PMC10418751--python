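"""Minimal reverse-mode automatic differentiation engine and neural-network
layers on numpy.

Implements exactly the primitives the detector needs: 2-D convolution
(full, pointwise and depthwise), batch normalization, Swish/ReLU/Sigmoid,
linear layers, stable log-softmax, separable bilinear interpolation and
quantized ROI max pooling, plus SGD with momentum.  Float32 throughout.

Gradients flow through a recorded tape (``Tensor._parents``); a module-level
switch (:func:`no_grad`) disables recording for inference so large forward
passes allocate nothing beyond activations.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents: tuple = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * np.power(self.data, p - 1))

        return self._make(np.power(self.data, p), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accum(acc)

        return self._make(self.data[idx], (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, g))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        amax = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == amax).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(mask * g)

        out_data = amax if keepdims or axis is None else np.squeeze(amax, axis=axis)
        if axis is None:
            out_data = np.float32(self.data.max())
        return self._make(out_data, (self,), backward)

    # -- pointwise nonlinearities ----------------------------------------------
    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        return self._make(e, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def swish(self):
        """x * sigmoid(x) — the activation used throughout the backbone."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        y = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s + y * (1.0 - s)))

        return self._make(y, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    # -- linear algebra ---------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- backprop ---------------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones((), dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go
                node._backward = None
                node._parents = ()


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    soft = np.exp(out_data)

    def backward(g):
        if x.requires_grad:
            x._accum(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def smooth_l1_t(x: Tensor) -> Tensor:
    """Smooth-L1 on a tensor: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise."""
    inner = np.abs(x.data) < 1.0
    quad = (x * x) * 0.5
    lin = x.abs() - 0.5
    mask = Tensor(inner.astype(np.float32))
    return quad * mask + lin * (1.0 - mask)


# -----------------------------------------------------------------------------
# convolution primitives
# -----------------------------------------------------------------------------

def same_padding(size: int, kernel: int, stride: int) -> tuple[int, int]:
    """Asymmetric 'same' padding for ceil-division output size.

    out = ceil(size / stride); total pad = max((out-1)*stride + kernel - size, 0),
    split low/high as (total//2, total - total//2).
    """
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None,
    stride: int = 1,
    padding: tuple[int, int] | tuple[tuple[int, int], tuple[int, int]] = (0, 0),
    depthwise: bool = False,
) -> Tensor:
    """2-D convolution over NCHW input.

    ``weight`` is (O, C, kh, kw) for a full convolution, (C, 1, kh, kw) for a
    depthwise one.  ``padding`` is either symmetric (ph, pw) or explicit
    ((pt, pb), (pl, pr)).
    """
    if isinstance(padding[0], tuple):
        (pt, pb), (pl, pr) = padding
    else:
        pt = pb = padding[0]
        pl = pr = padding[1]
    n, c, h, w = x.data.shape
    kh, kw = weight.data.shape[-2:]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr))) if (pt or pb or pl or pr) else x.data
    hp, wp = xp.shape[2:]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1

    if depthwise:
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]
        out = np.einsum("nchwuv,cuv->nchw", win, weight.data[:, 0], optimize=True)
        out = np.ascontiguousarray(out, dtype=np.float32)
        if bias is not None:
            out += bias.data[None, :, None, None]

        def backward(g):
            if weight.requires_grad:
                dw = np.einsum("nchwuv,nchw->cuv", win, g, optimize=True)
                weight._accum(dw[:, None])
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for u in range(kh):
                    for v in range(kw):
                        dxp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride] += (
                            g * weight.data[None, :, 0, u, v, None, None]
                        )
                x._accum(dxp[:, :, pt : pt + h, pl : pl + w])

        parents = (x, weight) if bias is None else (x, weight, bias)
        return Tensor._make(out, parents, backward)

    o = weight.data.shape[0]
    if kh == 1 and kw == 1 and stride == 1:
        # pointwise: pure matmul
        wmat = weight.data.reshape(o, c)
        out = np.tensordot(wmat, xp, axes=([1], [1])).transpose(1, 0, 2, 3)
        out = np.ascontiguousarray(out, dtype=np.float32)
        if bias is not None:
            out += bias.data[None, :, None, None]

        def backward(g):
            if weight.requires_grad:
                dw = np.einsum("nohw,nchw->oc", g, xp, optimize=True)
                weight._accum(dw.reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxp = np.tensordot(wmat.T, g, axes=([1], [1])).transpose(1, 0, 2, 3)
                x._accum(dxp[:, :, pt : pt + h, pl : pl + w])

        parents = (x, weight) if bias is None else (x, weight, bias)
        return Tensor._make(out, parents, backward)

    # general conv via im2col
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    wmat = weight.data.reshape(o, -1)
    out = (cols @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    out = np.ascontiguousarray(out, dtype=np.float32)
    if bias is not None:
        out += bias.data[None, :, None, None]

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        if weight.requires_grad:
            weight._accum((gmat.T @ cols).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride] += (
                        dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
                    )
            x._accum(dxp[:, :, pt : pt + h, pl : pl + w])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)


def interp_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of an NCHW tensor to (out_h, out_w).

    Uses the half-pixel (align_corners=False) convention.  Linear, so the
    backward pass is the transposed interpolation.
    """
    def matrix(n_out: int, n_in: int) -> np.ndarray:
        a = np.zeros((n_out, n_in), dtype=np.float32)
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        lo = np.floor(src).astype(int)
        frac = src - lo
        lo_c = np.clip(lo, 0, n_in - 1)
        hi_c = np.clip(lo + 1, 0, n_in - 1)
        a[np.arange(n_out), lo_c] += 1.0 - frac
        a[np.arange(n_out), hi_c] += frac
        return a

    ah = matrix(out_h, x.data.shape[2])
    aw = matrix(out_w, x.data.shape[3])
    t = x.data @ aw.T
    out = np.matmul(ah, t)

    def backward(g):
        if x.requires_grad:
            x._accum(np.matmul(ah.T, g) @ aw)

    return Tensor._make(np.ascontiguousarray(out, dtype=np.float32), (x,), backward)


def roi_max_pool(feature: Tensor, rois_feat: np.ndarray, output_size: int) -> Tensor:
    """Quantized max ROI pooling on a (1, C, H, W) feature grid.

    ``rois_feat`` is (R, 4) in feature-grid coordinates (x1, y1, x2, y2),
    already projected (divided by the stride).  Each ROI is quantized to
    integer cell bounds, partitioned into ``output_size``² bins and
    max-pooled per bin; an empty bin falls back to the nearest valid cell.
    """
    f = feature.data[0]
    c, h, w = f.shape
    r = len(rois_feat)
    out = np.empty((r, c, output_size, output_size), dtype=np.float32)
    # record flat argmax positions for the backward scatter
    arg = np.empty((r, c, output_size, output_size), dtype=np.int64)
    fflat = f.reshape(c, -1)
    for ri, (x1, y1, x2, y2) in enumerate(rois_feat):
        ix1 = int(np.floor(x1))
        iy1 = int(np.floor(y1))
        ix2 = max(int(np.ceil(x2)), ix1 + 1)
        iy2 = max(int(np.ceil(y2)), iy1 + 1)
        ix1 = min(max(ix1, 0), w - 1)
        iy1 = min(max(iy1, 0), h - 1)
        ix2 = min(max(ix2, ix1 + 1), w)
        iy2 = min(max(iy2, iy1 + 1), h)
        xb = np.floor(ix1 + np.arange(output_size + 1) * (ix2 - ix1) / output_size).astype(int)
        yb = np.floor(iy1 + np.arange(output_size + 1) * (iy2 - iy1) / output_size).astype(int)
        for i in range(output_size):
            y0, y1b = yb[i], max(yb[i + 1], yb[i] + 1)
            y0 = min(y0, h - 1)
            y1b = min(max(y1b, y0 + 1), h)
            for j in range(output_size):
                x0, x1b = xb[j], max(xb[j + 1], xb[j] + 1)
                x0 = min(x0, w - 1)
                x1b = min(max(x1b, x0 + 1), w)
                cell = f[:, y0:y1b, x0:x1b].reshape(c, -1)
                am = cell.argmax(axis=1)
                out[ri, :, i, j] = cell[np.arange(c), am]
                cy = y0 + am // (x1b - x0)
                cx = x0 + am % (x1b - x0)
                arg[ri, :, i, j] = cy * w + cx

    def backward(g):
        if feature.requires_grad:
            df = np.zeros((c, h * w), dtype=np.float32)
            cidx = np.broadcast_to(
                np.arange(c)[None, :, None, None], arg.shape
            )
            np.add.at(df, (cidx.ravel(), arg.ravel()), g.ravel())
            feature._accum(df.reshape(1, c, h, w))

    return Tensor._make(out, (feature,), backward)


# -----------------------------------------------------------------------------
# layers
# -----------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        return [p for _, m in self.named_modules()
                for p in m.__dict__.values()
                if isinstance(p, Tensor) and p.requires_grad]

    def named_modules(self, prefix: str = "") -> Iterable[tuple[str, "Module"]]:
        def walk(obj, pfx):
            if isinstance(obj, Module):
                yield pfx, obj
                for k, v in obj.__dict__.items():
                    yield from walk(v, f"{pfx}{k}.")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    yield from walk(item, f"{pfx}{i}.")

        yield prefix, self
        for k, v in self.__dict__.items():
            yield from walk(v, f"{prefix}{k}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, mod in self.named_modules():
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor):
                    state[f"{name}{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    state[f"{name}{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, mod in self.named_modules():
            for k, v in mod.__dict__.items():
                key = f"{name}{k}"
                if key in state and isinstance(v, (Tensor, np.ndarray)):
                    target = v.data if isinstance(v, Tensor) else v
                    if target.shape != state[key].shape:
                        raise ValueError(
                            f"shape mismatch for {key}: {target.shape} vs {state[key].shape}"
                        )
                    target[...] = state[key]

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding="same",
        depthwise: bool = False,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.kernel = kernel
        self.padding = padding
        self.depthwise = depthwise
        if depthwise:
            if in_channels != out_channels:
                raise ValueError("depthwise conv requires in_channels == out_channels")
            shape = (out_channels, 1, kernel, kernel)
            fan_in = kernel * kernel
        else:
            shape = (out_channels, in_channels, kernel, kernel)
            fan_in = in_channels * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, shape), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if self.padding == "same":
            pad_h = same_padding(x.data.shape[2], self.kernel, self.stride)
            pad_w = same_padding(x.data.shape[3], self.kernel, self.stride)
            padding = (pad_h, pad_w)
        else:
            padding = (self.padding, self.padding)
        return conv2d(x, self.weight, self.bias, self.stride, padding, self.depthwise)


class BatchNorm2d(Module):
    """Batch normalization with running statistics (momentum 0.99, eps 1e-3)."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and _GRAD_ENABLED:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            mu = self.running_mean[None, :, None, None]
            inv = 1.0 / np.sqrt(self.running_var[None, :, None, None] + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(inv)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, std, (in_features, out_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: Sequence[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
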