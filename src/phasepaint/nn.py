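"""Minimal reverse-mode automatic differentiation and neural-network layers.

This is the compute backbone of the virtual-painting generator: a tape-based
autodiff engine over NumPy arrays with exactly the operations the
encoder--decoder architecture needs (grouped/dilated 2-D convolution via
im2col, batch/group normalization, squeeze-and-excitation gating, nearest
upsampling, dropout) plus an Adam optimizer.  It is deliberately small and
deterministic: all randomness flows through explicit ``numpy.random.Generator``
objects, and a forward pass in eval mode is a pure function of the weights.

Gradient correctness is established by finite-difference checks in the test
suite rather than trusting the closed forms.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "maximum",
    "conv2d",
    "upsample_nearest",
    "dropout",
    "Module",
    "ModuleList",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "GroupNorm2d",
    "Dropout",
    "Adam",
    "he_normal",
]

DEFAULT_DTYPE = np.float32

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


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(DEFAULT_DTYPE)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- op construction ---------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(
            p.requires_grad or p._parents for p in parents
        ):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        """Wrap a non-Tensor operand, adopting this tensor's float dtype for
        plain Python scalars so they never promote the graph to float64."""
        if isinstance(other, Tensor):
            return other
        if np.isscalar(other):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._coerce(other)
        data = self.data + other.data

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = self._coerce(other)
        data = self.data - other.data

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(-g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __mul__(self, other):
        other = self._coerce(other)
        data = self.data * other.data

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        data = self.data / other.data

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        data = self.data**exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other))
        data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.data.shape))
            other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        data = self.data * mask

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(data, (self,), backward)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * data)

        return Tensor._make(data, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        data = np.clip(self.data, lo, hi)

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(data, (self,), backward)

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for ax in sorted(a % self.data.ndim for a in axes):
                        gg = np.expand_dims(gg, ax)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(data, (self,), backward)

    def transpose(self, *axes):
        data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor._make(data, tuple(tensors), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum; on ties the gradient flows to the first input."""
    mask = a.data >= b.data
    data = np.where(mask, a.data, b.data)

    def backward(g):
        a._accumulate(_unbroadcast(g * mask, a.data.shape))
        b._accumulate(_unbroadcast(g * ~mask, b.data.shape))

    return Tensor._make(data, (a, b), backward)


# ---------------------------------------------------------------------------
# convolution (im2col)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, dil: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ekh, ekw = (kh - 1) * dil + 1, (kw - 1) * dil + 1
    oh = (x.shape[2] - ekh) // stride + 1
    ow = (x.shape[3] - ekw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (ekh, ekw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dil, ::dil][:, :, :oh, :ow]
    # (n, c, oh, ow, kh, kw) -> (n, c, kh, kw, oh, ow)
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
    return cols, oh, ow


def _col2im(dcols: np.ndarray, x_shape, stride: int, pad: int, dil: int):
    n, c, h, w = x_shape
    kh, kw, oh, ow = dcols.shape[2], dcols.shape[3], dcols.shape[4], dcols.shape[5]
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[
                :,
                :,
                i * dil : i * dil + oh * stride : stride,
                j * dil : j * dil + ow * stride : stride,
            ] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
    dilation: int = 1,
) -> Tensor:
    """Grouped, dilated 2-D cross-correlation over NCHW inputs."""
    n, c, h, w = x.data.shape
    oc, cg, kh, kw = weight.data.shape
    if c != cg * groups or oc % groups:
        raise ValueError(
            f"channel mismatch: input {c}, weight expects {cg}x{groups} groups"
        )
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding, dilation)
    k = cg * kh * kw
    colsg = cols.reshape(n, groups, k, oh * ow)
    wg = weight.data.reshape(groups, oc // groups, k)
    out = np.matmul(wg, colsg)  # (n, groups, oc/g, L)
    out = out.reshape(n, oc, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, oc, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gg = g.reshape(n, groups, oc // groups, oh * ow)
        # batched BLAS: (g, oc/g, n*L) @ (g, n*L, k)
        a = gg.transpose(1, 2, 0, 3).reshape(groups, oc // groups, n * oh * ow)
        bmat = colsg.transpose(1, 0, 3, 2).reshape(groups, n * oh * ow, k)
        weight._accumulate((a @ bmat).reshape(weight.data.shape))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        dcols = np.matmul(np.swapaxes(wg, 1, 2), gg)  # (n, g, k, L)
        dcols = dcols.reshape(n, c, kh, kw, oh, ow)
        x._accumulate(_col2im(dcols, x.data.shape, stride, padding, dilation))

    return Tensor._make(out, parents, backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.data.shape
    data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def backward(g):
        gsum = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accumulate(gsum)

    return Tensor._make(data, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; the caller decides whether it is active."""
    if p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DEFAULT_DTYPE)


class Module:
    """Base class: tracks parameters, sub-modules, buffers, and train mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, (Module, ModuleList)):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = name
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict:
        out = {}
        for k, t in self._params.items():
            out[prefix + k] = t.data
        for k in self._buffers:
            out[prefix + k] = getattr(self, k)
        for k, m in self._modules.items():
            out.update(m.state_dict(prefix + k + "."))
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for k, t in self._params.items():
            t.data = np.asarray(state[prefix + k], dtype=t.data.dtype).reshape(
                t.data.shape
            )
        for k in self._buffers:
            object.__setattr__(
                self, k, np.asarray(state[prefix + k], dtype=getattr(self, k).dtype)
            )
        for k, m in self._modules.items():
            m.load_state_dict(state, prefix + k + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList:
    def __init__(self, modules=()):
        self._list = list(modules)

    def append(self, m: Module):
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def parameters(self):
        out = []
        for m in self._list:
            out.extend(m.parameters())
        return out

    def train(self, mode=True):
        for m in self._list:
            m.train(mode)
        return self

    def state_dict(self, prefix=""):
        out = {}
        for i, m in enumerate(self._list):
            out.update(m.state_dict(f"{prefix}{i}."))
        return out

    def load_state_dict(self, state, prefix=""):
        for i, m in enumerate(self._list):
            m.load_state_dict(state, f"{prefix}{i}.")


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.stride, self.padding, self.groups, self.dilation = (
            stride,
            padding,
            groups,
            dilation,
        )
        self.weight = Tensor(
            he_normal(
                rng,
                (out_channels, in_channels // groups, kernel_size, kernel_size),
                fan_in,
            ),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=DEFAULT_DTYPE), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            groups=self.groups,
            dilation=self.dilation,
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Tensor(
            he_normal(rng, (in_features, out_features), in_features),
            requires_grad=True,
        )
        self.bias = Tensor(
            np.zeros(out_features, dtype=DEFAULT_DTYPE), requires_grad=True
        )

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) with running statistics for eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones((1, channels, 1, 1), DEFAULT_DTYPE), True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), DEFAULT_DTYPE), True)
        self.register_buffer("running_mean", np.zeros((1, channels, 1, 1), np.float64))
        self.register_buffer("running_var", np.ones((1, channels, 1, 1), np.float64))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.astype(x.data.dtype))
            var = Tensor(self.running_var.astype(x.data.dtype))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class GroupNorm2d(Module):
    """Group normalization; batch-size independent (small-batch alternative)."""

    def __init__(self, channels: int, num_groups: int = 8, eps: float = 1e-5):
        super().__init__()
        while channels % num_groups:
            num_groups -= 1
        self.num_groups, self.eps = num_groups, eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), DEFAULT_DTYPE), True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), DEFAULT_DTYPE), True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.num_groups
        xg = x.reshape(n, g, c // g, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=(2, 3, 4), keepdims=True)
        xhat = ((xg - mu) * ((var + self.eps) ** -0.5)).reshape(n, c, h, w)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        return dropout(x, self.p, self.rng)


class Adam:
    """Adam optimizer with in-place parameter updates."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
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
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
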