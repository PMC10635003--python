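"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the segmentation networks and losses need:
elementwise arithmetic with broadcasting, reductions, ReLU, 2-D convolution
(im2col), 2x2 max pooling, nearest-neighbour upsampling, channel
concatenation/slicing and a channel softmax, plus small ``Module``/optimizer
machinery. Gradients are checked against finite differences in the test
suite.

All data is float32. A :class:`Tensor` wraps an ndarray; operations build a
tape that :meth:`Tensor.backward` unwinds in reverse topological order.
``detach`` implements the stop-gradient used for pseudo-labels.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "concat",
    "softmax",
    "conv2d",
    "max_pool2x2",
    "upsample_nearest2x",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Adam",
]


def _f32(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim and not arr.flags.c_contiguous:
        arr = np.ascontiguousarray(arr)
    return arr


_GRAD_ENABLED = True


class no_grad:
    """Context manager that suppresses tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """An ndarray plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _op(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if not _GRAD_ENABLED:
            return out
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        """A view of the same data cut off from the tape (stop-gradient)."""
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------

    def backward(self, grad=None):
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
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
        self.grad = _f32(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go; leaf grads survive
                node._backward = None
                node._parents = ()

    def _accumulate(self, grad: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic (broadcasting) --------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        return Tensor._op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._op(self.data * mask, (self,), backward)

    # -- reductions ------------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).astype(np.float32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, shape).astype(np.float32))

        return Tensor._op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shaping ----------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._accumulate(g.reshape(orig))

        return Tensor._op(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=np.float32)
            full[idx] = g
            self._accumulate(full)

        return Tensor._op(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# -- structural ops -------------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    return Tensor._op(out_data, tensors, backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        x._accumulate(p * (g - dot))

    return Tensor._op(p, (x,), backward)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 1,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel.

    Internally uses channels-last im2col assembled from per-offset block
    copies (one per kernel tap) — much faster in numpy than a generic strided
    gather — followed by a single GEMM.
    """
    B, C, H, W = x.data.shape
    Co, Ci, kh, kw = weight.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    s = stride
    # channels-last padded input
    xp = np.empty(
        (B, H + 2 * padding, W + 2 * padding, C), dtype=np.float32
    )
    if padding:
        xp[:] = 0.0
        xp[:, padding:-padding, padding:-padding, :] = x.data.transpose(0, 2, 3, 1)
    else:
        xp[:] = x.data.transpose(0, 2, 3, 1)
    Hp, Wp = xp.shape[1], xp.shape[2]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    col = np.empty((B, Ho, Wo, kh, kw, C), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            col[:, :, :, i, j, :] = xp[:, i : i + s * Ho : s, j : j + s * Wo : s, :]
    col = col.reshape(B * Ho * Wo, kh * kw * C)
    # weight as (Co, kh*kw*C) in the same tap-major layout
    Wm = np.ascontiguousarray(weight.data.transpose(0, 2, 3, 1)).reshape(
        Co, kh * kw * C
    )
    out = col @ Wm.T
    if bias is not None:
        out += bias.data
    out_data = np.ascontiguousarray(
        out.reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2)
    )

    def backward(g):
        gcol = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, Co)
        if weight.requires_grad:
            dW = (gcol.T @ col).reshape(Co, kh, kw, C)
            weight._accumulate(np.ascontiguousarray(dW.transpose(0, 3, 1, 2)))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = (gcol @ Wm).reshape(B, Ho, Wo, kh, kw, C)
            dxp = np.zeros((B, Hp, Wp, C), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + s * Ho : s, j : j + s * Wo : s, :] += dcol[
                        :, :, :, i, j, :
                    ]
            if padding:
                dxp = dxp[:, padding:-padding, padding:-padding, :]
            x._accumulate(np.ascontiguousarray(dxp.transpose(0, 3, 1, 2)))

    return Tensor._op(out_data, (x, weight, bias), backward)


def max_pool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2x2 needs even spatial dims, got {H}x{W}")
    v = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = np.ascontiguousarray(v).reshape(B, C, H // 2, W // 2, 4)
    idx = v.argmax(axis=-1)
    out_data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dv = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
        dv = dv.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dv.reshape(B, C, H, W))

    return Tensor._op(out_data, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        x._accumulate(
            g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)).astype(np.float32)
        )

    return Tensor._op(out_data, (x,), backward)


# -- modules --------------------------------------------------------------------


class Module:
    """Tiny module system: parameter discovery, train/eval flag, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Tensor):
                    state[f"{i}.{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    state[f"{i}.{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                key = f"{i}.{k}"
                if key not in state:
                    continue
                if isinstance(v, Tensor):
                    v.data = _f32(state[key])
                elif isinstance(v, np.ndarray):
                    setattr(m, k, np.asarray(state[key]))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
        bias: bool = True,
    ):
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))  # He initialisation for ReLU nets
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch statistics in training mode, running averages in eval mode.

    Implemented as one fused op (single forward pass, analytic backward)
    rather than a chain of elementwise primitives — batch norm sits in every
    block, so this is the second-hottest path after convolution.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.update_stats = True  # trainers may freeze stats on auxiliary batches
        self.gamma = Tensor(np.ones((1, n_ch, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n_ch, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, n_ch, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, n_ch, 1, 1), dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            if self.update_stats:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mu
                self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * ivar
        out_data = gamma.data * xhat + beta.data
        use_batch_stats = self.training
        n = x.data.size // x.data.shape[1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes, keepdims=True))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes, keepdims=True))
            if x.requires_grad:
                dxhat = g * gamma.data
                if use_batch_stats:
                    # batch statistics depend on x: full batch-norm backward
                    s1 = dxhat.sum(axis=axes, keepdims=True)
                    s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                    x._accumulate(ivar * (dxhat - (s1 + xhat * s2) / n))
                else:
                    x._accumulate(dxhat * ivar)

        return Tensor._op(out_data, (x, gamma, beta), backward)


class Adam:
    """Adam with the standard bias correction."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
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

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float32) for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float32) for v in state["v"]]
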