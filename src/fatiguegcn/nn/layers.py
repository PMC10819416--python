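"""Layers with explicit forward/backward passes.

Shapes follow the batch-first convention: Dense acts on the last axis,
Conv1d on (batch, channels, length), ChebGraphConv on
(batch, nodes, features). ``backward`` consumes the upstream gradient,
accumulates parameter gradients, and returns the input gradient.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Parameter", "Module", "Sequential", "Dense", "Conv1d", "Resize1d", "Reshape",
    "Flatten", "ReLU", "LeakyReLU", "Sigmoid", "Dropout", "BatchNorm1d", "ChebGraphConv",
]


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter({self.name}, shape={self.value.shape})"


class Module:
    def __init__(self) -> None:
        self.training = True
        self._params: list[Parameter] = []
        self._children: list[Module] = []

    def register(self, param: Parameter) -> Parameter:
        self._params.append(param)
        return param

    def add_child(self, module: "Module") -> "Module":
        self._children.append(module)
        return module

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for child in self._children:
            out.extend(child.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for child in self._children:
            child.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, values: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(values) != len(params):
            raise ValueError("state length mismatch")
        for p, v in zip(params, values):
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value[...] = v

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        super().__init__()
        self.modules = list(modules)
        for m in self.modules:
            self.add_child(m)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad


class Dense(Module):
    """Affine map on the last axis; He-scaled Gaussian init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init_scale: float | None = None, name: str = "dense") -> None:
        super().__init__()
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / in_features)
        self.W = self.register(
            Parameter(rng.normal(0.0, scale, size=(in_features, out_features)), f"{name}.W")
        )
        self.b = self.register(Parameter(np.zeros(out_features), f"{name}.b"))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.W.value.shape[0]:
            raise ValueError(
                f"feature-length mismatch: got {x.shape[-1]}, expected {self.W.value.shape[0]}"
            )
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        xf = x.reshape(-1, x.shape[-1])
        gf = grad.reshape(-1, grad.shape[-1])
        self.W.grad += xf.T @ gf
        self.b.grad += gf.sum(axis=0)
        return grad @ self.W.value.T


class Conv1d(Module):
    """Same-padded 1-D convolution (odd kernel, stride 1) via sliding windows."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, name: str = "conv") -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.W = self.register(Parameter(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size)), f"{name}.W"))
        self.b = self.register(Parameter(np.zeros(out_channels), f"{name}.b"))
        self.k = kernel_size
        self._view: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.W.value.shape[1]:
            raise ValueError("expected (batch, in_channels, length)")
        p = self.k // 2
        self._in_len = x.shape[2]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        view = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        self._view = view  # (B, Cin, L, k)
        return np.einsum("bclt,oct->bol", view, self.W.value, optimize=True) + self.b.value[:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, p, L = self.k, self.k // 2, self._in_len
        self.W.grad += np.einsum("bclt,bol->oct", self._view, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        gpad = np.pad(grad, ((0, 0), (0, 0), (k - 1, k - 1)))
        gview = np.lib.stride_tricks.sliding_window_view(gpad, k, axis=2)
        Wf = self.W.value[:, :, ::-1]
        dxp = np.einsum("bomt,oct->bcm", gview, Wf, optimize=True)  # (B, Cin, L + k - 1)
        return dxp[:, :, p : p + L]


class Resize1d(Module):
    """Linear-interpolation resize along the last axis (a fixed linear map)."""

    def __init__(self, in_len: int, out_len: int) -> None:
        super().__init__()
        pos = np.linspace(0.0, in_len - 1, out_len)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, in_len - 1)
        w = pos - lo
        M = np.zeros((out_len, in_len))
        M[np.arange(out_len), lo] += 1.0 - w
        M[np.arange(out_len), hi] += w
        self.M = M

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.M.T

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad @ self.M


class Reshape(Module):
    """Reshape the non-batch axes."""

    def __init__(self, shape: Sequence[int]) -> None:
        super().__init__()
        self.shape = tuple(shape)
        self._in_shape: tuple[int, ...] = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Flatten(Module):
    def __init__(self) -> None:
        super().__init__()
        self._in_shape: tuple[int, ...] = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01) -> None:
        super().__init__()
        self.slope = negative_slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(0.0)


class Sigmoid(Module):
    def __init__(self) -> None:
        super().__init__()
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class BatchNorm1d(Module):
    """Batch normalization over the trailing feature axis.

    Accepts (batch, features) or (batch, nodes, features); statistics pool
    over every non-feature axis. Running statistics feed inference mode.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        super().__init__()
        self.gamma = self.register(Parameter(np.ones(num_features), f"{name}.gamma"))
        self.beta = self.register(Parameter(np.zeros(num_features), f"{name}.beta"))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        shape = x.shape
        xf = x.reshape(-1, shape[-1])
        if self.training:
            mean = xf.mean(axis=0)
            var = xf.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (xf - mean) * ivar
        self._cache = (xhat, ivar, shape)
        return (self.gamma.value * xhat + self.beta.value).reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, ivar, shape = self._cache
        gf = grad.reshape(-1, shape[-1])
        m = gf.shape[0]
        self.gamma.grad += (gf * xhat).sum(axis=0)
        self.beta.grad += gf.sum(axis=0)
        if not self.training:
            return (gf * self.gamma.value * ivar).reshape(shape)
        dxhat = gf * self.gamma.value
        dx = (ivar / m) * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        return dx.reshape(shape)


class ChebGraphConv(Module):
    """Chebyshev spectral graph convolution.

    Given precomputed polynomial matrices T_k(L~) of the scaled Laplacian,
    maps node features X (batch, nodes, in) to
    sum_k T_k(L~) X W_k + b, with W of shape (K, in, out).
    """

    def __init__(self, cheb_mats: np.ndarray, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str = "cheb") -> None:
        super().__init__()
        self.T = np.asarray(cheb_mats, dtype=float)  # (K, n, n)
        if self.T.ndim != 3 or self.T.shape[1] != self.T.shape[2]:
            raise ValueError("cheb_mats must be (K, n, n)")
        K = self.T.shape[0]
        scale = np.sqrt(2.0 / (K * in_features))
        self.W = self.register(Parameter(
            rng.normal(0.0, scale, size=(K, in_features, out_features)), f"{name}.W"))
        self.b = self.register(Parameter(np.zeros(out_features), f"{name}.b"))
        self._TX: np.ndarray | None = None

    @property
    def cheb_order(self) -> int:
        return self.T.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.T.shape[1]:
            raise ValueError(f"expected (batch, {self.T.shape[1]} nodes, features)")
        if x.shape[2] != self.W.value.shape[1]:
            raise ValueError(
                f"feature-length mismatch: got {x.shape[2]}, expected {self.W.value.shape[1]}"
            )
        self._TX = np.einsum("kij,bjf->kbif", self.T, x, optimize=True)
        return np.einsum("kbif,kfo->bio", self._TX, self.W.value, optimize=True) + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += np.einsum("kbif,bio->kfo", self._TX, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 1))
        G = np.einsum("bio,kfo->kbif", grad, self.W.value, optimize=True)
        return np.einsum("kji,kbjf->bif", self.T, G, optimize=True)
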