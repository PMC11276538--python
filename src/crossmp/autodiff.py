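"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the translation network needs: broadcasted
arithmetic, matmul, the activations (ReLU, PReLU, sigmoid, softplus, exp,
log), lgamma for count likelihoods, reductions, concatenation and column
slicing — plus the layers (Linear, BatchNorm1d, PReLU) and an Adam optimizer.
Everything is float64 and single-threaded numpy, so runs are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.special import digamma, gammaln

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "Linear",
    "BatchNorm1d",
    "PReLU",
    "Adam",
    "clip_grad_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / (other.data**2))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out_data = self.data**e

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = g
                self._accumulate(full)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- elementwise functions ------------------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def softplus(self) -> "Tensor":
        out_data = np.logaddexp(0.0, self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / (1.0 + np.exp(-self.data)))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def lgamma(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * digamma(self.data))

        return Tensor(gammaln(self.data), _parents=(self,), _backward=bwd)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only where the input is inside the range."""
        inside = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * inside)

        return Tensor(np.clip(self.data, lo, hi), _parents=(self,), _backward=bwd)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """PReLU with a learnable scalar slope for the negative part."""
    pos = x.data > 0
    out_data = np.where(pos, x.data, slope.data * x.data)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * np.where(pos, 1.0, slope.data))
        if slope.requires_grad:
            slope._accumulate(np.sum(g * np.where(pos, 0.0, x.data)))

    return Tensor(out_data, _parents=(x, slope), _backward=bwd)


# ---------------------------------------------------------------------------
# layers


class Module:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(mode)

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers, for checkpointing."""
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[key] = v.data
            elif isinstance(v, Module):
                out.update(v.state_arrays(f"{key}."))
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                out[key] = v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{key}.{i}."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                v.data = np.array(state[key], dtype=np.float64)
            elif isinstance(v, Module):
                v.load_state_arrays(state, f"{key}.")
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                setattr(self, name, np.array(state[key], dtype=np.float64))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{key}.{i}.")


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in) if n_in > 0 else 1.0
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class PReLU(Module):
    def __init__(self, init: float = 0.25):
        self.slope = Parameter(np.asarray(init))

    def __call__(self, x: Tensor) -> Tensor:
        return prelu(x, self.slope)


class BatchNorm1d(Module):
    """Feature-wise batch normalisation with running statistics for inference."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.data.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.ravel()
            )
            n = x.data.shape[0]
            unbiased = var.data.ravel() * n / max(n - 1, 1)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            norm = centred / (var + self.eps).sqrt()
        else:
            norm = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return norm * self.gamma + self.beta


# ---------------------------------------------------------------------------
# optimisation


class Adam:
    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 0.01,
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

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grad_norm(params: Iterable[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad**2).sum()) for p in params)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad = p.grad * scale
    return total
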