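"""Minimal reverse-mode automatic differentiation and neural-network layers.

All trainable components of the pipeline (the gated-attention MIL heads, the
nested variant, the contrastive projection heads and the focal Tversky
training loss) are differentiable graphs built from the small :class:`Tensor`
type defined here.  The design is deliberately tiny: dense arrays, a handful
of vectorised ops with broadcasting, topological-order backpropagation, and
two optimizers (SGD, Adam).  Gradients are verified against central finite
differences in the test suite.

Everything is deterministic given the numpy ``Generator`` objects passed in;
no global random state is touched.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack_rows",
    "Module",
    "Linear",
    "MLP",
    "Dropout",
    "SGD",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers ------------------------------------------------
    @classmethod
    def _op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        return Tensor._op(self.data.T, (self,), lambda g: (g.T,))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(grad):
            return _unbroadcast(grad, a.data.shape), _unbroadcast(grad, b.data.shape)

        return Tensor._op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(grad):
            return (
                _unbroadcast(grad * b.data, a.data.shape),
                _unbroadcast(grad * a.data, b.data.shape),
            )

        return Tensor._op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(grad):
            return (
                _unbroadcast(grad / b.data, a.data.shape),
                _unbroadcast(-grad * a.data / (b.data**2), b.data.shape),
            )

        return Tensor._op(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def backward(grad):
            base = a.data
            # Subgradient 0 where the power is not differentiable (base == 0,
            # p < 1); keeps focal exponents finite at exact optima.
            with np.errstate(divide="ignore", invalid="ignore"):
                d = p * base ** (p - 1.0)
            d = np.where(np.isfinite(d), d, 0.0)
            return (grad * d,)

        return Tensor._op(a.data**p, (a,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(grad):
            ga = grad @ b.data.T if b.data.ndim > 1 else np.outer(grad, b.data)
            gb = a.data.T @ grad
            return ga, gb

        return Tensor._op(a.data @ b.data, (a, b), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._op(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )
        return Tensor._op(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def relu(self):
        mask = self.data > 0
        return Tensor._op(self.data * mask, (self,), lambda g: (g * mask,))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        a = self
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            m = out_data
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
                m = np.expand_dims(m, axis)
            mask = (a.data == m).astype(a.data.dtype)
            mask /= mask.sum(axis=axis, keepdims=True)
            return (mask * g,)

        return Tensor._op(out_data, (a,), backward)

    def logsumexp(self, axis=-1, keepdims: bool = False):
        """Numerically stable log-sum-exp along ``axis`` (exact at one term)."""
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        shifted = np.exp(a.data - m)
        s = shifted.sum(axis=axis, keepdims=True)
        out_data = np.log(s) + m
        soft = shifted / s  # softmax, reused in backward

        def backward(grad):
            g = np.asarray(grad)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (soft * g,)

        return Tensor._op(
            out_data if keepdims else np.squeeze(out_data, axis=axis), (a,), backward
        )

    def softmax(self, axis=-1):
        return (self - self.logsumexp(axis=axis, keepdims=True)).exp()

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        return Tensor._op(
            self.data.reshape(*shape), (a,), lambda g: (g.reshape(a.data.shape),)
        )

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf: accumulate into .grad
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = np.asarray(pg) if key not in grads else grads[key] + pg


def concat(tensors: list, axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        return tuple(np.split(grad, splits, axis=axis))

    return Tensor._op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def stack_rows(scalars: list) -> Tensor:
    """Stack scalar (or (1,1)) tensors into a flat vector."""
    return concat([s.reshape(1) for s in scalars], axis=0)


# ---------------------------------------------------------------------------
# layers


class Module:
    """Base class: anything with trainable :class:`Tensor` parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    """Dense layer ``x @ W + b`` with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(
            rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    """Inverted dropout; active only when called with ``training=True``."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator | None = None) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class MLP(Module):
    """Fully connected stack with ReLU hidden activations.

    ``sizes`` lists every layer width including input and output; dropout (if
    any) is applied after each hidden activation, mirroring the classifier
    head used throughout the MIL models.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 dropout: float = 0.0, dtype=np.float64):
        self.layers = [
            Linear(a, b, rng, dtype=dtype) for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.dropout = Dropout(dropout)

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        for layer in self.layers[:-1]:
            x = self.dropout(layer(x).relu(), training, rng)
        return self.layers[-1](x)


# ---------------------------------------------------------------------------
# optimizers


class SGD:
    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            if self.momentum:
                v *= self.momentum
                v += p.grad
                p.data = p.data - self.lr * v
            else:
                p.data = p.data - self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self._t)
            vhat = v / (1 - self.b2**self._t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
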