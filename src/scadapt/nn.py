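"""A compact CPU neural-network layer: linear maps with optional spectral
normalization, batch normalization, trainable-slope Swish, residual blocks,
and Adam — with explicit forward/backward passes so input gradients (needed
for path-integral attribution) are exact.

Shapes follow the (batch, features) convention throughout.  Every layer
caches what its backward pass needs during forward; ``backward`` returns
the gradient with respect to the layer input and accumulates parameter
gradients on ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Linear", "BatchNorm", "Swish", "ResidualBlock",
           "Sequential", "Adam", "swish"]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def swish(x: np.ndarray, alpha: float | np.ndarray = 1.0) -> np.ndarray:
    """Swish activation x * sigmoid(alpha * x), stable for large |alpha*x|."""
    x = np.asarray(x, dtype=float)
    ax = np.clip(alpha * x, -500, 500)
    return x / (1.0 + np.exp(-ax))


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(t, -500, 500)))


class Layer:
    trainable: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays needed to restore the layer (params + buffers)."""
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray], offset: int = 0) -> int:
        for p in self.params():
            p.value = np.array(arrays[offset], dtype=float).reshape(p.value.shape)
            offset += 1
        return offset


class Linear(Layer):
    """y = x W^T + b, optionally spectrally normalized.

    Spectral normalization rescales W by its leading singular value,
    estimated by one power-iteration step per training forward (the
    estimate is treated as a constant in the backward pass).
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 spectral_norm: bool = False, bias: bool = True):
        scale = np.sqrt(2.0 / in_dim)
        self.W = Param(rng.standard_normal((out_dim, in_dim)) * scale)
        self.b = Param(np.zeros(out_dim)) if bias else None
        self.spectral_norm = spectral_norm
        self._u = rng.standard_normal(out_dim)
        self._u /= np.linalg.norm(self._u) + 1e-12
        self._x: np.ndarray | None = None
        self._sigma = 1.0

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def effective_weight(self, update_power_iter: bool = False) -> np.ndarray:
        if not self.spectral_norm:
            return self.W.value
        W = self.W.value
        u = self._u
        sigma_prev = 0.0
        for _ in range(100):  # iterate to convergence; cheap at these sizes
            v = W.T @ u
            v /= np.linalg.norm(v) + 1e-12
            u = W @ v
            u /= np.linalg.norm(u) + 1e-12
            sigma = float(u @ W @ v)
            if abs(sigma - sigma_prev) <= 1e-9 * max(abs(sigma), 1e-12):
                break
            sigma_prev = sigma
        if update_power_iter:
            self._u = u
        self._sigma = max(abs(sigma), 1e-12)
        return W / self._sigma

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        Weff = self.effective_weight(update_power_iter=training)
        self._x = x
        y = x @ Weff.T
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        Weff = self.W.value / self._sigma if self.spectral_norm else self.W.value
        # sigma treated as a detached constant
        gW = grad_out.T @ self._x
        if self.spectral_norm:
            gW /= self._sigma
        self.W.grad += gW
        if self.b is not None:
            self.b.grad += grad_out.sum(axis=0)
        return grad_out @ Weff

    def state_arrays(self) -> list[np.ndarray]:
        return super().state_arrays() + [self._u]

    def load_state_arrays(self, arrays, offset: int = 0) -> int:
        offset = super().load_state_arrays(arrays, offset)
        self._u = np.array(arrays[offset], dtype=float)
        return offset + 1


class BatchNorm(Layer):
    """1-D batch normalization with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, training, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, n = self._cache
        self.gamma.grad += (grad_out * xhat).sum(axis=0)
        self.beta.grad += grad_out.sum(axis=0)
        g = grad_out * self.gamma.value
        if not training:
            return g * inv_std
        # full batch-stat backward
        return (inv_std / n) * (n * g - g.sum(axis=0) - xhat * (g * xhat).sum(axis=0))

    def state_arrays(self) -> list[np.ndarray]:
        return super().state_arrays() + [self.running_mean, self.running_var]

    def load_state_arrays(self, arrays, offset: int = 0) -> int:
        offset = super().load_state_arrays(arrays, offset)
        self.running_mean = np.array(arrays[offset], dtype=float)
        self.running_var = np.array(arrays[offset + 1], dtype=float)
        return offset + 2


class Swish(Layer):
    """Swish with one trainable slope alpha per layer (initialized 1)."""

    def __init__(self, alpha_init: float = 1.0):
        self.alpha = Param(np.array(alpha_init, dtype=float))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.alpha]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        a = float(self.alpha.value)
        s = _sigmoid(a * x)
        self._cache = (x, s, a)
        return x * s

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, s, a = self._cache
        dyda = x * x * s * (1 - s)
        self.alpha.grad += float((grad_out * dyda).sum())
        return grad_out * (s + a * x * s * (1 - s))


class ResidualBlock(Layer):
    """Linear -> (spectral norm) -> batch norm -> Swish, plus a shortcut.

    The shortcut is the identity when input and output widths match;
    otherwise it is a batch-norm followed by a linear map with no
    activation (dimension-adaptive shortcut).
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 spectral_norm: bool = False, alpha_init: float = 1.0):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.fc = Linear(in_dim, out_dim, rng, spectral_norm=spectral_norm)
        self.bn = BatchNorm(out_dim)
        self.act = Swish(alpha_init)
        if in_dim == out_dim:
            self.shortcut_bn = None
            self.shortcut_fc = None
        else:
            self.shortcut_bn = BatchNorm(in_dim)
            self.shortcut_fc = Linear(in_dim, out_dim, rng, spectral_norm=spectral_norm)

    def params(self) -> list[Param]:
        ps = self.fc.params() + self.bn.params() + self.act.params()
        if self.shortcut_fc is not None:
            ps += self.shortcut_bn.params() + self.shortcut_fc.params()
        return ps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        main = self.act.forward(self.bn.forward(self.fc.forward(x, training), training), training)
        if self.shortcut_fc is None:
            short = x
        else:
            short = self.shortcut_fc.forward(self.shortcut_bn.forward(x, training), training)
        return main + short

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g_main = self.fc.backward(self.bn.backward(self.act.backward(grad_out)))
        if self.shortcut_fc is None:
            g_short = grad_out
        else:
            g_short = self.shortcut_bn.backward(self.shortcut_fc.backward(grad_out))
        return g_main + g_short

    def _children(self) -> list[Layer]:
        kids = [self.fc, self.bn, self.act]
        if self.shortcut_fc is not None:
            kids += [self.shortcut_bn, self.shortcut_fc]
        return kids

    def state_arrays(self) -> list[np.ndarray]:
        return [a for child in self._children() for a in child.state_arrays()]

    def load_state_arrays(self, arrays, offset: int = 0) -> int:
        for child in self._children():
            offset = child.load_state_arrays(arrays, offset)
        return offset


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def state_arrays(self) -> list[np.ndarray]:
        return [a for layer in self.layers for a in layer.state_arrays()]

    def load_state_arrays(self, arrays, offset: int = 0) -> int:
        for layer in self.layers:
            offset = layer.load_state_arrays(arrays, offset)
        return offset


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
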