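"""Neural building blocks on top of :mod:`picaso.autodiff`.

Keeps to the conventions of mainstream deep-learning toolkits: a ``Module``
owns named ``Parameter`` leaves (collected recursively), ``Linear`` and
``LayerNorm`` are the dense primitives, and ``Adam`` implements the usual
bias-corrected first/second-moment update.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Adam",
    "kaiming_normal",
    "bce_with_logits",
]


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                   dtype=np.float32) -> np.ndarray:
    """Zero-mean Gaussian with variance 2/fan_in (He initialisation)."""
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: children and parameters are discovered via attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, out: list[Parameter], seen: set[int]) -> None:
        for value in vars(self).values():
            self._visit(value, out, seen)

    @staticmethod
    def _visit(value, out, seen):
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                out.append(value)
        elif isinstance(value, Module):
            value._collect(out, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._visit(v, out, seen)
        elif isinstance(value, dict):
            for v in value.values():
                Module._visit(v, out, seen)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # ------------------------------------------------------------ checkpoints
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint holds {len(state)} arrays, model has {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.astype(p.data.dtype)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as f:
            self.load_state_dict({k: f[k] for k in f.files})


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 bias: bool = True):
        self.w = Parameter(kaiming_normal(rng, (d_in, d_out), fan_in=d_in))
        self.b = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable binary cross entropy on raw logits.

    Uses log(1+exp(-|z|)) + max(z,0) - z*y, averaged over all elements.
    """
    t = np.asarray(targets, dtype=np.float64)
    z = logits
    zpos = z.relu()
    # log(1 + exp(-|z|)) computed via softplus of -|z|
    absz = z.abs()
    log_term = (1.0 + (-absz).exp()).log()
    loss = zpos - z * t + log_term
    return loss.mean()
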