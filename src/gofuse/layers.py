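"""Neural-network building blocks on top of the autodiff engine.

Conventions: activations operate on ``(L, channels)`` matrices where L is the
number of residues. Weights are float32 by default and initialized
Glorot-uniform from an explicit ``numpy.random.Generator`` so runs are
reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    """Tiny container: tracks named parameters, supports nesting."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out[name] = value
            elif isinstance(value, Module):
                for sub, p in value.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for k, p in params.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)


class Linear(Module):
    """Affine map applied row-wise: (L, d_in) -> (L, d_out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Tensor(glorot_uniform(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Conv1dSame(Module):
    """1-D convolution over the residue axis with 'same' zero padding.

    Implemented as a sum of k shifted matmuls over a zero-padded input:
    out[i] = b + sum_t x_pad[i + t] @ W[t], which for odd k and pad (k-1)/2
    matches a standard cross-correlation preserving the sequence length.
    """

    def __init__(self, d_in: int, d_out: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"kernel must be a positive odd integer, got {kernel}")
        self.kernel = kernel
        fan_in = d_in * kernel
        full = glorot_uniform(rng, fan_in, d_out, shape=(kernel, d_in, d_out))
        # one tensor per tap: gradients accumulate tap-locally without
        # materializing a full (k, d_in, d_out) zero buffer per tap
        self.taps = [Tensor(full[t].copy(), requires_grad=True) for t in range(kernel)]
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True) if bias else None

    def parameters(self) -> dict[str, Tensor]:
        out = {f"W{t}": w for t, w in enumerate(self.taps)}
        if self.b is not None:
            out["b"] = self.b
        return out

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[0]
        half = (self.kernel - 1) // 2
        xpad = x.pad_rows(half, half)
        out = None
        for t, w in enumerate(self.taps):
            term = xpad[t : t + L] @ w
            out = term if out is None else out + term
        if self.b is not None:
            out = out + self.b
        return out


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8), no weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits, numerically stable.

    Uses max(z,0) - z*y + log(1 + exp(-|z|)), the standard stable form.
    """
    y = np.asarray(targets, dtype=logits.dtype)
    pos = logits.relu()
    soft = ((logits.abs() * -1.0).exp() + 1.0).log()
    return (pos - logits * Tensor(y) + soft).mean()


def sigmoid_np(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))
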