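"""Network building blocks on top of the autodiff engine.

Linear layers, a GRU cell, a same-length 1-D convolution, an MLP head and
the Adam optimizer.  Weights are initialized with a uniform fan-in scheme,
U(-1/sqrt(fan_in), 1/sqrt(fan_in)), from an explicit NumPy generator so every
model build is reproducible from its seed.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: collects parameters from attributes, recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj) -> None:
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            p.data = arr.copy()


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    """Affine map y = x W + b."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = uniform_init(rng, (in_features, out_features), in_features)
        self.bias = uniform_init(rng, (out_features,), in_features)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GRUCell(Module):
    """Gated recurrent unit: h' = (1-z)*n + z*h with update/reset gates."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.w_z = Linear(input_size + hidden_size, hidden_size, rng)
        self.w_r = Linear(input_size + hidden_size, hidden_size, rng)
        self.w_n = Linear(input_size + hidden_size, hidden_size, rng)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        xh = ad.concat([x, h], axis=-1)
        z = ad.sigmoid(self.w_z(xh))
        r = ad.sigmoid(self.w_r(xh))
        n = ad.tanh(self.w_n(ad.concat([x, r * h], axis=-1)))
        return (1.0 - z) * n + z * h


class MLPHead(Module):
    """One hidden layer (ReLU) and a sigmoid output layer."""

    def __init__(self, in_features: int, hidden: int, out_features: int, rng: np.random.Generator):
        self.fc1 = Linear(in_features, hidden, rng)
        self.fc2 = Linear(hidden, out_features, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.sigmoid(self.fc2(ad.relu(self.fc1(x))))


class Conv1dSame(Module):
    """1-D convolution over (batch, length, channels) with 'same' padding.

    Odd kernel size h, stride 1, zero padding (h-1)/2 on both ends, so the
    output length always equals the input length.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError(
                f"kernel size must be odd for same-length padding, got {kernel_size}"
            )
        self.kernel_size = kernel_size
        self.weight = uniform_init(
            rng, (kernel_size * in_channels, out_channels), kernel_size * in_channels
        )
        self.bias = uniform_init(rng, (out_channels,), kernel_size * in_channels)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.kernel_size
        p = (h - 1) // 2
        B, L, C = x.data.shape
        xp = np.pad(x.data, ((0, 0), (p, p), (0, 0)))
        cols = np.stack([xp[:, i : i + L, :] for i in range(h)], axis=2)  # B,L,h,C
        cols2 = cols.reshape(B, L, h * C)
        w, b = self.weight, self.bias
        out_data = cols2 @ w.data + b.data

        x_, self_h, self_p = x, h, p

        def bw(g: np.ndarray) -> None:
            if w.requires_grad:
                w._accumulate(np.einsum("blk,blo->ko", cols2, g))
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 1)))
            if x_.requires_grad:
                dcols = (g @ w.data.T).reshape(B, L, self_h, C)
                dxp = np.zeros_like(xp)
                for i in range(self_h):
                    dxp[:, i : i + L, :] += dcols[:, :, i, :]
                x_._accumulate(dxp[:, self_p : self_p + L, :])

        return Tensor(out_data, parents=(x, w, b), backward=bw)


class Adam:
    """Adaptive-moment estimation optimizer (standard bias correction)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
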