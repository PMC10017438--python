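"""Neural-network layers and the AdamW optimizer on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import DTYPE, Tensor


class Module:
    """Parameter container with recursive state-dict traversal."""

    def parameters(self) -> list[Tensor]:
        return list(self.state_dict().values())

    def state_dict(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor):
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.state_dict(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.state_dict(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item
        return out

    def load_state_dict(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.state_dict()
        missing = set(params) - set(arrays)
        extra = set(arrays) - set(params)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in params.items():
            arr = np.asarray(arrays[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape).astype(DTYPE), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = _param(rng, (n_in, n_out), n_in)
        self.bias = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.stride = stride
        self.padding = kernel // 2
        self.weight = _param(rng, (c_out, c_in, kernel), c_in * kernel)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def state_dict(self, prefix: str = "") -> dict[str, Tensor]:
        return {f"{prefix}weight": self.weight, f"{prefix}bias": self.bias}

    def __call__(self, x) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias, self.stride, self.padding)


class ResBlock1d(Module):
    """Two k-sized convolutions with a skip connection (pre-activation omitted).

    When `stride > 1` or the channel count changes, the skip path is a
    1x1 strided convolution.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1d(c_in, c_out, kernel, stride, rng)
        self.conv2 = Conv1d(c_out, c_out, kernel, 1, rng)
        self.skip = (
            Conv1d(c_in, c_out, 1, stride, rng)
            if (stride != 1 or c_in != c_out) else None
        )

    def state_dict(self, prefix: str = "") -> dict[str, Tensor]:
        out = {}
        out.update(self.conv1.state_dict(prefix + "conv1."))
        out.update(self.conv2.state_dict(prefix + "conv2."))
        if self.skip is not None:
            out.update(self.skip.state_dict(prefix + "skip."))
        return out

    def __call__(self, x) -> Tensor:
        identity = self.skip(x) if self.skip is not None else ad.as_tensor(x)
        h = ad.relu(self.conv1(x))
        h = self.conv2(h)
        return ad.relu(ad.add(h, identity))


class GRUCell(Module):
    """Standard GRU cell; weights split per gate for clarity."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.w_ir = _param(rng, (n_in, n_hidden), n_in)
        self.w_iz = _param(rng, (n_in, n_hidden), n_in)
        self.w_in = _param(rng, (n_in, n_hidden), n_in)
        self.w_hr = _param(rng, (n_hidden, n_hidden), n_hidden)
        self.w_hz = _param(rng, (n_hidden, n_hidden), n_hidden)
        self.w_hn = _param(rng, (n_hidden, n_hidden), n_hidden)
        self.b_r = Tensor(np.zeros(n_hidden, dtype=DTYPE), requires_grad=True)
        self.b_z = Tensor(np.zeros(n_hidden, dtype=DTYPE), requires_grad=True)
        self.b_n = Tensor(np.zeros(n_hidden, dtype=DTYPE), requires_grad=True)
        self.b_hn = Tensor(np.zeros(n_hidden, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        r = ad.sigmoid(ad.add(ad.add(ad.matmul(x, self.w_ir), ad.matmul(h, self.w_hr)), self.b_r))
        z = ad.sigmoid(ad.add(ad.add(ad.matmul(x, self.w_iz), ad.matmul(h, self.w_hz)), self.b_z))
        hn = ad.add(ad.matmul(h, self.w_hn), self.b_hn)
        n = ad.tanh(ad.add(ad.add(ad.matmul(x, self.w_in), ad.mul(r, hn)), self.b_n))
        # h' = (1 - z) * n + z * h
        return ad.add(ad.mul(ad.add(ad.mul(z, -1.0), 1.0), n), ad.mul(z, h))

    def init_hidden(self, batch: int = 1) -> Tensor:
        return Tensor(np.zeros((batch, self.n_hidden), dtype=DTYPE))


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 3e-5, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = params
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.eps, self.weight_decay = eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            # decoupled weight decay, then Adam update
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
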