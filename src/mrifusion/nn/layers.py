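"""Network building blocks: conv, batch norm, linear, squeeze-excitation.

Parameter initialization follows He fan-out for convolutions and
uniform fan-in for linear layers.  Every module draws its weights from
the generator it is handed, so a fixed seed reproduces the network
bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Conv2d", "DepthwiseConv2d", "BatchNorm2d", "Linear",
           "SqueezeExcite", "Sequential"]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        seen, out = set(), []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    out.append(v)
        return out

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        return [(p.name or f"param{i}", p) for i, p in enumerate(self.parameters())]

    def decay_parameters(self) -> list[Tensor]:
        """Parameters subject to weight decay: conv/linear weights only."""
        out = []
        for m in self.modules():
            if isinstance(m, (Conv2d, DepthwiseConv2d, Linear)):
                out.append(m.weight)
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        state = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    state[f"{i}.{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    state[f"{i}.{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                key = f"{i}.{k}"
                if key in state:
                    if isinstance(v, Tensor):
                        v.data = np.asarray(state[key], dtype=np.float32).reshape(v.data.shape)
                    else:
                        setattr(m, k, np.asarray(state[key]).reshape(v.shape).astype(v.dtype))

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = ""):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_out = c_out * kernel * kernel
        std = float(np.sqrt(2.0 / fan_out))
        self.weight = Tensor(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)),
                             requires_grad=True, name=f"{name}.weight")
        self.stride = stride
        self.padding = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = ""):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = float(np.sqrt(2.0 / (kernel * kernel)))
        self.weight = Tensor(rng.normal(0.0, std, (channels, kernel, kernel)),
                             requires_grad=True, name=f"{name}.weight")
        self.stride = stride
        self.padding = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return x.dwconv2d(self.weight, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = ""):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True, name=f"{name}.gamma")
        self.beta = Tensor(np.zeros(channels), requires_grad=True, name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        return x.batchnorm(self.gamma, self.beta, mean, var, eps=self.eps,
                           training=self.training)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 name: str = ""):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = float(1.0 / np.sqrt(d_in))
        self.weight = Tensor(rng.uniform(-bound, bound, (d_in, d_out)),
                             requires_grad=True, name=f"{name}.weight")
        self.bias = Tensor(np.zeros(d_out), requires_grad=True, name=f"{name}.bias")

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class SqueezeExcite(Module):
    """Channel attention: squeeze (GAP) -> reduce -> SiLU -> expand -> sigmoid gate."""

    def __init__(self, channels: int, reduced: int,
                 rng: np.random.Generator | None = None, name: str = ""):
        super().__init__()
        self.fc1 = Linear(channels, reduced, rng=rng, name=f"{name}.fc1")
        self.fc2 = Linear(reduced, channels, rng=rng, name=f"{name}.fc2")

    def forward(self, x: Tensor) -> Tensor:
        s = x.global_avg_pool()                 # (N, C)
        s = self.fc1(s).silu()
        s = self.fc2(s).sigmoid()               # (N, C)
        n, c = s.shape
        return x * s.reshape(n, c, 1, 1)


class Sequential(Module):
    def __init__(self, *blocks: Module):
        super().__init__()
        self.blocks = list(blocks)

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x
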