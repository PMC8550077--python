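"""Thin layer abstractions over the functional ops.

Modules register parameters and submodules automatically through
``__setattr__`` so ``state_dict`` round-trips by name, PyTorch-style.
Weight initialisation is driven by an explicit ``numpy.random.Generator``
so two models built from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .ops import batch_norm, conv2d, max_pool2d
from .tensor import Tensor

__all__ = ["Module", "ModuleList", "Sequential", "Conv2d", "BatchNorm2d",
           "ConvBN", "MaxPool2d", "Identity"]


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array: np.ndarray):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for k, p in self._params.items():
            state[prefix + k] = p.data
        for k, b in self._buffers.items():
            state[prefix + k] = b
        for k, m in self._modules.items():
            state.update(m.named_state(prefix + k + "."))
        return state

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state mismatch; missing={sorted(missing)[:5]}, "
                f"unexpected={sorted(extra)[:5]}")
        for k, arr in own.items():
            src = np.asarray(state[k])
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{src.shape} vs {arr.shape}")
            arr[...] = src

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def summary(self) -> str:
        lines = [f"{type(self).__name__} ({self.num_parameters():,} parameters)"]
        for k, v in self.named_state().items():
            lines.append(f"  {k}: {tuple(v.shape)}")
        return "\n".join(lines)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int = 0, bias: bool = True):
        super().__init__()
        k = kernel_size
        self.stride = stride
        self.padding = padding
        self.weight = Tensor(
            _kaiming(rng, (out_ch, in_ch, k, k), in_ch * k * k),
            requires_grad=True)
        self.bias = (Tensor(np.zeros(out_ch, np.float32), requires_grad=True)
                     if bias else None)

    def forward(self, x):
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(ch, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(ch, np.float32))
        self.register_buffer("running_var", np.ones(ch, np.float32))

    def forward(self, x):
        return batch_norm(x, self.gamma, self.beta,
                          self.running_mean, self.running_var,
                          training=self.training,
                          momentum=self.momentum, eps=self.eps)


class ConvBN(Module):
    """Conv2d + BatchNorm2d, optionally rectified."""

    def __init__(self, in_ch, out_ch, kernel_size, rng,
                 stride=1, padding=0, relu=True):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel_size, rng,
                           stride=stride, padding=padding, bias=False)
        self.bn = BatchNorm2d(out_ch)
        self.relu = relu

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.relu() if self.relu else x


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return max_pool2d(x, self.kernel_size, self.stride, self.padding)
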