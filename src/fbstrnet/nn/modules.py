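"""Minimal layer/module system: parameter registration, train/eval mode,
state dicts. Layout and naming follow the familiar torch-style convention
so the detector definition reads naturally."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    def __init__(self):
        self.training = True

    # -- registration is implicit: anything in __dict__ that is a Tensor with
    #    requires_grad, a Module, or a list of Modules participates.
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, np.ndarray):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_buffers(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({f"buf::{name}": b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, arr in state.items():
            if key.startswith("buf::"):
                buf = bufs[key[5:]]
                buf[...] = arr
            else:
                p = params[key]
                if p.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}: {p.data.shape} vs {arr.shape}")
                p.data = np.asarray(arr, dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(shape, fan_in, rng: np.random.Generator) -> np.ndarray:
    bound = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, bound, size=shape).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reseed the weight-initialization stream (used by training harnesses)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True):
        super().__init__()
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError(f"channel counts must be positive, got {in_ch}->{out_ch}")
        if groups not in (1, in_ch):
            raise ValueError("only dense (groups=1) or depthwise (groups=in_ch) supported")
        if groups == in_ch and in_ch != out_ch:
            raise ValueError("depthwise convolution requires in_ch == out_ch")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.padding, self.groups = stride, padding, groups
        cpg = in_ch // groups
        fan_in = cpg * kernel * kernel
        self.weight = Tensor(
            _kaiming((out_ch, cpg, kernel, kernel), fan_in, _INIT_RNG), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        if self.groups == 1:
            return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)
        return F.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.03, eps: float = 1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Tensor(np.ones(ch, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(ch, np.float32), requires_grad=True)
        self.running_mean = np.zeros(ch, np.float32)
        self.running_var = np.ones(ch, np.float32)

    def forward(self, x):
        return F.batch_norm(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )
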