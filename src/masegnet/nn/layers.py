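"""Layer modules on top of the autograd core.

Weights are He-uniform initialised (bound sqrt(6 / fan_in)) from a
caller-supplied numpy Generator so whole networks are reproducibly
initialised from a single integer seed; biases start at zero.
"""

from __future__ import annotations

import numpy as np

from masegnet.nn.autograd import (
    Parameter,
    Tensor,
    conv2d,
    conv_transpose2d_2x,
    matmul,
)

DTYPE = np.float32


class Module:
    """Base class: child parameters/modules are discovered by attribute
    scan, pytorch-style."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch; missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs "
                    f"{state[name].shape}"
                )
            p.data = state[name].astype(p.data.dtype).copy()


class ModuleList(Module):
    def __init__(self, modules=()):
        self._items = list(modules)

    def append(self, m: Module) -> None:
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._items):
            yield from m.named_parameters(f"{prefix}{i}.")


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Stride-1 zero-padded 2D convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None,
                 bias: bool = True):
        if padding is None:
            padding = (kernel_size - 1) // 2  # same-size output for odd k
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_he_uniform(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, bias: bool = True):
        fan_in = in_channels * 4
        self.weight = Parameter(_he_uniform(
            rng, (in_channels, out_channels, 2, 2), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d_2x(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_he_uniform(
            rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


def count_parameters(module: Module) -> int:
    return sum(p.data.size for p in module.parameters())
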