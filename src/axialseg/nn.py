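"""Neural-network layers on the :mod:`axialseg.grad` backend.

Provides the minimal module system the segmentation network needs: parameter
registration and (de)serialisation, 3-D convolutions with He-style init,
2x transposed convolutions, instance normalisation, and pointwise activations.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import grad
from .grad import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: attribute-discovery of parameters and submodules."""

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    """3-D convolution, odd kernel, symmetric zero padding (same-size at stride 1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if kernel % 2 == 0:
            raise ValueError("Conv3d kernel must be odd")
        self.stride = stride
        self.padding = kernel // 2
        fan_in = in_ch * kernel ** 3
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = grad.conv3d(x, self.weight, stride=self.stride, padding=self.padding)
        if self.bias is not None:
            out = out + grad.reshape(self.bias, (1, -1, 1, 1, 1))
        return out


class ConvTranspose3d2x(Module):
    """Transposed convolution with kernel 2, stride 2 (doubles resolution)."""

    def __init__(self, in_ch: int, out_ch: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, 2, 2, 2), in_ch * 8))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = grad.conv_transpose3d_2x(x, self.weight)
        if self.bias is not None:
            out = out + grad.reshape(self.bias, (1, -1, 1, 1, 1))
        return out


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        if affine:
            self.gamma = Parameter(np.ones((1, channels, 1, 1, 1), dtype=np.float32))
            self.beta = Parameter(np.zeros((1, channels, 1, 1, 1), dtype=np.float32))
        else:
            self.gamma = self.beta = None

    def forward(self, x: Tensor) -> Tensor:
        return grad.instance_norm(x, self.gamma, self.beta, eps=self.eps)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return grad.leaky_relu(x, self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return grad.sigmoid(x)


class Linear(Module):
    """Affine map applied to the last axis."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out
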