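"""Layer/module abstractions built on the autograd core.

Weight initialization follows the Kaiming scheme (zero-mean normal with
variance 2 / fan_in) appropriate for ReLU networks; the offset-predicting
convolution inside the deformable block is zero-initialized so training
starts from an ordinary convolution.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        super().__setattr__(name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def num_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Same-size convolution, stride 1, odd kernel."""

    def __init__(self, in_c: int, out_c: int, k: int, rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((out_c, in_c, k, k), dtype=np.float32)
        else:
            w = _kaiming(rng, (out_c, in_c, k, k), in_c * k * k)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_c, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)


class GroupNorm(Module):
    def __init__(self, channels: int, groups: int):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.groups = groups
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.group_norm(x, self.gamma, self.beta, self.groups)


def _gn_groups(channels: int, cap: int = 8) -> int:
    g = min(cap, channels)
    while channels % g:
        g -= 1
    return g


class ConvGNReLU(Module):
    """3x3 conv + group norm + ReLU."""

    def __init__(self, in_c: int, out_c: int, rng: np.random.Generator, gn_cap: int = 8):
        super().__init__()
        self.conv = Conv2d(in_c, out_c, 3, rng)
        self.gn = GroupNorm(out_c, _gn_groups(out_c, gn_cap))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.relu(self.gn(self.conv(x)))


class DoubleConv(Module):
    """(3x3 conv + GN + ReLU) x 2 — the standard encoder/decoder block body."""

    def __init__(self, in_c: int, out_c: int, rng: np.random.Generator, gn_cap: int = 8):
        super().__init__()
        self.a = ConvGNReLU(in_c, out_c, rng, gn_cap)
        self.b = ConvGNReLU(out_c, out_c, rng, gn_cap)

    def __call__(self, x: Tensor) -> Tensor:
        return self.b(self.a(x))


class DeformConvGNReLU(Module):
    """3x3 deformable conv + GN + ReLU.

    A plain convolution predicts 18 per-position offsets (row/column for
    each kernel tap); it is zero-initialized so the block behaves as an
    ordinary convolution at the start of training.
    """

    def __init__(self, in_c: int, out_c: int, rng: np.random.Generator, gn_cap: int = 8):
        super().__init__()
        self.offset_conv = Conv2d(in_c, 18, 3, rng, zero_init=True)
        self.conv_w = Tensor(_kaiming(rng, (out_c, in_c, 3, 3), in_c * 9), requires_grad=True)
        self.conv_b = Tensor(np.zeros(out_c, dtype=np.float32), requires_grad=True)
        self.gn = GroupNorm(out_c, _gn_groups(out_c, gn_cap))

    def __call__(self, x: Tensor) -> Tensor:
        off = self.offset_conv(x)
        return ag.relu(self.gn(ag.deform_conv2d(x, off, self.conv_w, self.conv_b)))

    def offset_param_count(self) -> int:
        return int(np.prod(self.offset_conv.weight.shape)) + int(np.prod(self.offset_conv.bias.shape))


class UpConvGNReLU(Module):
    """Bilinear upsampling by an integer factor, then 3x3 conv + GN + ReLU."""

    def __init__(self, in_c: int, out_c: int, factor: int, rng: np.random.Generator,
                 deformable: bool = False, gn_cap: int = 8):
        super().__init__()
        self.factor = factor
        if deformable:
            self.block = DeformConvGNReLU(in_c, out_c, rng, gn_cap)
        else:
            self.block = ConvGNReLU(in_c, out_c, rng, gn_cap)

    def __call__(self, x: Tensor) -> Tensor:
        return self.block(ag.upsample_bilinear(x, self.factor))


class AttentionGate(Module):
    """Additive attention gate.

    Both inputs are projected by 1x1 convolutions to an intermediate width,
    summed, passed through ReLU and a 1x1 projection to a single channel,
    and squashed by a sigmoid; the resulting per-pixel coefficient in (0, 1)
    multiplicatively re-weights the skip input.
    """

    def __init__(self, gating_c: int, skip_c: int, rng: np.random.Generator, inter_c: int | None = None):
        super().__init__()
        inter_c = inter_c or max(skip_c // 2, 1)
        self.theta = Conv2d(gating_c, inter_c, 1, rng)
        self.phi = Conv2d(skip_c, inter_c, 1, rng)
        self.psi = Conv2d(inter_c, 1, 1, rng)

    def __call__(self, gating: Tensor, skip: Tensor) -> Tensor:
        if gating.shape[2:] != skip.shape[2:]:
            raise ValueError(f"spatial mismatch: {gating.shape} vs {skip.shape}")
        alpha = ag.sigmoid(self.psi(ag.relu(ag.add(self.theta(gating), self.phi(skip)))))
        return ag.mul(skip, alpha)
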