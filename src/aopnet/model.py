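"""The dual-branch segmentation network (DBSN) and its losses.

Architecture overview (for base width ``b``, input 1 x H x W, H and W
divisible by 16):

* **Shared encoder** — five double-conv blocks F1..F5 of widths
  ``b, 2b, 4b, 8b, 16b``; F1..F4 are followed by 2x2 max pooling, F5 is
  not, so the bottleneck sits at 1/16 resolution (32 x 24 for the
  standard 512 x 384 input at ``b = 32``, giving 512 channels).
* **Lower decoder branch** — four double-conv blocks L1..L4 halving the
  channel count (``16b -> 8b -> 4b -> 2b -> b``) at constant 1/16
  resolution, closed by a 1x1 convolution + softmax head ``D_L`` that
  emits a coarse 3-class probability map.
* **Upper decoder branch** — U1 fuses the pre-pool F4 skip with the
  upsampled, conv-projected L1 output; U2..U4 each fuse the matching
  encoder skip (``in_encode``), the upsampled previous-block output
  (``in_upper``), and an attention-gated copy of the matching lower-branch
  output (``in_ag``).  The gate is driven by a deformable-convolution
  projection of the previous block, letting the sampling grid bend along
  the curved, ellipse-like targets.  A 1x1 convolution + softmax head
  ``D_U`` emits the full-resolution probability map.
* **Collaborative loss** — ``w_U * Dice(D_U) + w_L * Dice(D_L)`` with the
  lower-branch target obtained by 16x thin-structure-preserving voting of
  the ground-truth mask.  Defaults ``w_U = 1.0``, ``w_L = 0.2``.

Ablation flags reproduce the three reduced variants: ``use_lower_branch``
off removes L1..L4/D_L and routes the F5 bottleneck straight into U1
(a plain U-Net-like decoder); ``use_attention_gates`` off keeps the lower
branch but concatenates its projected output instead of gating it;
``use_deformable`` off replaces the deformable projections with ordinary
convolutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = [
    "NetworkConfig",
    "DualOutput",
    "DBSN",
    "build_dbsn",
    "dice_loss",
    "collaborative_loss",
    "downsample_mask_majority",
    "save_checkpoint",
    "load_checkpoint",
    "CheckpointMismatchError",
    "sweep_w_lower",
]

NUM_CLASSES = 3  # 0 background, 1 pubic symphysis, 2 fetal head
PS_CLASS = 1


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    num_classes: int = NUM_CLASSES
    base_channels: int = 32
    gn_groups: int = 8
    use_lower_branch: bool = True
    use_attention_gates: bool = True
    use_deformable: bool = True
    w_upper: float = 1.0
    w_lower: float = 0.2

    def __post_init__(self):
        if self.base_channels % self.gn_groups:
            raise ValueError(
                f"base_channels {self.base_channels} not divisible by gn_groups {self.gn_groups}"
            )
        if self.use_attention_gates and not self.use_lower_branch:
            raise ValueError("attention gates require the lower branch")
        if self.w_upper < 0 or self.w_lower < 0:
            raise ValueError("loss weights must be >= 0")
        if self.in_channels < 1 or self.num_classes < 2:
            raise ValueError("invalid channel/class counts")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass(frozen=True)
class DualOutput:
    """Per-pixel class-probability maps from the two decoder heads.

    ``upper`` has shape (H, W, C) at input resolution; ``lower`` has shape
    (H/16, W/16, C), or is None for the no-lower-branch ablation.
    """

    upper: np.ndarray
    lower: np.ndarray | None


class DBSN(nn.Module):
    """Dual-branch segmentation network (see module docstring)."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        b = cfg.base_channels
        g = cfg.gn_groups
        C = cfg.num_classes

        self.enc1 = nn.DoubleConv(cfg.in_channels, b, rng, g)
        self.enc2 = nn.DoubleConv(b, 2 * b, rng, g)
        self.enc3 = nn.DoubleConv(2 * b, 4 * b, rng, g)
        self.enc4 = nn.DoubleConv(4 * b, 8 * b, rng, g)
        self.enc5 = nn.DoubleConv(8 * b, 16 * b, rng, g)

        if cfg.use_lower_branch:
            self.low1 = nn.DoubleConv(16 * b, 8 * b, rng, g)
            self.low2 = nn.DoubleConv(8 * b, 4 * b, rng, g)
            self.low3 = nn.DoubleConv(4 * b, 2 * b, rng, g)
            self.low4 = nn.DoubleConv(2 * b, b, rng, g)
            self.d_l = nn.Conv2d(b, C, 1, rng)
            # lower -> upper fusion paths (upsample by 2^level to match U_k)
            self.lower_path1 = nn.UpConvGNReLU(8 * b, 8 * b, 2, rng, gn_cap=g)
            self.lower_path2 = nn.UpConvGNReLU(4 * b, 4 * b, 4, rng, gn_cap=g)
            self.lower_path3 = nn.UpConvGNReLU(2 * b, 2 * b, 8, rng, gn_cap=g)
            self.lower_path4 = nn.UpConvGNReLU(b, b, 16, rng, gn_cap=g)
        else:
            # plain decoder: bottleneck feeds U1 through the standard path
            self.bottleneck_path = nn.UpConvGNReLU(16 * b, 8 * b, 2, rng, gn_cap=g)

        # in_upper paths: previous block output, x2 upsampled + projected
        self.upper_path2 = nn.UpConvGNReLU(8 * b, 4 * b, 2, rng, gn_cap=g)
        self.upper_path3 = nn.UpConvGNReLU(4 * b, 2 * b, 2, rng, gn_cap=g)
        self.upper_path4 = nn.UpConvGNReLU(2 * b, b, 2, rng, gn_cap=g)

        if cfg.use_attention_gates:
            # gate drivers: deformable (or plain) projections of the previous block
            dc = cfg.use_deformable
            self.gate_path2 = nn.UpConvGNReLU(8 * b, 4 * b, 2, rng, deformable=dc, gn_cap=g)
            self.gate_path3 = nn.UpConvGNReLU(4 * b, 2 * b, 2, rng, deformable=dc, gn_cap=g)
            self.gate_path4 = nn.UpConvGNReLU(2 * b, b, 2, rng, deformable=dc, gn_cap=g)
            self.ag2 = nn.AttentionGate(4 * b, 4 * b, rng)
            self.ag3 = nn.AttentionGate(2 * b, 2 * b, rng)
            self.ag4 = nn.AttentionGate(b, b, rng)

        lower_in = 1 if cfg.use_lower_branch else 0
        self.up1 = nn.DoubleConv(8 * b + 8 * b, 8 * b, rng, g)
        self.up2 = nn.DoubleConv((2 + lower_in) * 4 * b, 4 * b, rng, g)
        self.up3 = nn.DoubleConv((2 + lower_in) * 2 * b, 2 * b, rng, g)
        self.up4 = nn.DoubleConv((2 + lower_in) * b, b, rng, g)
        self.d_u = nn.Conv2d(b, C, 1, rng)

    # -- forward ---------------------------------------------------------

    def forward_tensors(self, x: Tensor) -> tuple[Tensor, Tensor | None]:
        """Forward pass on an NCHW tensor; returns (upper, lower) probability tensors."""
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(f"input spatial dims must be divisible by 16, got {h}x{w}")
        cfg = self.cfg

        s1 = self.enc1(x)
        s2 = self.enc2(ag.max_pool2x2(s1))
        s3 = self.enc3(ag.max_pool2x2(s2))
        s4 = self.enc4(ag.max_pool2x2(s3))
        f5 = self.enc5(ag.max_pool2x2(s4))

        lower_prob = None
        if cfg.use_lower_branch:
            l1 = self.low1(f5)
            l2 = self.low2(l1)
            l3 = self.low3(l2)
            l4 = self.low4(l3)
            lower_prob = ag.softmax_channels(self.d_l(l4))
            in_lower1 = self.lower_path1(l1)
            in_lower2 = self.lower_path2(l2)
            in_lower3 = self.lower_path3(l3)
            in_lower4 = self.lower_path4(l4)
            u1 = self.up1(ag.concat([s4, in_lower1]))
        else:
            u1 = self.up1(ag.concat([s4, self.bottleneck_path(f5)]))

        def decode(block, upper_path, gate_path, gate, prev, skip, in_lower):
            parts = [skip, upper_path(prev)]
            if in_lower is not None:
                if gate is not None:
                    parts.append(gate(gate_path(prev), in_lower))
                else:
                    parts.append(in_lower)
            return block(ag.concat(parts))

        if cfg.use_attention_gates:
            u2 = decode(self.up2, self.upper_path2, self.gate_path2, self.ag2, u1, s3, in_lower2)
            u3 = decode(self.up3, self.upper_path3, self.gate_path3, self.ag3, u2, s2, in_lower3)
            u4 = decode(self.up4, self.upper_path4, self.gate_path4, self.ag4, u3, s1, in_lower4)
        elif cfg.use_lower_branch:
            u2 = decode(self.up2, self.upper_path2, None, None, u1, s3, in_lower2)
            u3 = decode(self.up3, self.upper_path3, None, None, u2, s2, in_lower3)
            u4 = decode(self.up4, self.upper_path4, None, None, u3, s1, in_lower4)
        else:
            u2 = decode(self.up2, self.upper_path2, None, None, u1, s3, None)
            u3 = decode(self.up3, self.upper_path3, None, None, u2, s2, None)
            u4 = decode(self.up4, self.upper_path4, None, None, u3, s1, None)

        upper_prob = ag.softmax_channels(self.d_u(u4))
        return upper_prob, lower_prob

    def forward(self, image: np.ndarray) -> DualOutput:
        """Inference on a single normalized (H, W) image; no gradient graph."""
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 2:
            raise ValueError("expected a single-channel (H, W) image")
        x = Tensor(image[None, None])
        with ag.no_grad():
            up, low = self.forward_tensors(x)
        upper = np.moveaxis(up.data[0], 0, -1)
        lower = None if low is None else np.moveaxis(low.data[0], 0, -1)
        return DualOutput(upper=upper, lower=lower)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        """Argmax label mask from the upper (full-resolution) head."""
        return self.forward(image).upper.argmax(axis=-1).astype(np.uint8)

    def deformable_offset_param_count(self) -> int:
        total = 0
        for _, m in self._walk():
            if isinstance(m, nn.DeformConvGNReLU):
                total += m.offset_param_count()
        return total

    def _walk(self):
        stack = [("", self)]
        while stack:
            name, mod = stack.pop()
            yield name, mod
            for n, m in mod._modules.items():
                stack.append((name + "." + n, m))


def build_dbsn(cfg: NetworkConfig, seed: int = 0) -> DBSN:
    """Construct a Kaiming-initialized DBSN (or ablated variant) from a config."""
    return DBSN(cfg, seed=seed)


# ------------------------------------------------------------------ losses


def _one_hot(truth: np.ndarray, num_classes: int) -> np.ndarray:
    truth = np.asarray(truth)
    oh = np.zeros((1, num_classes) + truth.shape, dtype=np.float32)
    for c in range(num_classes):
        oh[0, c] = truth == c
    return oh


def dice_loss(pred: Tensor | np.ndarray, truth: np.ndarray) -> Tensor:
    """Soft Dice loss over the foreground classes, pooled.

    ``D = 1 - 2 * sum(y * p) / sum(y + p)`` with both sums running over all
    pixels and the non-background channels jointly.  ``pred`` is an NCHW (or
    HWC array) probability map, ``truth`` an integer label mask.  Returns a
    scalar tensor in [0, 1].
    """
    if not isinstance(pred, Tensor):
        arr = np.asarray(pred, dtype=np.float32)
        if arr.ndim == 3:  # HWC -> NCHW
            arr = np.moveaxis(arr, -1, 0)[None]
        pred = Tensor(arr)
    n, c, h, w = pred.shape
    truth = np.asarray(truth)
    if truth.shape != (h, w):
        raise ValueError(f"truth shape {truth.shape} != prediction spatial shape {(h, w)}")
    y = _one_hot(truth, c)
    y[:, 0] = 0.0  # background excluded from the Dice sum
    fg_sel = np.zeros((1, c, 1, 1), dtype=np.float32)
    fg_sel[:, 1:] = 1.0
    y_sum = float(y.sum())
    num = ag.tsum(ag.mul(pred, Tensor(y)))
    den = ag.scalar_add(ag.tsum(ag.mul(pred, Tensor(fg_sel))), y_sum)
    return ag.scalar_add(ag.scalar_mul(ag.div(ag.scalar_mul(num, 2.0), den), -1.0), 1.0)


def downsample_mask_majority(mask: np.ndarray, factor: int = 16,
                             num_classes: int = NUM_CLASSES) -> np.ndarray:
    """Downsample a label mask with thin-structure-preserving voting.

    The pubic symphysis is far thinner than a coarse-grid cell, so a plain
    per-cell majority would erase it from every downsampled target and the
    auxiliary branch would learn that the class does not exist.  A cell is
    therefore claimed by PS when PS covers at least 1/8 of it; otherwise
    the cell takes the majority label (ties: lowest label).
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    if h % factor or w % factor:
        raise ValueError("mask dims must be divisible by the downsampling factor")
    counts = np.zeros((num_classes, h // factor, w // factor), dtype=np.int64)
    for c in range(num_classes):
        counts[c] = (
            (mask == c)
            .reshape(h // factor, factor, w // factor, factor)
            .sum(axis=(1, 3))
        )
    out = counts.argmax(axis=0).astype(mask.dtype)
    if num_classes > PS_CLASS:
        out[counts[PS_CLASS] * 8 >= factor * factor] = PS_CLASS
    return out


def collaborative_loss(
    out: tuple[Tensor, Tensor | None] | DualOutput,
    truth: np.ndarray,
    cfg: NetworkConfig,
) -> Tensor:
    """Weighted sum of the upper- and lower-branch Dice losses.

    The lower-branch target is the ground-truth mask majority-vote
    downsampled to the coarse head's resolution.  Without the lower branch
    the loss is the upper term alone.
    """
    if isinstance(out, DualOutput):
        upper, lower = out.upper, out.lower
    else:
        upper, lower = out
    loss = ag.scalar_mul(dice_loss(upper, truth), cfg.w_upper)
    if cfg.use_lower_branch and lower is not None:
        hw = upper.shape[:2] if isinstance(upper, np.ndarray) and upper.ndim == 3 else upper.shape[2:]
        lh = lower.shape[0] if isinstance(lower, np.ndarray) and lower.ndim == 3 else lower.shape[2]
        factor = hw[0] // lh
        low_truth = downsample_mask_majority(truth, factor, cfg.num_classes)
        loss = ag.add(loss, ag.scalar_mul(dice_loss(lower, low_truth), cfg.w_lower))
    return loss


# -------------------------------------------------------------- checkpoints


class CheckpointMismatchError(RuntimeError):
    """Checkpoint network configuration differs from the expected one."""


def save_checkpoint(path, model: DBSN) -> None:
    arrays = {name: p.data for name, p in model.named_parameters()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path, expected_cfg: NetworkConfig | None = None) -> DBSN:
    with np.load(path) as data:
        cfg = NetworkConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        if expected_cfg is not None and cfg != expected_cfg:
            raise CheckpointMismatchError(
                f"checkpoint config {cfg} != expected {expected_cfg}"
            )
        model = build_dbsn(cfg)
        named = dict(model.named_parameters())
        missing = set(named) - set(data.files)
        if missing:
            raise CheckpointMismatchError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        for name, p in named.items():
            arr = data[name]
            if arr.shape != p.data.shape:
                raise CheckpointMismatchError(f"shape mismatch for {name}")
            p.data = arr.astype(np.float32)
    return model


def sweep_w_lower(values: Sequence[float], trainer_config, samples):
    """Grid over the lower-branch loss weight; delegates to the pipeline."""
    from .pipeline import sweep_w_lower as _sweep

    return _sweep(values, trainer_config, samples)
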