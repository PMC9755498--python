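"""Deterministic resizing/normalization and stochastic augmentation.

Transperineal ultrasound frames are acquired at 1,295 x 1,026 and
processed at 512 x 384 with intensities mapped to [-1, 1].  The resize is
anisotropic (the two aspect ratios differ; the stated sizes are followed
literally, without padding).  Augmentation applies a common random
rotation (default +/-30 degrees) and horizontal flip to image, mask, and
key points so that labels and geometry stay consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

__all__ = [
    "AugmentationSpec",
    "TARGET_WIDTH",
    "TARGET_HEIGHT",
    "resize_normalize",
    "resize_mask",
    "augment",
    "apply_affine",
    "affine_matrix",
]

TARGET_WIDTH = 512
TARGET_HEIGHT = 384


@dataclass(frozen=True)
class AugmentationSpec:
    rotation_range_deg: tuple[float, float] = (-30.0, 30.0)
    hflip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.rotation_range_deg
        if not (-180.0 <= lo <= hi <= 180.0):
            raise ValueError("rotation range must lie within [-180, 180]")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must be a probability")


def resize_normalize(
    image: np.ndarray, size: tuple[int, int] = (TARGET_HEIGHT, TARGET_WIDTH)
) -> np.ndarray:
    """Bilinear resize of an 8-bit image to (H, W) and map to [-1, 1].

    The intensity map is ``v' = v / 127.5 - 1``.
    """
    from skimage.transform import resize

    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty single-channel image")
    out = resize(image.astype(np.float32), size, order=1,
                 preserve_range=True, anti_aliasing=False)
    return (out / 127.5 - 1.0).astype(np.float32)


def resize_mask(
    mask: np.ndarray, size: tuple[int, int] = (TARGET_HEIGHT, TARGET_WIDTH)
) -> np.ndarray:
    """Nearest-neighbor resize of a label mask; labels are never interpolated."""
    from skimage.transform import resize

    mask = np.asarray(mask)
    if mask.shape == tuple(size):
        return mask.copy()
    out = resize(mask, size, order=0, preserve_range=True, anti_aliasing=False)
    return out.astype(mask.dtype)


def affine_matrix(shape: tuple[int, int], theta_deg: float, hflip: bool) -> np.ndarray:
    """Forward 3x3 affine map in (x, y) homogeneous coordinates.

    Rotation by ``theta_deg`` about the image center (pixel-center
    convention), followed by a horizontal flip when requested.
    """
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    t = math.radians(theta_deg)
    ct, st = math.cos(t), math.sin(t)
    rot = np.array(
        [
            [ct, -st, cx - ct * cx + st * cy],
            [st, ct, cy - st * cx - ct * cy],
            [0.0, 0.0, 1.0],
        ]
    )
    if not hflip:
        return rot
    flip = np.array([[-1.0, 0.0, w - 1.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    return flip @ rot


def apply_affine(points: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Apply a forward 3x3 affine map to (n, 2) points in (x, y) order."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    ph = np.column_stack([pts, np.ones(len(pts))])
    return (ph @ matrix.T)[:, :2]


def _warp_pair(image: np.ndarray, mask: np.ndarray, matrix: np.ndarray):
    inv = AffineTransform(matrix=np.linalg.inv(matrix))
    img_out = warp(image.astype(np.float32), inv, order=1, cval=-1.0,
                   preserve_range=True).astype(np.float32)
    mask_out = warp(mask, inv, order=0, cval=0, preserve_range=True).astype(mask.dtype)
    return img_out, mask_out


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    keypoints: np.ndarray | None,
    spec: AugmentationSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Randomly rotate and flip (image, mask, key points) consistently.

    The same rotation angle (uniform over the configured range) and the
    same flip decision are applied to all three.  Images are interpolated
    bilinearly with a -1 (black) fill; masks use nearest neighbor with a
    background fill; key points follow the exact affine map.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    lo, hi = spec.rotation_range_deg
    theta = float(rng.uniform(lo, hi))
    flip = bool(rng.random() < spec.hflip_prob)
    return augment_with_params(image, mask, keypoints, theta, flip)


def augment_with_params(
    image: np.ndarray,
    mask: np.ndarray,
    keypoints: np.ndarray | None,
    theta_deg: float,
    hflip: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Deterministic core of :func:`augment` for a known angle/flip."""
    if theta_deg == 0.0 and not hflip:
        kp = None if keypoints is None else np.asarray(keypoints, dtype=float).copy()
        return image.copy(), mask.copy(), kp
    m = affine_matrix(image.shape, theta_deg, hflip)
    img_out, mask_out = _warp_pair(image, mask, m)
    kp_out = None if keypoints is None else apply_affine(keypoints, m)
    return img_out, mask_out, kp_out
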