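"""Ultrasound-like phantoms with exact masks, key points, and analytic AoP.

Each phantom emulates the standard transperineal plane: a fan-shaped
speckled field containing a small bright filled ellipse (the pubic
symphysis, PS) and a large bright elliptical rim with a darker interior
(the fetal-head skull echo, FH).  Because the generating ellipses are
known in closed form, every downstream stage has an exact oracle: the
mask is the rasterization of the true ellipse interiors, the key points
and the AoP are computed analytically from the exact parameters via the
same geometric construction the measurement pipeline uses.

The speckle model (constant tissue level plus half-normal noise, Gaussian
blurred) is a visual stand-in only; no physical acoustics are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .geometry import (
    AoPKeyPoints,
    GeometricEllipse,
    Point2D,
    analytic_aop,
    geometric_to_conic,
)

__all__ = [
    "PhantomSpec",
    "SyntheticSample",
    "PhantomError",
    "sample_phantom_spec",
    "generate_sample",
    "generate_dataset",
    "DEFAULT_IMAGE_SIZE",
]

DEFAULT_IMAGE_SIZE = (384, 512)  # (H, W): width 512, height 384
_REFERENCE_WIDTH = 512

# axis ranges in pixels at the reference 512-wide frame; scaled linearly
# for other frame sizes
_PS_MAJOR = (25.0, 45.0)
_PS_MINOR = (8.0, 16.0)
_FH_MAJOR = (90.0, 150.0)
_FH_MINOR = (70.0, 120.0)

_AOP_RANGE = (60.0, 170.0)
_MAX_RETRIES = 1000


class PhantomError(RuntimeError):
    """No valid phantom layout found within the retry budget."""


@dataclass(frozen=True)
class PhantomSpec:
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE  # (H, W)
    ps_center: tuple[float, float] = (170.0, 110.0)
    ps_axes: tuple[float, float] = (35.0, 12.0)
    ps_theta: float = 0.9
    fh_center: tuple[float, float] = (300.0, 210.0)
    fh_axes: tuple[float, float] = (120.0, 95.0)
    fh_theta: float = 0.3
    speckle_sigma: float = 0.13
    blur_sigma: float = 1.5
    fan_angle_deg: float = 85.0
    seed: int = 0

    def ps_ellipse(self) -> GeometricEllipse:
        return GeometricEllipse(
            Point2D(*self.ps_center), self.ps_axes[0], self.ps_axes[1],
            self.ps_theta % math.pi,
        )

    def fh_ellipse(self) -> GeometricEllipse:
        return GeometricEllipse(
            Point2D(*self.fh_center), self.fh_axes[0], self.fh_axes[1],
            self.fh_theta % math.pi,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray  # (H, W) float32 in [-1, 1]
    mask: np.ndarray  # (H, W) uint8, 0 bg / 1 PS / 2 FH
    gt_keypoints: AoPKeyPoints
    gt_aop_deg: float
    spec: PhantomSpec
    patient_id: str = "p000"
    image_id: str = "img000"


# --------------------------------------------------------------- sampling


def _quadform_grid(e: GeometricEllipse, h: int, w: int) -> np.ndarray:
    """(x-c)^T M (x-c) evaluated at every pixel center; 1 on the boundary."""
    ct, st = math.cos(e.theta), math.sin(e.theta)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    dx = xx - e.center.x
    dy = yy - e.center.y
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / e.semi_major) ** 2 + (v / e.semi_minor) ** 2


def _quadform_scalar(e: GeometricEllipse, p: Point2D) -> float:
    ct, st = math.cos(e.theta), math.sin(e.theta)
    dx, dy = p.x - e.center.x, p.y - e.center.y
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / e.semi_major) ** 2 + (v / e.semi_minor) ** 2


def _ellipses_valid(ps: GeometricEllipse, fh: GeometricEllipse,
                    h: int, w: int, fan_angle_deg: float) -> bool:
    margin = 3.0
    for e in (ps, fh):
        pts = e.boundary_points(128)
        if (pts[:, 0] < margin).any() or (pts[:, 0] > w - 1 - margin).any():
            return False
        if (pts[:, 1] < margin).any() or (pts[:, 1] > h - 1 - margin).any():
            return False
        if not _points_in_fan(pts, h, w, fan_angle_deg):
            return False  # both structures must be insonated, not in the dark
    fh_conic = geometric_to_conic(fh)
    ps_conic = geometric_to_conic(ps)
    # disjoint interiors: each boundary entirely outside the other ellipse
    for pt in ps.boundary_points(128):
        if fh_conic.evaluate(Point2D(*pt)) <= 0:
            return False
    for pt in fh.boundary_points(128):
        if ps_conic.evaluate(Point2D(*pt)) <= 0:
            return False
    return True


def sample_phantom_spec(
    rng: np.random.Generator,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    seed: int = 0,
) -> PhantomSpec:
    """Rejection-sample a valid phantom layout.

    The fetal head is placed right-of-center with its long axis near
    horizontal; the pubic symphysis sits up-and-left of the head at
    1.25-1.9 head-radii, its long axis pointing roughly at the head with
    about +/-57 degrees of jitter.  A layout is accepted when both
    ellipses fit in the frame, their interiors are disjoint, the inferior
    PS endpoint clears the head by a soft-tissue margin, and the analytic
    AoP falls in [60, 170] degrees.
    """
    h, w = image_size
    scale = w / _REFERENCE_WIDTH
    fan_angle = 85.0
    for _ in range(_MAX_RETRIES):
        fh_a = rng.uniform(*_FH_MAJOR) * scale
        fh_b = rng.uniform(_FH_MINOR[0] * scale, min(_FH_MINOR[1] * scale, fh_a))
        fh_theta = rng.uniform(-0.45, 0.45) % math.pi
        fh_cx = rng.uniform(0.50, 0.68) * w
        fh_cy = rng.uniform(0.45, 0.62) * h
        fh = GeometricEllipse(Point2D(fh_cx, fh_cy), fh_a, fh_b, fh_theta)

        phi = rng.uniform(math.radians(175.0), math.radians(245.0))
        dist = rng.uniform(1.25, 1.9) * fh_a
        ps_cx = fh_cx + dist * math.cos(phi)
        ps_cy = fh_cy + dist * math.sin(phi)
        ps_a = rng.uniform(*_PS_MAJOR) * scale
        ps_b = rng.uniform(_PS_MINOR[0] * scale, min(_PS_MINOR[1] * scale, ps_a))
        toward = math.atan2(fh_cy - ps_cy, fh_cx - ps_cx)
        ps_theta = (toward + rng.uniform(-1.0, 1.0)) % math.pi
        try:
            ps = GeometricEllipse(Point2D(ps_cx, ps_cy), ps_a, ps_b, ps_theta)
        except Exception:
            continue
        if not _ellipses_valid(ps, fh, h, w, fan_angle):
            continue
        try:
            aop, kp = analytic_aop(ps, fh)
        except Exception:
            continue
        if not (_AOP_RANGE[0] <= aop <= _AOP_RANGE[1]):
            continue
        # a soft-tissue gap separates the inferior PS end from the skull:
        # keep Lp well clear of the head so the tangent direction is stable
        if _quadform_scalar(fh, kp.Lp) < 1.15:
            continue
        return PhantomSpec(
            image_size=(h, w),
            ps_center=(ps_cx, ps_cy),
            ps_axes=(ps_a, ps_b),
            ps_theta=ps_theta,
            fh_center=(fh_cx, fh_cy),
            fh_axes=(fh_a, fh_b),
            fh_theta=fh_theta,
            # blur scales with the frame so smaller phantoms are a
            # photometrically consistent shrink of the reference frame
            blur_sigma=max(1.5 * scale, 0.4),
            seed=seed,
        )
    raise PhantomError(f"no valid layout after {_MAX_RETRIES} attempts")


# -------------------------------------------------------------- rendering


def _fan_apex(h: int, w: int) -> tuple[float, float]:
    return w / 2.0, -0.25 * h


def _fan_indicator(h: int, w: int, fan_angle_deg: float) -> np.ndarray:
    """Fan sector with apex above the top edge, opening downward."""
    apex_x, apex_y = _fan_apex(h, w)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    dx = xx - apex_x
    dy = yy - apex_y
    ang = np.abs(np.arctan2(dx, dy))  # angle from straight-down
    r = np.hypot(dx, dy)
    return (ang <= math.radians(fan_angle_deg / 2.0)) & (r <= 1.35 * h)


def _points_in_fan(pts: np.ndarray, h: int, w: int, fan_angle_deg: float) -> bool:
    apex_x, apex_y = _fan_apex(h, w)
    dx = pts[:, 0] - apex_x
    dy = pts[:, 1] - apex_y
    ang = np.abs(np.arctan2(dx, dy))
    r = np.hypot(dx, dy)
    margin = math.radians(2.0)  # keep structures clear of the dark sector edge
    return bool((ang <= math.radians(fan_angle_deg / 2.0) - margin).all()
                and (r <= 1.3 * h).all())


def generate_sample(spec: PhantomSpec) -> SyntheticSample:
    """Render one phantom: image, exact mask, exact key points, analytic AoP."""
    h, w = spec.image_size
    ps = spec.ps_ellipse()
    fh = spec.fh_ellipse()
    rng = np.random.default_rng(spec.seed)

    q_ps = _quadform_grid(ps, h, w)
    q_fh = _quadform_grid(fh, h, w)
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[q_fh <= 1.0] = 2
    mask[q_ps <= 1.0] = 1  # interiors are disjoint by construction

    tissue = 0.32 + np.abs(rng.normal(0.0, spec.speckle_sigma, size=(h, w)))
    s_fh = np.sqrt(q_fh)
    rim = 0.75 * np.exp(-(((s_fh - 1.0) / 0.05) ** 2))
    interior_dim = np.where(s_fh < 0.92, -0.18, 0.0)  # skull interior echoes darker
    ps_blob = 1.5 * np.clip((1.0 - np.sqrt(q_ps)) / 0.12, 0.0, 1.0)
    img = (tissue + rim + ps_blob + interior_dim) * _fan_indicator(h, w, spec.fan_angle_deg)
    img = ndimage.gaussian_filter(img.astype(np.float32), spec.blur_sigma)
    lo, hi = float(img.min()), float(img.max())
    img = (2.0 * (img - lo) / (hi - lo) - 1.0).astype(np.float32)

    aop, keypoints = analytic_aop(ps, fh)
    return SyntheticSample(
        image=img, mask=mask, gt_keypoints=keypoints, gt_aop_deg=aop, spec=spec
    )


def generate_dataset(
    n: int,
    base_seed: int = 0,
    patients: int = 1,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
) -> list[SyntheticSample]:
    """Generate ``n`` phantoms assigned round-robin to synthetic patients.

    Per-sample randomness derives deterministically from ``base_seed``; the
    same call yields bit-identical datasets.
    """
    samples = []
    for i in range(n):
        rng = np.random.default_rng([base_seed, i])
        seed = int((base_seed * 1_000_003 + i) % (2**31 - 1))
        spec = sample_phantom_spec(rng, image_size=image_size, seed=seed)
        s = generate_sample(spec)
        samples.append(
            SyntheticSample(
                image=s.image,
                mask=s.mask,
                gt_keypoints=s.gt_keypoints,
                gt_aop_deg=s.gt_aop_deg,
                spec=s.spec,
                patient_id=f"p{i % patients:03d}",
                image_id=f"img{i:04d}",
            )
        )
    return samples
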