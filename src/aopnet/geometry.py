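"""Ellipse fitting and angle-of-progression (AoP) geometry.

The AoP is the angle at the inferior endpoint of the pubic symphysis (PS)
between (i) the PS long axis and (ii) the line tangent to the fetal head
(FH) contour.  Given a 3-class label mask (0 background, 1 PS, 2 FH) this
module extracts region boundaries, fits an ellipse to each structure by
direct least squares under the quadratic conic constraint ``4AC - B^2 = 1``,
takes the PS major-axis endpoints, constructs the tangent line from the
inferior endpoint to the FH ellipse, and returns the angle in degrees.

Coordinates are continuous pixel positions: x grows rightward (columns),
y grows downward (rows), with geometry evaluated at pixel centers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Point2D",
    "ConicCoefficients",
    "GeometricEllipse",
    "AoPKeyPoints",
    "AoPResult",
    "AoPStatus",
    "GeometryError",
    "EmptyClassError",
    "EllipseFitError",
    "DegenerateConicError",
    "TangentError",
    "mask_to_boundary",
    "fit_ellipse",
    "conic_to_geometric",
    "geometric_to_conic",
    "major_axis_endpoints",
    "label_endpoints",
    "tangent_points",
    "select_tangent",
    "compute_aop",
    "measure_aop_from_mask",
    "PS_CLASS",
    "FH_CLASS",
]

PS_CLASS = 1
FH_CLASS = 2

_CIRCLE_TIE_EPS = 1e-9


class GeometryError(ValueError):
    """Base class for geometric failures."""


class EmptyClassError(GeometryError):
    """The mask contains no pixel of the requested class."""


class EllipseFitError(GeometryError):
    """Direct least-squares ellipse fitting failed (too few / degenerate points)."""


class DegenerateConicError(GeometryError):
    """Conic coefficients do not describe a real ellipse."""


class TangentError(GeometryError):
    """No tangent exists: the point lies inside or on the ellipse."""


@dataclass(frozen=True)
class Point2D:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class ConicCoefficients:
    """Conic ``A x^2 + B xy + C y^2 + D x + E y + F = 0``.

    Normalized so that ``4AC - B^2 = 1`` (with ``A > 0``), the quadratic
    constraint under which the least-squares fit is solved; any true ellipse
    admits exactly one such scaling up to sign.
    """

    A: float
    B: float
    C_coef: float
    D_coef: float
    E: float
    F_coef: float

    def __post_init__(self) -> None:
        disc = self.B * self.B - 4.0 * self.A * self.C_coef
        if not disc < 0:
            raise DegenerateConicError(f"not an ellipse: B^2 - 4AC = {disc}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.A, self.B, self.C_coef, self.D_coef, self.E, self.F_coef],
            dtype=float,
        )

    def matrix(self) -> np.ndarray:
        """Symmetric 3x3 homogeneous conic matrix Q with x^T Q x = F(a, x)."""
        A, B, C, D, E, F = self.as_array()
        return np.array(
            [
                [A, B / 2.0, D / 2.0],
                [B / 2.0, C, E / 2.0],
                [D / 2.0, E / 2.0, F],
            ]
        )

    def evaluate(self, p: Point2D) -> float:
        """Algebraic residual F(a, p); negative inside, positive outside."""
        x, y = p.x, p.y
        return (
            self.A * x * x
            + self.B * x * y
            + self.C_coef * y * y
            + self.D_coef * x
            + self.E * y
            + self.F_coef
        )


@dataclass(frozen=True)
class GeometricEllipse:
    center: Point2D
    semi_major: float
    semi_minor: float
    theta: float  # major-axis orientation, radians, in [0, pi)

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise GeometryError(
                f"invalid axes (a={self.semi_major}, b={self.semi_minor})"
            )
        if not (0.0 <= self.theta < math.pi):
            raise GeometryError(f"theta {self.theta} outside [0, pi)")

    def boundary_points(self, n: int) -> np.ndarray:
        """n points on the ellipse, uniformly spaced in parametric angle."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        ct, st = math.cos(self.theta), math.sin(self.theta)
        x = self.center.x + self.semi_major * np.cos(t) * ct - self.semi_minor * np.sin(t) * st
        y = self.center.y + self.semi_major * np.cos(t) * st + self.semi_minor * np.sin(t) * ct
        return np.column_stack([x, y])


@dataclass(frozen=True)
class AoPKeyPoints:
    Up: Point2D
    Lp: Point2D
    Tp: Point2D


class AoPStatus(str, enum.Enum):
    ok = "ok"
    ps_fit_failed = "ps_fit_failed"
    fh_fit_failed = "fh_fit_failed"
    lp_inside_fh = "lp_inside_fh"
    empty_class = "empty_class"


@dataclass(frozen=True)
class AoPResult:
    status: AoPStatus
    aop_deg: float | None = None
    keypoints: AoPKeyPoints | None = None
    ps_ellipse: GeometricEllipse | None = None
    fh_ellipse: GeometricEllipse | None = None


# ---------------------------------------------------------------------------
# boundary extraction


def mask_to_boundary(mask: np.ndarray, class_id: int) -> np.ndarray:
    """Boundary pixel centers of the largest 8-connected component of a class.

    A boundary pixel is a component pixel with at least one 4-neighbor outside
    the component; the image border counts as outside.  Returns an (n, 2)
    array of (x, y) pixel-center coordinates.
    """
    mask = np.asarray(mask)
    binary = mask == class_id
    if not binary.any():
        raise EmptyClassError(f"mask has no pixels of class {class_id}")
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        comp = labels == (int(np.argmax(sizes)) + 1)
    else:
        comp = labels == 1
    interior = (
        comp
        & np.roll(comp, 1, axis=0)
        & np.roll(comp, -1, axis=0)
        & np.roll(comp, 1, axis=1)
        & np.roll(comp, -1, axis=1)
    )
    # np.roll wraps; border pixels must never count as interior
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    rows, cols = np.nonzero(comp & ~interior)
    return np.column_stack([cols, rows]).astype(float)


# ---------------------------------------------------------------------------
# direct least-squares ellipse fitting (conic constraint 4AC - B^2 = 1)


def fit_ellipse(points: Sequence | np.ndarray) -> ConicCoefficients:
    """Fit an ellipse to scattered points by direct least squares.

    Minimizes the algebraic residual ``sum_i F(a, x_i)^2`` subject to the
    quadratic constraint ``4AC - B^2 = 1``, which forces an elliptical
    solution.  Solved via the numerically stable block decomposition of the
    generalized eigenproblem (Halir & Flusser formulation); data are centered
    on their centroid first for conditioning.
    """
    pts = _as_points_array(points)
    if pts.shape[0] < 5:
        raise EllipseFitError(f"need >= 5 points, got {pts.shape[0]}")
    mean = pts.mean(axis=0)
    x = pts[:, 0] - mean[0]
    y = pts[:, 1] - mean[1]

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate point configuration") from exc
    M = S1 + S2 @ T
    # inverse of the constraint matrix [[0,0,2],[0,-1,0],[2,0,0]] applied row-wise
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    # the ellipse solution is the eigenvector with 4ac - b^2 > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    valid = np.nonzero((cond > 0) & np.isfinite(eigval) & (np.abs(eigval.imag) == 0))[0]
    if valid.size == 0:
        raise EllipseFitError("no elliptical eigensolution")
    a1 = eigvec[:, valid[0]].real
    a = np.concatenate([a1, T @ a1])

    # undo the centroid shift: substitute x -> x - mx, y -> y - my
    A, B, C, D, E, F = a
    mx, my = mean
    D0 = D - 2.0 * A * mx - B * my
    E0 = E - 2.0 * C * my - B * mx
    F0 = F + A * mx * mx + B * mx * my + C * my * my - D * mx - E * my
    a = np.array([A, B, C, D0, E0, F0])

    k = 4.0 * a[0] * a[2] - a[1] ** 2
    if k <= 0:
        raise EllipseFitError("fitted conic is not an ellipse")
    a = a / math.sqrt(k)
    if a[0] < 0:
        a = -a
    return ConicCoefficients(*a)


def _as_points_array(points: Sequence | np.ndarray) -> np.ndarray:
    if isinstance(points, np.ndarray):
        return points.astype(float).reshape(-1, 2)
    return np.array(
        [(p.x, p.y) if isinstance(p, Point2D) else tuple(p) for p in points],
        dtype=float,
    ).reshape(-1, 2)


def conic_to_geometric(conic: ConicCoefficients) -> GeometricEllipse:
    """Convert algebraic conic coefficients to center/axes/orientation form."""
    A, B, C, D, E, F = conic.as_array()
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    try:
        center = np.linalg.solve(2.0 * M, -np.array([D, E]))
    except np.linalg.LinAlgError as exc:
        raise DegenerateConicError("singular quadratic form") from exc
    x0, y0 = center
    Fc = A * x0 * x0 + B * x0 * y0 + C * y0 * y0 + D * x0 + E * y0 + F
    if not Fc < 0:
        raise DegenerateConicError("conic has no real points (imaginary ellipse)")
    eigval, eigvec = np.linalg.eigh(M)  # ascending; both > 0 for an ellipse
    if eigval[0] <= 0:
        raise DegenerateConicError("quadratic form not positive definite")
    semi_major = math.sqrt(-Fc / eigval[0])
    semi_minor = math.sqrt(-Fc / eigval[1])
    if semi_major - semi_minor <= _CIRCLE_TIE_EPS * semi_major:
        theta = 0.0  # circles have no preferred axis: fix theta deterministically
    else:
        vx, vy = eigvec[:, 0]  # eigenvector of the smaller eigenvalue = major axis
        theta = math.atan2(vy, vx) % math.pi
        if theta >= math.pi:  # guard the wrap at pi from rounding
            theta = 0.0
    return GeometricEllipse(Point2D(x0, y0), semi_major, semi_minor, theta)


def geometric_to_conic(e: GeometricEllipse) -> ConicCoefficients:
    """Inverse of :func:`conic_to_geometric`, normalized to ``4AC - B^2 = 1``."""
    ct, st = math.cos(e.theta), math.sin(e.theta)
    R = np.array([[ct, -st], [st, ct]])
    M = R @ np.diag([1.0 / e.semi_major**2, 1.0 / e.semi_minor**2]) @ R.T
    c = e.center.as_array()
    A = M[0, 0]
    B = 2.0 * M[0, 1]
    C = M[1, 1]
    D, E = -2.0 * M @ c
    F = c @ M @ c - 1.0
    a = np.array([A, B, C, D, E, F])
    a = a / math.sqrt(4.0 * A * C - B * B)
    return ConicCoefficients(*a)


# ---------------------------------------------------------------------------
# key points


def major_axis_endpoints(e: GeometricEllipse) -> tuple[Point2D, Point2D]:
    """The two endpoints of the major axis, ``center +/- a (cos t, sin t)``."""
    d = np.array([math.cos(e.theta), math.sin(e.theta)]) * e.semi_major
    c = e.center.as_array()
    p_minus, p_plus = c - d, c + d
    return Point2D(*p_minus), Point2D(*p_plus)


def label_endpoints(
    p1: Point2D, p2: Point2D, fh_center: Point2D
) -> tuple[Point2D, Point2D]:
    """Assign (Up, Lp): Lp is the endpoint nearer the fetal-head center.

    The inferior PS endpoint abuts the descending head, so proximity to the
    FH center identifies it regardless of image orientation.  Ties go to the
    endpoint with larger x, then larger y.
    """
    if p1 == p2:
        raise GeometryError("degenerate axis: identical endpoints")
    d1 = np.hypot(p1.x - fh_center.x, p1.y - fh_center.y)
    d2 = np.hypot(p2.x - fh_center.x, p2.y - fh_center.y)
    if d1 != d2:
        lp, up = (p1, p2) if d1 < d2 else (p2, p1)
    elif (p1.x, p1.y) != (p2.x, p2.y):
        lp, up = (p1, p2) if (p1.x, p1.y) > (p2.x, p2.y) else (p2, p1)
    return up, lp


def tangent_points(p: Point2D, e: GeometricEllipse) -> tuple[Point2D, Point2D]:
    """Both points where tangent lines from an external point touch the ellipse.

    Uses the polar line of ``p`` with respect to the conic: the chord of
    contact.  Its two intersections with the ellipse are the tangency points.
    """
    conic = geometric_to_conic(e)
    if conic.evaluate(p) <= 0:
        raise TangentError("point inside or on the ellipse: no tangent")
    Q = conic.matrix()
    ph = np.array([p.x, p.y, 1.0])
    line = Q @ ph  # polar line (l0, l1, l2): l0 x + l1 y + l2 = 0
    pts = _line_conic_intersections(line, Q)
    if pts.shape[0] != 2:
        raise TangentError("polar line does not meet the ellipse in two points")
    t1, t2 = Point2D(*pts[0]), Point2D(*pts[1])
    return t1, t2


def _line_conic_intersections(line: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Intersect line l0 x + l1 y + l2 = 0 with conic x^T Q x = 0."""
    l0, l1, l2 = line
    n = np.array([l0, l1])
    nn = n @ n
    if nn == 0:
        return np.empty((0, 2))
    p0 = -l2 * n / nn  # foot of the line closest to origin
    d = np.array([-l1, l0]) / math.sqrt(nn)  # unit direction along the line
    p0h = np.array([p0[0], p0[1], 1.0])
    dh = np.array([d[0], d[1], 0.0])
    qa = dh @ Q @ dh
    qb = 2.0 * (dh @ Q @ p0h)
    qc = p0h @ Q @ p0h
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0 or qa == 0:
        return np.empty((0, 2))
    r = math.sqrt(max(disc, 0.0))
    t1 = (-qb - r) / (2.0 * qa)
    t2 = (-qb + r) / (2.0 * qa)
    return np.array([p0 + t1 * d, p0 + t2 * d])


def select_tangent(Up: Point2D, Lp: Point2D, t1: Point2D, t2: Point2D) -> Point2D:
    """Pick the tangency point defining the AoP.

    The clinically measured tangent runs along the leading (advancing) head
    contour, which is the candidate giving the larger angle at Lp; the
    near-side tangent gives the smaller one.  Ties break to larger x.
    """
    a1 = compute_aop(AoPKeyPoints(Up, Lp, t1))
    a2 = compute_aop(AoPKeyPoints(Up, Lp, t2))
    if a1 != a2:
        return t1 if a1 > a2 else t2
    return t1 if (t1.x, t1.y) >= (t2.x, t2.y) else t2


def compute_aop(k: AoPKeyPoints) -> float:
    """Angle at Lp between rays Lp->Up and Lp->Tp, in degrees [0, 180]."""
    u = k.Up.as_array() - k.Lp.as_array()
    v = k.Tp.as_array() - k.Lp.as_array()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("zero-length ray in AoP computation")
    c = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


# ---------------------------------------------------------------------------
# end-to-end mask -> AoP


def measure_aop_from_mask(mask: np.ndarray, tangent_rule: str = "max-angle") -> AoPResult:
    """Measure the AoP from a 3-class label mask (0 bg, 1 PS, 2 FH).

    Pipeline: boundary extraction -> constrained least-squares ellipse fit for
    PS and FH -> PS major-axis endpoints -> tangent from the inferior endpoint
    to the FH ellipse -> angle.  Failures are reported through ``status``;
    this function never raises for content-related problems.

    ``tangent_rule`` selects between the orientation-invariant ``max-angle``
    tangency point (default) and the literal ``right-x`` (larger-x) one;
    the two coincide for standard acquisition orientation.
    """
    if tangent_rule not in ("max-angle", "right-x"):
        raise ValueError(f"unknown tangent rule {tangent_rule!r}")
    try:
        ps_pts = mask_to_boundary(mask, PS_CLASS)
        fh_pts = mask_to_boundary(mask, FH_CLASS)
    except EmptyClassError:
        return AoPResult(status=AoPStatus.empty_class)
    try:
        ps_ellipse = conic_to_geometric(fit_ellipse(ps_pts))
    except GeometryError:
        return AoPResult(status=AoPStatus.ps_fit_failed)
    try:
        fh_ellipse = conic_to_geometric(fit_ellipse(fh_pts))
    except GeometryError:
        return AoPResult(status=AoPStatus.fh_fit_failed, ps_ellipse=ps_ellipse)
    p1, p2 = major_axis_endpoints(ps_ellipse)
    up, lp = label_endpoints(p1, p2, fh_ellipse.center)
    try:
        t1, t2 = tangent_points(lp, fh_ellipse)
    except TangentError:
        return AoPResult(
            status=AoPStatus.lp_inside_fh, ps_ellipse=ps_ellipse, fh_ellipse=fh_ellipse
        )
    if tangent_rule == "max-angle":
        tp = select_tangent(up, lp, t1, t2)
    else:
        tp = t1 if (t1.x, t1.y) >= (t2.x, t2.y) else t2
    keypoints = AoPKeyPoints(up, lp, tp)
    return AoPResult(
        status=AoPStatus.ok,
        aop_deg=compute_aop(keypoints),
        keypoints=keypoints,
        ps_ellipse=ps_ellipse,
        fh_ellipse=fh_ellipse,
    )


def analytic_aop(
    ps: GeometricEllipse, fh: GeometricEllipse, tangent_rule: str = "max-angle"
) -> tuple[float, AoPKeyPoints]:
    """AoP from exact ellipse parameters (no rasterization).

    Same key-point construction as :func:`measure_aop_from_mask` but applied
    to closed-form ellipses; raises on geometric failure instead of returning
    a status.
    """
    p1, p2 = major_axis_endpoints(ps)
    up, lp = label_endpoints(p1, p2, fh.center)
    t1, t2 = tangent_points(lp, fh)
    if tangent_rule == "max-angle":
        tp = select_tangent(up, lp, t1, t2)
    else:
        tp = t1 if (t1.x, t1.y) >= (t2.x, t2.y) else t2
    k = AoPKeyPoints(up, lp, tp)
    return compute_aop(k), k
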