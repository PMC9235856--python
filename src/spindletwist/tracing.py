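"""Oblique-circle quantification of traced microtubule bundles.

Each bundle is an ordered list of points clicked along the bundle contour
in the end-on view. After calibration and untilting (see
:mod:`spindletwist.geometry`), a total-least-squares plane is fitted to
the points, then a circle lying in that plane. From the two fits:

* curvature = 1 / R, with R the fitted circle radius;
* |twist| = beta / rho_bar, where beta is the angle between the fitted
  plane and the spindle (z) axis and rho_bar the mean distance of the
  points from that axis, in degrees per micrometre;
* the sign of the twist is the sign of the mean azimuthal advance per
  unit z along the ordered trace: negative = clockwise when moving toward
  the observer = left-handed;
* contour length = length of the fitted circular arc plus the distance of
  each bundle end from its nearer pole.

A straight (collinear) bundle is achiral: it gets twist 0 and curvature 0
and is flagged rather than rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .geometry import (
    Calibration,
    PixelPoint,
    PolePair,
    SpindleFrame,
    calibrate_points,
    untilt,
)

__all__ = [
    "BundleTrace",
    "ObliqueCircleFit",
    "SpindleTwistSummary",
    "DegeneratePlaneError",
    "fit_plane",
    "fit_circle_in_plane",
    "bundle_twist_sign",
    "analyze_bundle",
    "analyze_spindle",
]

#: Mean axial distance (um) below which beta/rho_bar is numerically
#: unstable and the twist is flagged unreliable.
DEFAULT_RHO_MIN_UM = 0.25

#: Relative eigenvalue threshold declaring a point set collinear.
_COLLINEAR_RTOL = 1e-12


class DegeneratePlaneError(ValueError):
    """Raised when fewer than 3 points or an empty spindle is analyzed."""


@dataclass(frozen=True)
class BundleTrace:
    """Ordered pixel-space points of one traced bundle."""

    bundle_id: str
    points: tuple[PixelPoint, ...]
    spindle_id: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError(
                f"bundle {self.bundle_id!r}: a trace needs >= 3 points, "
                f"got {len(self.points)}"
            )
        planes = [p.plane for p in self.points]
        if any(b < a for a, b in zip(planes, planes[1:])):
            raise ValueError(
                f"bundle {self.bundle_id!r}: plane indices must be "
                "monotonically non-decreasing along the trace"
            )

    @property
    def xy_px(self) -> np.ndarray:
        return np.array([[p.x_px, p.y_px] for p in self.points])

    @property
    def planes(self) -> np.ndarray:
        return np.array([p.plane for p in self.points], dtype=float)


@dataclass
class ObliqueCircleFit:
    """Plane + in-plane circle fit of one bundle, with derived quantities.

    ``radius`` is ``inf`` and ``curvature`` 0 for a straight bundle.
    ``beta_deg`` is the angle between the fitted plane and the z axis
    (0 for a plane containing the z direction). ``rho_mean_um`` is the
    mean distance of the (untilted, calibrated) points from the z axis.
    """

    bundle_id: str
    plane_normal: np.ndarray
    plane_offset: float
    center: np.ndarray
    radius: float
    beta_deg: float
    rho_mean_um: float
    twist_deg_per_um: float
    curvature_per_um: float
    contour_length_um: float
    rms_residual_um: float
    flags: list[str] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags


@dataclass
class SpindleTwistSummary:
    """Per-spindle aggregate of bundle twists (unweighted mean +- SEM)."""

    spindle_id: str
    bundle_twists: np.ndarray
    mean_twist: float
    sem: float
    n_bundles: int
    twist_class: str


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through >= 3 points.

    Returns (unit normal, offset) with the plane {x : n.x = offset}. The
    normal is the direction of smallest scatter through the centroid,
    oriented so its z component is >= 0 (ties broken toward +x).

    Raises
    ------
    DegeneratePlaneError
        If the points are (numerically) collinear, in which case no plane
        is defined; callers treat the bundle as straight.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegeneratePlaneError("plane fit needs >= 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # singular values sorted descending; eigenvalues of the scatter matrix
    # are their squares
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    ev = s**2
    if ev[1] < _COLLINEAR_RTOL * ev[0] and ev[2] < _COLLINEAR_RTOL * ev[0]:
        raise DegeneratePlaneError("points are collinear; no unique plane")
    normal = vt[2]
    if normal[2] < 0 or (normal[2] == 0 and normal[0] < 0):
        normal = -normal
    return normal, float(np.dot(normal, centroid))


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (e1, e2) with e1 x e2 = normal."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def _kasa_circle(uv: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit in 2D; raises LinAlgError if singular."""
    u, v = uv[:, 0], uv[:, 1]
    A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    b = u**2 + v**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cu, cv, c = sol
    r2 = c + cu**2 + cv**2
    if not r2 > 0 or not np.isfinite(r2):
        raise np.linalg.LinAlgError("degenerate circle")
    return np.array([cu, cv]), float(np.sqrt(r2))


def fit_circle_in_plane(
    points: np.ndarray, normal: np.ndarray, offset: float
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Fit a circle lying in the given plane to 3D points.

    Points are projected orthogonally into the plane; the circle is fitted
    algebraically (Kasa) and refined by least orthogonal distances.

    Returns ``(center3d, radius, projected_points, rms_residual)``.
    ``radius`` is ``inf`` when the projected points are collinear in-plane
    (straight bundle limit); the caller maps that to curvature 0.
    """
    pts = np.asarray(points, dtype=float)
    foot = pts - np.outer(pts @ normal - offset, normal)
    e1, e2 = _plane_basis(normal)
    origin = foot.mean(axis=0)
    uv = np.column_stack([(foot - origin) @ e1, (foot - origin) @ e2])

    # in-plane collinearity -> infinite radius
    s = np.linalg.svd(uv - uv.mean(axis=0), compute_uv=False)
    if len(s) < 2 or s[1] ** 2 < 1e-10 * s[0] ** 2:
        return origin, math.inf, foot, 0.0

    try:
        c0, r0 = _kasa_circle(uv)
    except np.linalg.LinAlgError:
        return origin, math.inf, foot, 0.0

    def resid(p: np.ndarray) -> np.ndarray:
        return np.hypot(uv[:, 0] - p[0], uv[:, 1] - p[1]) - p[2]

    sol = least_squares(resid, x0=[c0[0], c0[1], r0], method="lm")
    cu, cv, r = sol.x
    if not np.isfinite(r) or r <= 0 or r > 1e6:
        return origin, math.inf, foot, float(np.sqrt(np.mean(sol.fun**2)))
    center3d = origin + cu * e1 + cv * e2
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return center3d, float(r), foot, rms


def bundle_twist_sign(points: np.ndarray) -> float:
    """Sign of the mean azimuthal advance per unit z along a trace.

    theta is the azimuth about the z axis, unwrapped along the ordered
    trace; the sign is that of the least-squares slope of theta against z.
    Negative means clockwise when moving toward the observer (+z), i.e.
    left-handed. Returns 0.0 for traces with no z extent.
    """
    pts = np.asarray(points, dtype=float)
    theta = np.unwrap(np.arctan2(pts[:, 1], pts[:, 0]))
    z = pts[:, 2]
    dz = z - z.mean()
    denom = np.dot(dz, dz)
    if denom < 1e-18:
        return 0.0
    slope = np.dot(dz, theta - theta.mean()) / denom
    return float(np.sign(slope))


def _arc_length(
    uv_center: np.ndarray, radius: float, uv_points: np.ndarray
) -> float:
    """Length of the fitted arc spanned by the trace.

    The arc runs between the projections of the first and last trace
    points; of the two candidate arcs, the one containing the projected
    interior points is used.
    """
    ang = np.arctan2(
        uv_points[:, 1] - uv_center[1], uv_points[:, 0] - uv_center[0]
    )
    a0, a1 = ang[0], ang[-1]
    ccw_span = (a1 - a0) % (2 * math.pi)
    interior = (ang[1:-1] - a0) % (2 * math.pi)
    n_in_ccw = int(np.sum(interior <= ccw_span))
    n_in_cw = int(np.sum(interior >= ccw_span))
    span = ccw_span if n_in_ccw >= n_in_cw else 2 * math.pi - ccw_span
    return float(radius * span)


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _end_to_pole_distances(
    points: np.ndarray, pole1: np.ndarray, pole2: np.ndarray
) -> float:
    ends = points[[0, -1]]
    d = 0.0
    for e in ends:
        d += min(np.linalg.norm(e - pole1), np.linalg.norm(e - pole2))
    return d


def analyze_bundle(
    bundle_id: str,
    points_um: np.ndarray,
    pole1: np.ndarray = np.zeros(3),
    pole2: np.ndarray | None = None,
    rho_min_um: float = DEFAULT_RHO_MIN_UM,
) -> ObliqueCircleFit:
    """Run the oblique-circle method on calibrated, untilted points.

    ``points_um`` must be in the canonical frame (poles on the z axis).
    ``pole1``/``pole2`` are the pole positions in that frame, used only
    for the contour length.
    """
    pts = np.asarray(points_um, dtype=float)
    if pole2 is None:
        pole2 = np.array([0.0, 0.0, pts[:, 2].max()])
    rho = np.hypot(pts[:, 0], pts[:, 1])
    rho_mean = float(rho.mean())
    flags: list[str] = []

    end_dist = _end_to_pole_distances(pts, pole1, pole2)

    try:
        normal, offset = fit_plane(pts)
    except DegeneratePlaneError:
        # straight bundle: achiral by convention
        return ObliqueCircleFit(
            bundle_id=bundle_id,
            plane_normal=np.full(3, np.nan),
            plane_offset=np.nan,
            center=np.full(3, np.nan),
            radius=math.inf,
            beta_deg=0.0,
            rho_mean_um=rho_mean,
            twist_deg_per_um=0.0,
            curvature_per_um=0.0,
            contour_length_um=_polyline_length(pts) + end_dist,
            rms_residual_um=0.0,
            flags=["degenerate"],
        )

    # angle between the plane and the z axis: 0 when the plane contains
    # the z direction (normal perpendicular to z), 90 for an axial slice
    beta = float(np.degrees(np.arcsin(abs(np.clip(normal[2], -1, 1)))))

    center, radius, foot, rms = fit_circle_in_plane(pts, normal, offset)
    curvature = 0.0 if math.isinf(radius) else 1.0 / radius

    if rho_mean < rho_min_um:
        flags.append("unreliable_twist")
        twist = math.nan
    else:
        twist = bundle_twist_sign(pts) * beta / rho_mean

    if math.isinf(radius):
        flags.append("straight")
        contour = _polyline_length(pts) + end_dist
    else:
        e1, e2 = _plane_basis(normal)
        uv_pts = np.column_stack([(foot - center) @ e1, (foot - center) @ e2])
        contour = _arc_length(np.zeros(2), radius, uv_pts) + end_dist

    return ObliqueCircleFit(
        bundle_id=bundle_id,
        plane_normal=normal,
        plane_offset=offset,
        center=center,
        radius=radius,
        beta_deg=beta,
        rho_mean_um=rho_mean,
        twist_deg_per_um=twist,
        curvature_per_um=curvature,
        contour_length_um=contour,
        rms_residual_um=rms,
        flags=flags,
    )


def analyze_spindle(
    traces: list[BundleTrace],
    poles_px: tuple[PixelPoint, PixelPoint],
    calibration: Calibration | None = None,
    rho_min_um: float = DEFAULT_RHO_MIN_UM,
) -> tuple[SpindleTwistSummary, list[ObliqueCircleFit], SpindleFrame]:
    """Full bundle-tracing pipeline for one spindle.

    Calibrates the pole and trace annotations, untilts the spindle, fits
    every bundle, and aggregates the per-bundle twists into an unweighted
    mean with SEM (sd / sqrt(n)).
    """
    from .stats import classify_twist  # local import: no module cycle

    if calibration is None:
        calibration = Calibration()
    if not traces:
        raise DegeneratePlaneError("no traces supplied")

    p1, p2 = poles_px
    if p1.plane > p2.plane:
        p1, p2 = p2, p1
    poles = PolePair(
        pole1=calibrate_points(
            np.array([[p1.x_px, p1.y_px]]), np.array([p1.plane]), calibration
        )[0],
        pole2=calibrate_points(
            np.array([[p2.x_px, p2.y_px]]), np.array([p2.plane]), calibration
        )[0],
        source_px=(p1, p2),
    )
    frame, _ = untilt(None, poles)
    pole1_c = frame.apply(poles.pole1)[0]
    pole2_c = frame.apply(poles.pole2)[0]

    fits = []
    for tr in traces:
        pts = calibrate_points(tr.xy_px, tr.planes, calibration)
        pts_c = frame.apply(pts)
        fits.append(
            analyze_bundle(
                tr.bundle_id, pts_c, pole1_c, pole2_c, rho_min_um=rho_min_um
            )
        )

    # flagged bundles (straight, or too close to the axis) stay in the
    # per-bundle table but do not enter the spindle mean
    twists = np.array(
        [
            f.twist_deg_per_um
            for f in fits
            if not f.flags and np.isfinite(f.twist_deg_per_um)
        ]
    )
    if twists.size == 0:
        raise DegeneratePlaneError(
            "all traces degenerate or unreliable; no twist summary"
        )
    mean = float(twists.mean())
    sem = (
        float(twists.std(ddof=1) / np.sqrt(twists.size))
        if twists.size >= 2
        else math.nan
    )
    summary = SpindleTwistSummary(
        spindle_id=traces[0].spindle_id,
        bundle_twists=twists,
        mean_twist=mean,
        sem=sem,
        n_bundles=int(twists.size),
        twist_class=classify_twist(mean).value,
    )
    return summary, fits, frame
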