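"""Calibration and rigid-frame geometry for end-on spindle stacks.

Annotations (bundle traces, pole positions) come in pixel/plane coordinates
of a z-stack acquired end-on, i.e. with the imaging planes roughly
perpendicular to the pole-to-pole axis. This module converts them to a
physical, right-handed coordinate frame in micrometres and rigidly rotates
("untilts") the spindle so the pole-to-pole axis coincides with +z. All
chirality measurements downstream are defined in that canonical frame.

Conventions
-----------
* +z points toward the observer of the end-on view; plane index grows
  toward the observer.
* Image rows grow downward, so the physical y coordinate is ``-row * pixel
  size``; this keeps the frame right-handed and makes "bundles rotating
  clockwise when moving toward the observer" (left-handed chirality)
  correspond to a negative d(theta)/dz.
* The axial step between planes is corrected for the refractive-index
  mismatch between immersion oil and aqueous sample by a constant factor
  (0.81 by default), so z = plane * plane_spacing * z_correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Calibration",
    "PixelPoint",
    "PolePair",
    "SpindleFrame",
    "InvalidAnnotationError",
    "DegenerateAxisError",
    "calibrate_point",
    "calibrate_points",
    "compute_tilt",
    "untilt",
    "spindle_length",
    "width_length_ratio",
]

#: Tilt (degrees) above which a spindle is flagged as unreliably oriented
#: for end-on analysis. Spindles are selected to have both poles close to
#: the same plane; larger tilts indicate the stack is not truly end-on.
DEFAULT_MAX_TILT_DEG = 20.0


class InvalidAnnotationError(ValueError):
    """A pixel/plane annotation violates its constraints (e.g. plane < 0)."""


class DegenerateAxisError(ValueError):
    """The two pole annotations coincide; no spindle axis is defined."""


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a z-stack.

    Parameters
    ----------
    pixel_size_xy : float
        Lateral pixel size in micrometres per pixel (default 0.083, i.e.
        83 nm).
    plane_spacing : float
        Nominal axial distance between successive planes in micrometres
        (default 0.5).
    z_correction : float
        Dimensionless refractive-index correction applied to axial
        distances (default 0.81). The effective axial step is
        ``plane_spacing * z_correction``.
    """

    pixel_size_xy: float = 0.083
    plane_spacing: float = 0.5
    z_correction: float = 0.81

    def __post_init__(self) -> None:
        for name in ("pixel_size_xy", "plane_spacing", "z_correction"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def dz_um(self) -> float:
        """Corrected axial distance between successive planes (um)."""
        return self.plane_spacing * self.z_correction


@dataclass(frozen=True)
class PixelPoint:
    """A point annotated in image coordinates: column, row, plane index.

    ``plane`` is an integer slice index for manual annotations, but float
    values are accepted (e.g. interpolated or synthetic annotations).
    """

    x_px: float
    y_px: float
    plane: float

    def __post_init__(self) -> None:
        if self.plane < 0:
            raise InvalidAnnotationError(
                f"plane index must be >= 0, got {self.plane}"
            )


@dataclass(frozen=True)
class PolePair:
    """Calibrated spindle poles. pole1 is the far pole (lower plane index),
    pole2 the near pole toward the observer."""

    pole1: np.ndarray
    pole2: np.ndarray
    source_px: tuple[PixelPoint, PixelPoint] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pole1", np.asarray(self.pole1, dtype=float))
        object.__setattr__(self, "pole2", np.asarray(self.pole2, dtype=float))
        if not np.linalg.norm(self.pole2 - self.pole1) > 0:
            raise DegenerateAxisError("spindle poles coincide")

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from pole1 to pole2."""
        v = self.pole2 - self.pole1
        return v / np.linalg.norm(v)

    @property
    def separation(self) -> float:
        return float(np.linalg.norm(self.pole2 - self.pole1))


@dataclass(frozen=True)
class SpindleFrame:
    """Rigid transform into the canonical spindle frame.

    Applying the frame maps pole1 to the origin and pole2 to (0, 0, L)
    where L is the pole separation. ``tilt_deg`` is the angle between the
    pole-to-pole axis and the optical (+z) axis before untilting.
    """

    rotation: np.ndarray
    translation: np.ndarray
    tilt_deg: float
    pole_separation: float
    max_tilt_deg: float = DEFAULT_MAX_TILT_DEG
    tilt_flagged: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rotation", np.asarray(self.rotation, dtype=float)
        )
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(
            self, "tilt_flagged", bool(self.tilt_deg > self.max_tilt_deg)
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of points into the canonical frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.translation) @ self.rotation.T


def calibrate_point(p: PixelPoint, c: Calibration) -> np.ndarray:
    """Convert a pixel/plane annotation to physical coordinates (um).

    x = x_px * pixel_size, y = -y_px * pixel_size (right-handed frame with
    image rows growing downward), z = plane * plane_spacing * z_correction.
    """
    if p.plane < 0:
        raise InvalidAnnotationError("plane index must be >= 0")
    return np.array(
        [
            p.x_px * c.pixel_size_xy,
            -p.y_px * c.pixel_size_xy,
            p.plane * c.plane_spacing * c.z_correction,
        ]
    )


def calibrate_points(
    xy_px: np.ndarray, planes: np.ndarray, c: Calibration
) -> np.ndarray:
    """Vectorised :func:`calibrate_point` for (N, 2) pixel coords + planes."""
    xy_px = np.asarray(xy_px, dtype=float)
    planes = np.asarray(planes, dtype=float)
    if np.any(planes < 0):
        raise InvalidAnnotationError("plane indices must be >= 0")
    out = np.empty((len(planes), 3))
    out[:, 0] = xy_px[:, 0] * c.pixel_size_xy
    out[:, 1] = -xy_px[:, 1] * c.pixel_size_xy
    out[:, 2] = planes * c.plane_spacing * c.z_correction
    return out


def compute_tilt(poles: PolePair) -> float:
    """Angle (degrees, 0-90) between the pole-to-pole axis and +z.

    The sign/direction of the axis is ignored: a spindle pointing 170 deg
    from +z is tilted 10 deg from the optical axis.
    """
    axis = poles.axis
    cos_t = abs(np.clip(axis[2], -1.0, 1.0))
    return float(np.degrees(np.arccos(cos_t)))


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking a unit vector onto +z.

    Rotates about the axis perpendicular to both; identity if already
    aligned. For an anti-aligned axis, a 180-degree rotation about x.
    """
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(axis, z))
    if c > 1.0 - 1e-15:
        return np.eye(3)
    if c < -1.0 + 1e-15:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    vx = np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
    )
    # Rodrigues formula for the rotation by angle arccos(c) about v/s
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def untilt(
    points: np.ndarray | None,
    poles: PolePair,
    max_tilt_deg: float = DEFAULT_MAX_TILT_DEG,
) -> tuple[SpindleFrame, np.ndarray | None]:
    """Rigidly transform points so pole1 -> origin and pole2 -> (0, 0, L).

    Returns the :class:`SpindleFrame` and the transformed points (or None
    if no points were given). Distances are preserved exactly up to
    floating point.
    """
    tilt = compute_tilt(poles)
    R = _rotation_to_z(poles.axis)
    frame = SpindleFrame(
        rotation=R,
        translation=poles.pole1,
        tilt_deg=tilt,
        pole_separation=poles.separation,
        max_tilt_deg=max_tilt_deg,
    )
    transformed = None if points is None else frame.apply(points)
    return frame, transformed


def spindle_length(poles: PolePair) -> float:
    """Pole-to-pole Euclidean distance in micrometres."""
    return poles.separation


def width_length_ratio(width_um: float, length_um: float) -> float:
    """Spindle equatorial width divided by pole-to-pole length.

    Rounder spindles (ratio near 1) carry larger bending moments; the
    ratio is the abscissa of twist-vs-shape regressions.
    """
    if not length_um > 0:
        raise ValueError("spindle length must be positive")
    return width_um / length_um
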