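"""Ground-truth synthetic chiral spindles.

Two forward models provide known-answer inputs for the twist estimators:

* **Helix model** (:func:`generate_traces`): each bundle winds around the
  pole-to-pole axis at a constant azimuthal rate omega (deg/um of z, the
  ground-truth twist; negative = left-handed), with a barrel-shaped
  radial profile rho(z) = rho_max * (4 z (L - z) / L^2)^e reproducing the
  rounded outline of a metaphase spindle. Default dimensions follow
  typical HeLa metaphase spindles (length 11.5 um, width 9 um).

* **Tilted-circle model** (:func:`generate_tilted_circle_trace`): points
  placed exactly on a circle of radius R lying in a plane making angle
  beta with the z axis, at mean axial distance rho_bar, so that the
  oblique-circle twist identity |twist| = beta / rho_bar and curvature =
  1/R hold exactly. This is the analytic oracle for the tracing method.

Traces are emitted in pixel/plane units by inverse calibration, exactly
as manual annotations would be. :func:`render_stack` turns traces into a
16-bit image stack (Gaussian spots + background + seeded shot/read
noise) for the optical-flow pipeline; :func:`rotate_stack` builds a
pure-rotation stack, the sharpest oracle for the flow method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import brentq

from .geometry import Calibration, PixelPoint
from .flow import ImageStack
from .tracing import BundleTrace, bundle_twist_sign

__all__ = [
    "SyntheticSpindleParams",
    "GroundTruth",
    "generate_traces",
    "generate_tilted_circle_trace",
    "render_stack",
    "rotate_stack",
    "mirror_stack",
]


@dataclass
class SyntheticSpindleParams:
    """Parameters of the helix-model spindle generator.

    ``twist_deg_per_um`` is the ground-truth azimuthal rate omega;
    ``bundle_z_fraction`` is the central fraction of the pole-to-pole
    length spanned by the bundles (bundles are a few um long, not
    pole-to-pole). Noise defaults give a per-bundle peak SNR of roughly
    10. ``seed`` fixes all randomness.
    """

    n_bundles: int = 12
    twist_deg_per_um: float = -2.0
    length_um: float = 11.5
    rho_max_um: float = 4.5
    barrel_exponent: float = 0.5
    bundle_z_fraction: float = 0.6
    amplitude: float = 400.0
    background: float = 100.0
    static_texture_amplitude: float = 0.0
    psf_sigma_um: float = 0.25
    gaussian_noise_sigma: float = 30.0
    poisson_noise: bool = True
    tilt_deg: float = 0.0
    azimuth_jitter_deg: float = 5.0
    pole_margin_planes: int = 2
    seed: int = 0
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.rho_max_um <= 0:
            raise ValueError("length and radius must be positive")
        if self.n_bundles < 1:
            raise ValueError("need at least one bundle")
        if not 0 < self.bundle_z_fraction <= 1:
            raise ValueError("bundle_z_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calibration"] = asdict(self.calibration)
        return d


@dataclass
class GroundTruth:
    """What the generator actually built, for parameter-recovery checks."""

    true_twist_per_bundle: np.ndarray
    true_curvature_per_bundle: np.ndarray
    pole1_px: PixelPoint
    pole2_px: PixelPoint
    length_um: float
    axis_center_px: tuple[float, float]
    field_shape: tuple[int, int]
    n_planes: int


def _field_geometry(
    params: SyntheticSpindleParams,
) -> tuple[int, int, int, float, float, float]:
    """Common stack geometry: field size, plane count, center, actual L."""
    c = params.calibration
    dz = c.dz_um
    half_px = int(math.ceil((params.rho_max_um + 1.5) / c.pixel_size_xy))
    side = 2 * half_px + 1
    n_axis_planes = max(2, int(round(params.length_um / dz)))
    length = n_axis_planes * dz  # snapped so poles sit on integer planes
    n_planes = n_axis_planes + 2 * params.pole_margin_planes + 1
    center = float(half_px)
    return side, n_planes, params.pole_margin_planes, center, length, dz


def generate_traces(
    params: SyntheticSpindleParams,
) -> tuple[list[BundleTrace], tuple[PixelPoint, PixelPoint], GroundTruth]:
    """Build helix-model bundle traces and pole annotations.

    Bundles are evenly spaced in azimuth (with seeded jitter), each
    sampled at every imaging plane inside its z range. Traces are exact:
    no noise is added to the point coordinates (annotation noise is a
    property of stacks, not traces).
    """
    rng = np.random.default_rng(params.seed)
    c = params.calibration
    side, n_planes, margin, center, L, dz = _field_geometry(params)
    omega = math.radians(params.twist_deg_per_um)  # rad per um of z
    tilt = math.radians(params.tilt_deg)

    theta0 = np.linspace(0.0, 2 * math.pi, params.n_bundles, endpoint=False)
    theta0 = theta0 + rng.normal(
        0.0, math.radians(params.azimuth_jitter_deg), params.n_bundles
    )

    z_lo = L * (1 - params.bundle_z_fraction) / 2
    z_hi = L * (1 + params.bundle_z_fraction) / 2

    def to_pixel(p_um: np.ndarray) -> PixelPoint:
        # tilt: rotate about the y axis through the spindle midpoint
        if tilt != 0.0:
            x, y, z = p_um
            zm = z - L / 2
            x, zm = (
                x * math.cos(tilt) + zm * math.sin(tilt),
                -x * math.sin(tilt) + zm * math.cos(tilt),
            )
            p_um = np.array([x, y, zm + L / 2])
        return PixelPoint(
            x_px=center + p_um[0] / c.pixel_size_xy,
            y_px=center - p_um[1] / c.pixel_size_xy,
            plane=margin + p_um[2] / dz,
        )

    traces = []
    for b in range(params.n_bundles):
        pts = []
        for k in range(n_planes):
            z = (k - margin) * dz
            if not z_lo <= z <= z_hi:
                continue
            rho = params.rho_max_um * (
                4 * z * (L - z) / L**2
            ) ** params.barrel_exponent
            th = theta0[b] + omega * z
            pts.append(
                to_pixel(np.array([rho * math.cos(th), rho * math.sin(th), z]))
            )
        traces.append(
            BundleTrace(bundle_id=f"b{b:02d}", points=tuple(pts),
                        spindle_id="synthetic")
        )

    pole1 = to_pixel(np.array([0.0, 0.0, 0.0]))
    pole2 = to_pixel(np.array([0.0, 0.0, L]))
    truth = GroundTruth(
        true_twist_per_bundle=np.full(
            params.n_bundles, params.twist_deg_per_um
        ),
        true_curvature_per_bundle=np.full(params.n_bundles, np.nan),
        pole1_px=pole1,
        pole2_px=pole2,
        length_um=L,
        axis_center_px=(center, center),
        field_shape=(side, side),
        n_planes=n_planes,
    )
    return traces, (pole1, pole2), truth


def generate_tilted_circle_trace(
    beta_deg: float,
    rho_bar_um: float,
    radius_um: float = 5.0,
    n_points: int = 15,
    arc_half_angle_deg: float = 25.0,
    z0_um: float = 6.0,
    left_handed: bool = True,
    calibration: Calibration | None = None,
    bundle_id: str = "oracle",
) -> tuple[BundleTrace, float, float]:
    """Points exactly on a circle in a plane at angle ``beta_deg`` to z.

    The circle center is positioned (by 1D root finding, to ~1e-12 um) so
    the mean distance of the points from the z axis equals
    ``rho_bar_um``; hence the true oblique-circle twist is exactly
    ``beta_deg / rho_bar_um`` in magnitude and the true curvature is
    ``1 / radius_um``. Returns (trace in pixel units, signed true twist,
    true curvature).
    """
    if calibration is None:
        calibration = Calibration()
    c = calibration
    beta = math.radians(beta_deg)
    # plane normal (0, cos b, sin b): its z component is sin(beta), so the
    # angle between the plane and the z axis is exactly beta
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, math.sin(beta), -math.cos(beta)])
    T = math.radians(arc_half_angle_deg)
    # order t descending so z = z0 - R sin(t) cos(beta) increases
    t = np.linspace(T, -T, n_points)
    R = radius_um

    def mean_rho(a: float) -> float:
        x = a + R * np.cos(t)
        y = R * np.sin(t) * math.sin(beta)
        return float(np.mean(np.hypot(x, y)))

    lo, hi = -R + 1e-9, rho_bar_um + R
    a = brentq(lambda a: mean_rho(a) - rho_bar_um, lo, hi, xtol=1e-13)

    center = np.array([a, 0.0, z0_um])
    pts_um = center + R * (np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2))
    if not left_handed:
        pts_um[:, 1] *= -1.0

    sign = bundle_twist_sign(pts_um)
    true_twist = sign * beta_deg / rho_bar_um
    true_curvature = 1.0 / R

    points = tuple(
        PixelPoint(
            x_px=p[0] / c.pixel_size_xy,
            y_px=-p[1] / c.pixel_size_xy,
            plane=p[2] / c.dz_um,
        )
        for p in pts_um
    )
    trace = BundleTrace(bundle_id=bundle_id, points=points,
                        spindle_id="oracle")
    return trace, true_twist, true_curvature


def render_stack(
    traces: list[BundleTrace],
    params: SyntheticSpindleParams,
) -> ImageStack:
    """Render traces into a 16-bit stack: Gaussian spots + noise.

    Each trace point becomes an isotropic 2D Gaussian spot on its
    (nearest) plane; a constant background and seeded Poisson + Gaussian
    noise emulate fluorescence acquisition. Same seed, same stack.

    ``static_texture_amplitude`` > 0 additionally superimposes a smooth
    random texture that is identical in every plane, emulating
    out-of-focus cytoplasmic signal. Static structure has zero motion
    between planes, so it biases the optical-flow twist toward zero --
    the known direction of that method's sensitivity to background.
    """
    c = params.calibration
    side, n_planes, _, _, _, _ = _field_geometry(params)
    sigma_px = params.psf_sigma_um / c.pixel_size_xy
    clean = np.full((n_planes, side, side), params.background, dtype=float)
    if params.static_texture_amplitude > 0:
        from scipy.ndimage import gaussian_filter

        tex_rng = np.random.default_rng(params.seed + 2)
        tex = gaussian_filter(tex_rng.random((side, side)), 3.0)
        tex -= tex.min()
        tex *= params.static_texture_amplitude / max(tex.max(), 1e-12)
        clean += tex[None, :, :]
    win = int(math.ceil(4 * sigma_px))

    for tr in traces:
        for p in tr.points:
            k = int(round(p.plane))
            if not 0 <= k < n_planes:
                raise ValueError(
                    f"bundle {tr.bundle_id!r} leaves the stack at plane "
                    f"{p.plane}"
                )
            r0, c0 = p.y_px, p.x_px
            if not (0 <= r0 < side and 0 <= c0 < side):
                raise ValueError(
                    f"bundle {tr.bundle_id!r} leaves the field of view"
                )
            rr = np.arange(
                max(0, int(r0) - win), min(side, int(r0) + win + 1)
            )
            cc = np.arange(
                max(0, int(c0) - win), min(side, int(c0) + win + 1)
            )
            g = np.exp(
                -(
                    (rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2
                )
                / (2 * sigma_px**2)
            )
            clean[k, rr[0] : rr[-1] + 1, cc[0] : cc[-1] + 1] += (
                params.amplitude * g
            )

    rng = np.random.default_rng(params.seed + 1)
    noisy = clean
    if params.poisson_noise:
        noisy = rng.poisson(clean).astype(float)
    if params.gaussian_noise_sigma > 0:
        noisy = noisy + rng.normal(
            0.0, params.gaussian_noise_sigma, noisy.shape
        )
    np.clip(noisy, 0, 65535, out=noisy)
    return ImageStack(noisy.astype(np.uint16), c)


def rotate_stack(
    base_plane: np.ndarray,
    dtheta_deg_per_plane: float,
    n_planes: int,
    center_px: tuple[float, float] | None = None,
    calibration: Calibration | None = None,
) -> ImageStack:
    """Stack whose plane k is the base plane rotated by k * dtheta.

    ``dtheta`` is the physical rotation per plane in degrees, positive =
    counterclockwise in the right-handed frame (y up), i.e. right-handed
    chirality. Bilinear interpolation. This is the pure-rotation oracle
    for the flow pipeline: the true raw helicity is
    ``dtheta / (plane_spacing * z_correction)``.
    """
    if calibration is None:
        calibration = Calibration()
    base = np.asarray(base_plane, dtype=float)
    H, W = base.shape
    cy, cx = ((H - 1) / 2.0, (W - 1) / 2.0)
    if center_px is not None:
        cx, cy = center_px
    rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    X = cols - cx
    Y = cy - rows  # right-handed y
    out = np.empty((n_planes, H, W), dtype=float)
    for k in range(n_planes):
        phi = math.radians(k * dtheta_deg_per_plane)
        # inverse map: rotate output coords by -phi to find source pixel
        x_in = X * math.cos(phi) + Y * math.sin(phi)
        y_in = -X * math.sin(phi) + Y * math.cos(phi)
        r_in = cy - y_in
        c_in = cx + x_in
        out[k] = map_coordinates(base, [r_in, c_in], order=1, mode="constant")
    return ImageStack(out, calibration)


def mirror_stack(stack: ImageStack) -> ImageStack:
    """Flip the column (x) axis of every plane; an exact involution."""
    return ImageStack(stack.data[:, :, ::-1].copy(), stack.calibration)
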