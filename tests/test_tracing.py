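"""Oblique-circle fits: plane, circle, twist, curvature, contour length."""

import math

import numpy as np
import pytest

from spindletwist import (
    BundleTrace,
    Calibration,
    PixelPoint,
    analyze_bundle,
    analyze_spindle,
    calibrate_points,
    fit_circle_in_plane,
    fit_plane,
    generate_tilted_circle_trace,
)
from spindletwist.tracing import DegeneratePlaneError, _arc_length


def trace_to_um(trace: BundleTrace, calib=Calibration()) -> np.ndarray:
    return calibrate_points(trace.xy_px, trace.planes, calib)


class TestFitPlane:
    def test_horizontal_plane(self, rng):
        pts = np.column_stack(
            [rng.normal(size=10), rng.normal(size=10), np.full(10, 3.0)]
        )
        n, off = fit_plane(pts)
        np.testing.assert_allclose(np.abs(n), [0, 0, 1], atol=1e-9)
        assert off == pytest.approx(3.0, abs=1e-9)

    def test_vertical_plane_x0(self, rng):
        pts = np.column_stack(
            [np.zeros(10), rng.normal(size=10), rng.normal(size=10)]
        )
        n, _ = fit_plane(pts)
        np.testing.assert_allclose(np.abs(n), [1, 0, 0], atol=1e-9)

    def test_constructed_tilted_plane(self, rng):
        normal = np.array([0.3, -0.4, 0.866])
        normal /= np.linalg.norm(normal)
        e1 = np.cross(normal, [0, 0, 1.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        uv = rng.normal(size=(30, 2))
        pts = 2.0 * normal + uv[:, :1] * e1 + uv[:, 1:] * e2
        n, off = fit_plane(pts)
        np.testing.assert_allclose(n, normal, atol=1e-9)
        assert off == pytest.approx(2.0, abs=1e-9)

    def test_collinear_points_degenerate(self):
        pts = np.outer(np.linspace(0, 1, 5), [1.0, 2.0, 3.0])
        with pytest.raises(DegeneratePlaneError):
            fit_plane(pts)


class TestFitCircle:
    def test_circumcircle_of_three_points(self):
        pts = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0]], dtype=float)
        n, off = fit_plane(pts)
        center, R, _, _ = fit_circle_in_plane(pts, n, off)
        np.testing.assert_allclose(center, [0, 0, 0], atol=1e-9)
        assert R == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_circle_radius_4(self):
        t = np.linspace(0.3, 2.2, 20)
        pts = np.column_stack(
            [1.0 + 4 * np.cos(t), -2.0 + 4 * np.sin(t), np.full(20, 5.0)]
        )
        n, off = fit_plane(pts)
        center, R, _, rms = fit_circle_in_plane(pts, n, off)
        assert R == pytest.approx(4.0, abs=1e-9)
        np.testing.assert_allclose(center, [1.0, -2.0, 5.0], atol=1e-9)
        assert rms < 1e-9

    def test_collinear_in_plane_gives_infinite_radius(self):
        # numerically straight bundle: line plus sub-nm transverse jitter
        jitter = 2e-5 * np.array([0, 1, 0, 1, 0, 1, 0, 1.0])
        pts = np.column_stack(
            [np.linspace(0, 5, 8), np.zeros(8), jitter]
        )
        n, off = fit_plane(pts)
        _, R, _, _ = fit_circle_in_plane(pts, n, off)
        assert math.isinf(R)


class TestTwistOracle:
    @pytest.mark.parametrize("beta", [2.0, 5.0, 10.0, 20.0])
    @pytest.mark.parametrize("rho", [1.0, 2.0, 4.0])
    def test_tilted_circle_identity(self, beta, rho):
        """Exact construction: |twist| = beta/rho_bar, curvature = 1/R."""
        trace, true_twist, true_curv = generate_tilted_circle_trace(
            beta, rho, radius_um=5.0
        )
        fit = analyze_bundle("b", trace_to_um(trace))
        assert fit.twist_deg_per_um == pytest.approx(true_twist, rel=1e-6)
        assert fit.curvature_per_um == pytest.approx(true_curv, rel=1e-6)

    def test_planar_bundle_untwisted(self):
        # bundle in a plane containing the z axis: beta = 0 exactly
        z = np.linspace(2, 7, 10)
        pts = np.column_stack([1.5 + 0.3 * (z - 4.5) ** 2, np.zeros(10), z])
        fit = analyze_bundle("b", pts)
        assert fit.beta_deg == pytest.approx(0.0, abs=1e-9)
        assert fit.twist_deg_per_um == pytest.approx(0.0, abs=1e-9)

    def test_mirror_negates_twist_exactly(self):
        trace, _, _ = generate_tilted_circle_trace(10.0, 2.0)
        pts = trace_to_um(trace)
        mirrored = pts * np.array([1.0, -1.0, 1.0])
        f = analyze_bundle("b", pts)
        fm = analyze_bundle("b", mirrored)
        assert fm.twist_deg_per_um == pytest.approx(
            -f.twist_deg_per_um, rel=1e-12
        )
        assert fm.curvature_per_um == pytest.approx(
            f.curvature_per_um, rel=1e-12
        )

    def test_invariance_under_z_rotation_and_translation(self):
        trace, _, _ = generate_tilted_circle_trace(8.0, 3.0)
        pts = trace_to_um(trace)
        a = 1.1
        Rz = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0],
             [0, 0, 1.0]]
        )
        f = analyze_bundle("b", pts)
        fr = analyze_bundle("b", pts @ Rz.T)
        ft = analyze_bundle("b", pts + np.array([0, 0, 2.0]))
        for g in (fr, ft):
            assert g.twist_deg_per_um == pytest.approx(
                f.twist_deg_per_um, abs=1e-9
            )
            assert g.curvature_per_um == pytest.approx(
                f.curvature_per_um, abs=1e-9
            )
        # contour length is z-rotation invariant (pole axis is z)
        assert fr.contour_length_um == pytest.approx(
            f.contour_length_um, abs=1e-9
        )

    def test_scale_consistency(self):
        trace, _, _ = generate_tilted_circle_trace(10.0, 2.0)
        pts = trace_to_um(trace)
        f1 = analyze_bundle("b", pts)
        f2 = analyze_bundle("b", 2.0 * pts)
        assert f2.twist_deg_per_um == pytest.approx(
            f1.twist_deg_per_um / 2, rel=1e-9
        )
        assert f2.curvature_per_um == pytest.approx(
            f1.curvature_per_um / 2, rel=1e-9
        )

    def test_straight_bundle_flagged_achiral(self):
        z = np.linspace(1, 6, 6)
        pts = np.column_stack([np.full(6, 2.0), np.full(6, 1.0), z])
        fit = analyze_bundle("b", pts)
        assert fit.degenerate
        assert fit.twist_deg_per_um == 0.0
        assert fit.curvature_per_um == 0.0

    def test_near_axis_twist_flagged_unreliable(self):
        trace, _, _ = generate_tilted_circle_trace(5.0, 0.1, radius_um=2.0)
        fit = analyze_bundle("b", trace_to_um(trace))
        assert "unreliable_twist" in fit.flags
        assert math.isnan(fit.twist_deg_per_um)


class TestContourLength:
    def test_semicircle_plus_end_distances(self):
        # semicircular arc R=2 in an axial plane, ends 1 um from each pole
        t = np.linspace(0, np.pi, 21)
        pts = np.column_stack(
            [2 * np.sin(t), np.zeros_like(t), 5.0 - 2 * np.cos(t)]
        )
        pole1 = np.array([0, 0, 2.0])   # 1 um below the lower end (z=3)
        pole2 = np.array([0, 0, 8.0])   # 1 um above the upper end (z=7)
        fit = analyze_bundle("b", pts, pole1, pole2)
        assert fit.contour_length_um == pytest.approx(
            math.pi * 2 + 2.0, rel=1e-6
        )

    def test_straight_trace_between_poles(self):
        z = np.linspace(0, 5, 11)
        pts = np.column_stack([np.zeros(11), np.ones(11) * 0.0, z])
        pts[:, 0] = 1e-7 * np.sin(z)  # numerically straight
        fit = analyze_bundle("b", pts, np.zeros(3), np.array([0, 0, 5.0]))
        assert fit.contour_length_um == pytest.approx(5.0, abs=1e-3)

    def test_quarter_arc_formula(self):
        assert _arc_length(
            np.zeros(2),
            3.0,
            np.column_stack(
                [3 * np.cos(np.linspace(0, np.pi / 2, 9)),
                 3 * np.sin(np.linspace(0, np.pi / 2, 9))]
            ),
        ) + 0.5 + 0.7 == pytest.approx(3 * math.pi / 2 + 1.2, rel=1e-9)

    def test_major_arc_chosen_when_interior_points_wrap(self):
        # 3/4 circle: interior points lie on the long way round
        t = np.linspace(0, 1.5 * np.pi, 25)
        uv = np.column_stack([2 * np.cos(t), 2 * np.sin(t)])
        assert _arc_length(np.zeros(2), 2.0, uv) == pytest.approx(
            2 * 1.5 * np.pi, rel=1e-9
        )


class TestAnalyzeSpindle:
    @staticmethod
    def _poles(calib=Calibration()):
        return (PixelPoint(0, 0, 0), PixelPoint(0, 0, 30))

    def test_single_bundle_mean_is_bundle_twist(self):
        trace, true_twist, _ = generate_tilted_circle_trace(10.0, 2.0)
        summary, fits, _ = analyze_spindle([trace], self._poles())
        assert summary.n_bundles == 1
        assert summary.mean_twist == pytest.approx(
            fits[0].twist_deg_per_um
        )
        assert summary.mean_twist == pytest.approx(true_twist, rel=1e-6)

    def test_identical_twist_bundles_have_zero_sem(self):
        # ten copies of the same oblique circle rotated about the z axis:
        # twist is rotation invariant, so all bundles agree exactly
        base, true_twist, _ = generate_tilted_circle_trace(8.0, 4.0)
        pts = trace_to_um(base)
        traces = []
        for i in range(10):
            a = 2 * np.pi * i / 10
            Rz = np.array(
                [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0],
                 [0, 0, 1.0]]
            )
            rot = pts @ Rz.T
            c = Calibration()
            traces.append(
                BundleTrace(
                    bundle_id=f"b{i}",
                    points=tuple(
                        PixelPoint(
                            p[0] / c.pixel_size_xy,
                            -p[1] / c.pixel_size_xy,
                            p[2] / c.dz_um,
                        )
                        for p in rot
                    ),
                    spindle_id="s",
                )
            )
        summary, _, _ = analyze_spindle(traces, self._poles())
        assert summary.mean_twist == pytest.approx(true_twist, rel=1e-6)
        assert summary.sem == pytest.approx(0.0, abs=1e-9)
        assert summary.n_bundles == 10

    def test_helix_population_mean_near_generator_twist(self):
        from spindletwist import SyntheticSpindleParams, generate_traces

        params = SyntheticSpindleParams(twist_deg_per_um=-2.0, seed=5)
        traces, poles, _ = generate_traces(params)
        summary, _, _ = analyze_spindle(traces, poles)
        # the oblique-circle fit approximates a helix arc by a circle;
        # the population mean stays within 10% of the generator rate
        assert summary.mean_twist == pytest.approx(-2.0, rel=0.10)

    def test_all_degenerate_raises(self):
        z = np.linspace(0, 4, 5)
        c = Calibration()
        straight = BundleTrace(
            bundle_id="s0",
            points=tuple(PixelPoint(24.0, 0.0, zz / c.dz_um) for zz in z),
            spindle_id="s",
        )
        with pytest.raises(DegeneratePlaneError):
            analyze_spindle([straight], self._poles())
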