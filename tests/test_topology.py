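"""Twist, writhe, linking number: oracles, invariances, calibration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from supertwist.minicircle import MinicircleSpec, build_planar_minicircle
from supertwist.synthetic import parametric_curve, ribbon_from_contour
from supertwist.topology import (
    Contour,
    calibrate_lk0,
    extract_axis,
    linking_number,
    site_accumulated_twist,
    superhelical_density,
    twist_global,
    writhe,
)

# Dense-quadrature Gauss-integral value for the asymmetric lissajous test
# curve sampled at n = 4000 (computed once with `_writhe_quadrature` below
# at that resolution and frozen; the exact segment method at n = 400 must
# agree to the discretization error of the curve itself).
LISSAJOUS_QUADRATURE_WRITHE = -0.42461293


def _writhe_quadrature(pts: np.ndarray) -> float:
    """Brute-force midpoint quadrature of the Gauss double integral.

    Independent oracle for the exact segment-pair method: O(n^2) sum of
    (t_i x t_j) . (r_i - r_j) / |r_i - r_j|^3 over segment midpoints.
    """
    n = len(pts)
    mid = 0.5 * (pts + np.roll(pts, -1, axis=0))
    dv = np.roll(pts, -1, axis=0) - pts
    total = 0.0
    for i in range(n):
        r = mid[i] - mid
        d3 = np.einsum("ij,ij->i", r, r) ** 1.5
        num = np.einsum("ij,ij->i", np.cross(dv[i], dv), r)
        mask = d3 > 1e-12
        total += float((num[mask] / d3[mask]).sum())
    return total / (4.0 * np.pi)


class TestWrithe:
    def test_planar_circle_is_exactly_zero(self):
        for n in (16, 100, 400):
            t = np.linspace(0, 2 * np.pi, n, endpoint=False)
            circle = np.column_stack([np.cos(t), np.sin(t), np.zeros(n)])
            assert abs(writhe(circle)) < 1e-9

    def test_single_right_handed_crossing_approaches_plus_one(self):
        c = parametric_curve("figure_eight", 600, eps=0.005, handed=1)
        assert writhe(c) == pytest.approx(1.0, abs=0.02)

    def test_mirror_reflection_negates_writhe(self):
        c = parametric_curve("trefoil_like", 300)
        mirrored = c.points * np.array([1.0, 1.0, -1.0])
        assert writhe(mirrored) == pytest.approx(-writhe(c), abs=1e-9)

    def test_orientation_reversal_preserves_writhe(self):
        c = parametric_curve("lissajous", 300)
        assert writhe(c.points[::-1]) == pytest.approx(writhe(c), abs=1e-9)

    def test_rigid_motion_invariance(self):
        c = parametric_curve("lissajous", 300)
        R = Rotation.from_euler("xyz", [1.0, 0.2, -0.5]).as_matrix()
        moved = c.points @ R.T + np.array([3.0, -7.0, 2.0])
        assert writhe(moved) == pytest.approx(writhe(c), abs=1e-9)

    def test_exact_kernel_matches_dense_quadrature_oracle(self):
        c = parametric_curve("lissajous", 400)
        assert writhe(c) == pytest.approx(LISSAJOUS_QUADRATURE_WRITHE, abs=1e-4)
        # cross-check the oracle itself at moderate resolution
        assert _writhe_quadrature(c.points) == pytest.approx(
            LISSAJOUS_QUADRATURE_WRITHE, abs=2e-3
        )

    def test_coincident_consecutive_points_rejected(self):
        pts = parametric_curve("circle", 64).points.copy()
        pts[10] = pts[11]
        with pytest.raises(ValueError, match="coincident"):
            writhe(pts)


class TestExtractAxis:
    def test_circle_stays_a_circle_with_zero_writhe(self):
        c = parametric_curve("circle", 120, radius=50.0)
        axis = extract_axis(c.points, window=10)
        radii = np.linalg.norm(axis.points - axis.points.mean(axis=0), axis=1)
        assert radii.std() < 1e-9            # concentric circle
        assert abs(writhe(axis)) < 1e-9

    def test_window_one_is_identity(self):
        c = parametric_curve("lissajous", 100)
        np.testing.assert_allclose(extract_axis(c.points, 1).points, c.points)

    def test_recovers_axis_of_ideal_helix(self):
        # backbone winding around a planar circular axis, 10 bp per turn;
        # a one-repeat window cancels the helical wobble exactly, leaving
        # only the slight radial shrinkage of averaging along the circle
        n, repeat, r_helix = 720, 10, 9.0
        rib = build_planar_minicircle(MinicircleSpec(n_bp=n, lk=n // repeat))
        backbone = rib.origins + r_helix * rib.references
        axis = extract_axis(backbone, window=repeat)
        rms = np.sqrt(np.mean(np.sum((axis.points - rib.origins) ** 2, axis=1)))
        assert rms < 0.3

    def test_invalid_window_rejected(self):
        c = parametric_curve("circle", 64)
        for w in (0, 64, 80):
            with pytest.raises(ValueError):
                extract_axis(c.points, w)


class TestTwist:
    def test_rigid_rotation_leaves_twist_unchanged(self):
        rib = build_planar_minicircle(MinicircleSpec(n_bp=120, lk=12))
        R = Rotation.from_euler("zxz", [0.3, 1.2, -0.8]).as_matrix()
        assert twist_global(rib.transformed(R, np.zeros(3))) == pytest.approx(
            twist_global(rib), abs=1e-9
        )

    def test_whites_theorem_on_deformed_closed_ribbon(self, mc_topoisomers):
        """Tw = Lk - Wr for an MC-deformed ribbon held at Lk = 29."""
        traj = mc_topoisomers[-2]          # lk_reference 31 + (-2) = 29
        rib = traj.ribbons[-1]
        tw = twist_global(rib)
        wr = writhe(Contour(rib.origins))
        assert tw == pytest.approx(29.0 - wr, abs=0.05)

    def test_non_perpendicular_reference_rejected(self):
        rib = build_planar_minicircle(MinicircleSpec(n_bp=60, lk=6))
        rib.references[5] = rib.tangents[5]
        with pytest.raises(ValueError):
            twist_global(rib)


class TestLinkingNumber:
    def test_unlinked_distant_circles(self):
        c1 = parametric_curve("circle", 100).points
        c2 = c1 + np.array([50.0, 0.0, 0.0])
        assert linking_number(c1, c2) == 0

    def test_hopf_link_is_plus_or_minus_one(self):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        c1 = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        c2 = np.column_stack([1 + np.cos(t), np.zeros_like(t), np.sin(t)])
        assert abs(linking_number(c1, c2)) == 1

    def test_exact_kernel_gives_integer_lk_at_any_resolution(self):
        """The solid-angle kernel is topologically exact for polylines: the
        raw Gauss integral between disjoint closed strand curves is an
        integer to machine precision even at coarse sampling."""
        from supertwist.minicircle import strand_curves

        for n in (100, 400):
            axis = parametric_curve("lissajous", n).points * 40.0
            rib = ribbon_from_contour(axis, lk=5)
            s1, s2 = strand_curves(rib, strand_radius=2.0)
            integral = linking_number(s1, s2, raw=True)
            assert abs(integral - 5.0) < 1e-9

    def test_polyline_writhe_converges_with_refinement(self):
        """Doubling the sampling halves-or-better the distance to the
        continuum writhe (frozen dense-quadrature reference)."""
        def residual(n):
            return abs(
                writhe(parametric_curve("lissajous", n))
                - LISSAJOUS_QUADRATURE_WRITHE
            )

        assert residual(400) < residual(200) < residual(100)


class TestSuperhelicalDensity:
    def test_paper_span_with_calibrated_lk0(self):
        assert superhelical_density(29, 31.08) == pytest.approx(-0.067, abs=5e-4)
        assert superhelical_density(34, 31.08) == pytest.approx(0.094, abs=5e-4)

    def test_relaxed_circle_has_zero_sigma(self):
        assert superhelical_density(31.08, 31.08) == 0.0

    def test_invalid_lk0_rejected(self):
        with pytest.raises(ValueError):
            superhelical_density(30, 0.0)


class TestCalibration:
    def test_exact_linear_data_recovers_root(self):
        pts = [(lk, 0.8 * (lk - 31.08)) for lk in range(29, 35)]
        assert calibrate_lk0(pts).lk0 == pytest.approx(31.08, abs=1e-9)

    def test_noisy_recovery_unbiased_over_many_seeds(self):
        rng = np.random.default_rng(42)
        roots = []
        for _ in range(200):
            pts = [
                (lk, 0.8 * (lk - 31.08) + rng.normal(0, 0.1))
                for lk in range(29, 35)
            ]
            roots.append(calibrate_lk0(pts).lk0)
        assert abs(np.mean(roots) - 31.08) < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrate_lk0([(29, -1.0), (34, 1.0)])
        with pytest.raises(ValueError):
            calibrate_lk0([(29, 0.5), (31, 0.5), (34, 0.5)])


class TestSiteTwist:
    def test_uniform_helix_accumulates_uniform_twist(self):
        # 10.5 bp/turn: n=336 at lk=32
        rib = build_planar_minicircle(MinicircleSpec(n_bp=336, lk=32))
        got = site_accumulated_twist(rib, (100, 121))   # 21 dinucleotide steps
        assert got == pytest.approx(21 * 360 / 10.5, abs=1e-6)

    def test_topoisomer_difference_matches_uniform_arithmetic(self):
        r29 = build_planar_minicircle(MinicircleSpec(n_bp=336, lk=29))
        r34 = build_planar_minicircle(MinicircleSpec(n_bp=336, lk=34))
        d = site_accumulated_twist(r34, (100, 121)) - site_accumulated_twist(
            r29, (100, 121)
        )
        assert d == pytest.approx(21 * 360 * 5 / 336, abs=1e-6)

    def test_range_wraps_across_origin(self):
        rib = build_planar_minicircle(MinicircleSpec(n_bp=336, lk=32))
        assert site_accumulated_twist(rib, (330, 10)) == pytest.approx(
            16 * 360 * 32 / 336, abs=1e-6
        )

    def test_empty_range_rejected(self):
        rib = build_planar_minicircle(MinicircleSpec(n_bp=336, lk=32))
        with pytest.raises(ValueError, match="empty"):
            site_accumulated_twist(rib, (10, 10))
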