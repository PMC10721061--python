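"""Contour extraction, discrete curvature, and the curvature-variation
statistic with its invariances."""

import math

import numpy as np
import pytest

from phaserestore import (
    ContourCurve,
    Grid,
    default_epsilon,
    extract_zero_contour,
    measure_captured_area,
    resample_uniform,
    select_plateau,
    tanh_circle_field,
)
from phaserestore.curvature import curvature_profile, curvature_variation


def circle_curve(radius: float, n: int, center=(0.0, 0.0)) -> ContourCurve:
    th = 2 * np.pi * np.arange(n) / n
    v = np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )
    return ContourCurve(v, closed=True, ds=2 * np.pi * radius / n)


def perturbed_circle(radius: float, n: int, amp=0.05, mode=5) -> ContourCurve:
    th = 2 * np.pi * np.arange(n) / n
    r = radius * (1 + amp * np.cos(mode * th))
    v = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return resample_uniform(ContourCurve(v, closed=True), 2 * np.pi * radius / n)


def stadium_polyline(r=0.1, straight=0.2, n_fine=4000) -> ContourCurve:
    """Two semicircles of radius r joined by straights (counter-clockwise)."""
    t = np.linspace(-np.pi / 2, np.pi / 2, n_fine // 4, endpoint=False)
    right = np.column_stack([straight / 2 + r * np.cos(t), r * np.sin(t)])
    top = np.column_stack(
        [np.linspace(straight / 2, -straight / 2, n_fine // 4, endpoint=False),
         np.full(n_fine // 4, r)]
    )
    t2 = np.linspace(np.pi / 2, 3 * np.pi / 2, n_fine // 4, endpoint=False)
    left = np.column_stack([-straight / 2 + r * np.cos(t2), r * np.sin(t2)])
    bottom = np.column_stack(
        [np.linspace(-straight / 2, straight / 2, n_fine // 4, endpoint=False),
         np.full(n_fine // 4, -r)]
    )
    return ContourCurve(np.vstack([right, top, left, bottom]), closed=True)


class TestExtraction:
    def test_tanh_disk_yields_single_accurate_circle(self):
        grid = Grid.unit_square(256)
        f = tanh_circle_field((0.5, 0.5), 0.25, default_epsilon(grid.h), grid)
        curves = extract_zero_contour(f, grid)
        assert len(curves) == 1 and curves[0].closed
        r = np.hypot(curves[0].vertices[:, 0] - 0.5, curves[0].vertices[:, 1] - 0.5)
        assert np.abs(r - 0.25).max() <= grid.h

    def test_no_sign_change_raises(self):
        grid = Grid.unit_square(32)
        with pytest.raises(ValueError, match="no interface"):
            extract_zero_contour(np.full(grid.shape, -1.0), grid)

    def test_saddle_field_resolved_deterministically(self):
        grid = Grid.unit_square(64)
        X, Y = grid.cell_centers()
        f = (X - 0.5) * (Y - 0.5) - 0.001
        a = extract_zero_contour(f, grid)
        b = extract_zero_contour(f, grid)
        assert len(a) == 2
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.vertices, cb.vertices)

    def test_extracted_area_consistent_with_field_measure(self):
        grid = Grid.unit_square(128)
        f = tanh_circle_field((0.5, 0.5), 0.25, default_epsilon(grid.h), grid)
        curve = extract_zero_contour(f, grid)[0]
        tol = 2 * grid.h * curve.arc_length()
        assert abs(curve.enclosed_area() - measure_captured_area(f, grid)) <= tol


class TestCurvature:
    def test_circle_curvature_constant(self):
        c = curvature_profile(circle_curve(0.22, 400))
        np.testing.assert_allclose(c.kappa, 1 / 0.22, rtol=0.005)

    def test_straight_segment_zero_curvature(self):
        v = np.column_stack([np.linspace(0, 1, 100), np.linspace(0, 0.5, 100)])
        c = curvature_profile(
            resample_uniform(ContourCurve(v, closed=False), 0.01)
        )
        np.testing.assert_allclose(c.kappa, 0.0, atol=1e-10)

    def test_ellipse_vertex_curvature(self):
        a, b = 0.3, 0.15
        th = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        v = np.column_stack([a * np.cos(th), b * np.sin(th)])
        total = ContourCurve(v, closed=True).arc_length()
        c = curvature_profile(
            resample_uniform(ContourCurve(v, closed=True), total / 800),
            smooth_window=1,
        )
        assert c.kappa.max() == pytest.approx(a / b ** 2, rel=0.02)

    def test_repeated_vertices_rejected(self):
        v = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.5, 1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            curvature_profile(ContourCurve(v, closed=True, ds=0.1))


class TestCurvatureVariation:
    def test_circle_statistic_vanishes(self):
        c = curvature_profile(circle_curve(0.22, 400))
        assert curvature_variation(c) < 1e-3

    def test_too_few_samples_rejected(self):
        c = circle_curve(0.2, 4)
        with pytest.raises(ValueError):
            curvature_variation(
                ContourCurve(c.vertices, True, ds=c.ds, kappa=np.ones(4))
            )

    def test_rigid_motion_invariance(self):
        base = curvature_profile(perturbed_circle(0.2, 800))
        d0 = curvature_variation(base)
        th = np.pi / 6
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved_v = perturbed_circle(0.2, 800).vertices @ R.T + np.array([1.3, -0.7])
        moved = curvature_profile(
            ContourCurve(moved_v, closed=True, ds=base.ds)
        )
        d1 = curvature_variation(moved)
        assert abs(d1 - d0) / d0 < 1e-6

    def test_scaling_law_c_cubed(self):
        c = 2.0
        base = perturbed_circle(0.2, 800)
        scaled = ContourCurve(base.vertices * c, closed=True, ds=base.ds * c)
        d0 = curvature_variation(curvature_profile(base))
        d1 = curvature_variation(curvature_profile(scaled))
        assert d1 / d0 == pytest.approx(c ** -3, rel=0.01)

    def test_stadium_matches_bruteforce_and_grows_with_refinement(self):
        # kappa jumps at the semicircle/straight junctions, so the discrete
        # statistic grows under refinement; the oracle re-implements the
        # formula with plain loops
        def brute_force(curve):
            k = curve.kappa
            n = len(k)
            ds = curve.ds
            total = 0.0
            for i in range(n):
                dk = (k[(i + 1) % n] - k[(i - 1) % n]) / (2 * ds)
                total += dk * dk * ds
            return total

        fine = stadium_polyline()
        ds400 = fine.arc_length() / 400
        d_vals = {}
        for n in (400, 1600):
            cur = curvature_profile(
                resample_uniform(fine, fine.arc_length() / n)
            )
            d_vals[n] = curvature_variation(cur)
            assert d_vals[n] == pytest.approx(brute_force(cur), rel=1e-10)
        assert d_vals[1600] > d_vals[400]

    def test_open_curve_excludes_terminal_samples(self):
        # a parabola arc: statistic finite and positive, endpoints excluded
        x = np.linspace(-0.5, 0.5, 2000)
        v = np.column_stack([x, x ** 2])
        c = curvature_profile(resample_uniform(ContourCurve(v, False), 0.002))
        d = curvature_variation(c)
        assert np.isfinite(d) and d > 0


class TestSelection:
    def test_steep_paper_like_sequence_has_no_knee(self):
        betas = [0.1, 0.3, 0.5, 0.7, 0.9, 1.1]
        d = [10900, 5190, 1750, 330, 8.85, 1.14]
        sel, status = select_plateau(betas, d, threshold=0.5)
        assert sel is None and status == "no knee found"

    def test_plateau_start_selected(self):
        sel, status = select_plateau(
            [0.2, 0.4, 0.6, 0.8, 1.0], [100.0, 30.0, 10.0, 8.0, 7.5]
        )
        assert status == "selected" and sel == 0.6

    def test_degenerate_zero_sequence_selects_smallest(self):
        sel, status = select_plateau([0.1, 0.2, 0.3], [0.0, 0.0, 0.0])
        assert sel == 0.1 and status == "selected"

    def test_too_short_sweep_rejected(self):
        with pytest.raises(ValueError):
            select_plateau([0.1], [1.0])
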