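"""Standard ellipse geometry: SEA/SEAc, boundaries, overlap, convex hull."""

import numpy as np
import pytest

from isoniche.ellipse import (
    DegenerateDataError,
    convex_hull_area,
    ellipse_boundary,
    ellipse_overlap,
    ellipse_polygon,
    fit_standard_ellipse,
)

CROSS = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])


def _circle_fit(n=8):
    """A fit whose standard ellipse is the unit circle (identity covariance)."""
    fit = fit_standard_ellipse(np.array([[0.0, 0.0], [1.0, 1.0], [1.0, -1.0], [-1.0, 0.5]]))
    return type(fit)(centroid=np.zeros(2), covariance=np.eye(2), n=n)


class TestFit:
    def test_four_point_cross_closed_form(self):
        fit = fit_standard_ellipse(CROSS)
        assert np.allclose(fit.centroid, [0.0, 0.0])
        assert np.allclose(fit.covariance, np.diag([2 / 3, 2 / 3]))
        assert fit.sea == pytest.approx(2 * np.pi / 3, rel=1e-12)
        assert fit.seac == pytest.approx(np.pi, rel=1e-12)

    def test_large_sample_sea_matches_population_area(self, rng):
        pts = rng.multivariate_normal([0, 0], np.diag([4.0, 1.0]), size=100_000)
        fit = fit_standard_ellipse(pts)
        assert fit.sea == pytest.approx(2 * np.pi, rel=0.01)

    def test_seac_exceeds_sea(self, rng):
        pts = rng.normal(size=(10, 2))
        fit = fit_standard_ellipse(pts)
        assert fit.seac > fit.sea
        assert fit.seac == pytest.approx(fit.sea * 9 / 8)

    def test_sea_equals_pi_times_semiaxes_product(self, rng):
        pts = rng.normal(size=(30, 2)) @ np.array([[2.0, 0.3], [0.0, 0.7]])
        fit = fit_standard_ellipse(pts)
        lam = np.linalg.eigvalsh(fit.covariance)
        assert fit.sea == pytest.approx(np.pi * np.sqrt(lam[0] * lam[1]), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_translation_and_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(20, 2))
        shift = rng.normal(size=2) * 10
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        base = fit_standard_ellipse(pts)
        assert fit_standard_ellipse(pts + shift).sea == pytest.approx(base.sea)
        assert fit_standard_ellipse(pts @ rot.T).sea == pytest.approx(base.sea)
        assert convex_hull_area(pts + shift) == pytest.approx(convex_hull_area(pts))
        assert convex_hull_area(pts @ rot.T) == pytest.approx(convex_hull_area(pts))

    def test_too_few_points(self):
        with pytest.raises(DegenerateDataError):
            fit_standard_ellipse(CROSS[:2])

    def test_collinear_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(DegenerateDataError, match="degenerate"):
            fit_standard_ellipse(pts)


class TestBoundary:
    def test_unit_circle_polygon_area(self):
        poly = ellipse_polygon(_circle_fit(), n_vertices=4096)
        assert poly.area == pytest.approx(np.pi, rel=1e-4)

    def test_radius_scale_two_quadruples_area(self):
        p1 = ellipse_polygon(_circle_fit(), radius_scale=1.0, n_vertices=512)
        p2 = ellipse_polygon(_circle_fit(), radius_scale=2.0, n_vertices=512)
        assert p2.area == pytest.approx(4 * p1.area, rel=1e-9)

    def test_major_axis_orientation(self):
        fit = _circle_fit()
        fit = type(fit)(centroid=np.zeros(2), covariance=np.diag([4.0, 1.0]), n=8)
        ring = ellipse_boundary(fit, n_vertices=1024)
        assert ring[:, 0].max() == pytest.approx(2.0, abs=1e-6)  # sqrt(4) along x
        assert ring[:, 1].max() == pytest.approx(1.0, abs=1e-6)

    def test_vertex_count_validation(self):
        with pytest.raises(ValueError):
            ellipse_boundary(_circle_fit(), n_vertices=8)
        with pytest.raises(ValueError):
            ellipse_boundary(_circle_fit(), radius_scale=0.0)


class TestOverlap:
    def _unit_circle_at(self, x, n=10):
        fit = _circle_fit(n)
        return type(fit)(centroid=np.array([x, 0.0]), covariance=np.eye(2), n=n)

    def test_identical_fits_overlap_is_own_area(self):
        a = self._unit_circle_at(0.0)
        got = ellipse_overlap(a, a, use_seac=False)
        assert got == pytest.approx(np.pi, rel=1e-4)

    def test_circle_lens_closed_form(self):
        # two unit circles with centres 1 apart: lens area 2*pi/3 - sqrt(3)/2
        a, b = self._unit_circle_at(0.0), self._unit_circle_at(1.0)
        expected = 2 * np.pi / 3 - np.sqrt(3) / 2
        assert ellipse_overlap(a, b, use_seac=False) == pytest.approx(expected, rel=1e-3)

    def test_symmetric_and_monotone_in_separation(self):
        areas = []
        for sep in (0.0, 0.5, 1.0, 1.5, 2.5):
            a, b = self._unit_circle_at(0.0), self._unit_circle_at(sep)
            ab = ellipse_overlap(a, b, use_seac=False)
            ba = ellipse_overlap(b, a, use_seac=False)
            assert ab == pytest.approx(ba, rel=1e-9)
            areas.append(ab)
        assert all(x >= y for x, y in zip(areas, areas[1:]))
        assert areas[-1] == 0.0

    def test_polygonization_converged_at_1024_vertices(self):
        a, b = self._unit_circle_at(0.0), self._unit_circle_at(1.0)
        v1 = ellipse_overlap(a, b, use_seac=False, n_vertices=1024)
        v2 = ellipse_overlap(a, b, use_seac=False, n_vertices=2048)
        assert abs(v2 - v1) / v1 < 1e-3

    def test_seac_scaling_enlarges_overlap(self):
        a, b = self._unit_circle_at(0.0, n=4), self._unit_circle_at(1.0, n=4)
        assert ellipse_overlap(a, b, use_seac=True) > ellipse_overlap(a, b, use_seac=False)

    def test_overlap_bounded_by_smaller_area(self, rng):
        pts_a = rng.normal(size=(15, 2))
        pts_b = rng.normal(size=(15, 2)) * 0.5
        fa, fb = fit_standard_ellipse(pts_a), fit_standard_ellipse(pts_b)
        got = ellipse_overlap(fa, fb, use_seac=True)
        assert 0.0 <= got <= min(fa.seac, fb.seac) * (1 + 1e-6)


class TestConvexHull:
    def test_unit_square(self, unit_square):
        assert convex_hull_area(unit_square) == pytest.approx(1.0)

    def test_triangle(self):
        assert convex_hull_area(np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])) == pytest.approx(2.0)

    def test_permutation_invariance(self, rng):
        pts = rng.normal(size=(12, 2))
        shuffled = pts[rng.permutation(12)]
        assert convex_hull_area(shuffled) == pytest.approx(convex_hull_area(pts))

    def test_collinear_returns_zero_with_warning(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.warns(UserWarning, match="collinear"):
            assert convex_hull_area(pts) == 0.0
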