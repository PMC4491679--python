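"""Tests for midpoint-rule MLC leaf fitting and scalloping-area error."""

import math

import numpy as np
import pytest
import shapely

from protonplan.mlc import (
    AperturePolygon,
    ApertureError,
    aperture_area_error,
    fit_leaf_positions,
    orientation_variants,
)
from protonplan.synthetic import gen_aperture


def circle_polygon(radius=2.5, center=(0.0, 0.0), n=720):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return AperturePolygon(
        np.column_stack([center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)])
    )


def random_convex_polygon(rng, n_points=12, scale=3.0):
    points = rng.normal(scale=scale, size=(n_points, 2))
    hull = shapely.convex_hull(shapely.MultiPoint(points))
    return AperturePolygon(np.asarray(hull.exterior.coords)[:-1])


def rasterized_area_error(polygon, bank, cell=0.01):
    """Independent scalloping-area oracle: count cells whose membership differs.

    Polygon membership comes from point-in-polygon tests at cell centres;
    leaf-opening membership is recomputed directly from the leaf intervals,
    without any polygon-clipping machinery.
    """
    minx, miny, maxx, maxy = polygon.to_shapely().buffer(2 * bank.leaf_width).bounds
    xs = np.arange(minx + cell / 2, maxx, cell)
    ys = np.arange(miny + cell / 2, maxy, cell)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    in_poly = shapely.contains_xy(polygon.to_shapely(), gx.ravel(), gy.ravel()).reshape(gx.shape)
    in_bank = np.zeros_like(in_poly)
    for leaf in bank.open_leaves():
        if bank.orientation == "y":
            rows = (gy >= leaf.row_min) & (gy < leaf.row_max)
            travel = gx
        else:
            rows = (gx >= leaf.row_min) & (gx < leaf.row_max)
            travel = gy
        in_bank |= rows & (travel >= leaf.left_tip) & (travel <= leaf.right_tip)
    return float((in_poly ^ in_bank).sum()) * cell * cell


class TestApertureValidation:
    def test_too_few_vertices(self):
        with pytest.raises(ApertureError):
            AperturePolygon([(0, 0), (1, 0)])

    def test_zero_area(self):
        with pytest.raises(ApertureError):
            AperturePolygon([(0, 0), (1, 0), (2, 0)])

    def test_self_intersection(self):
        with pytest.raises(ApertureError):
            AperturePolygon([(0, 0), (1, 1), (1, 0), (0, 1)])

    def test_closed_ring_accepted(self):
        poly = AperturePolygon([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert len(poly.vertices) == 4

    def test_csv_round_trip(self, tmp_path):
        poly = gen_aperture(seed=5)
        path = tmp_path / "aperture.csv"
        poly.to_csv(path)
        assert np.allclose(AperturePolygon.from_csv(path).vertices, poly.vertices)

    def test_json_round_trip(self, tmp_path):
        poly = gen_aperture(seed=5)
        path = tmp_path / "aperture.json"
        poly.to_json(path)
        assert np.allclose(AperturePolygon.from_json(path).vertices, poly.vertices)


class TestLeafFitting:
    def test_leaf_aligned_rectangle_is_exact(self):
        rect = AperturePolygon([(0, 0), (4, 0), (4, 2), (0, 2)])
        bank = fit_leaf_positions(rect, leaf_width=0.5)
        assert len(bank.leaves) == 4
        for leaf in bank.leaves:
            assert leaf.open
            assert leaf.left_tip == pytest.approx(0.0, abs=1e-12)
            assert leaf.right_tip == pytest.approx(4.0, abs=1e-12)
        assert aperture_area_error(rect, bank) == pytest.approx(0.0, abs=1e-12)

    def test_circle_tips_at_chord_half_width(self):
        radius, width = 2.5, 0.5
        bank = fit_leaf_positions(circle_polygon(radius), leaf_width=width)
        for leaf in bank.open_leaves():
            y_mid = 0.5 * (leaf.row_min + leaf.row_max)
            half_chord = math.sqrt(radius**2 - y_mid**2)
            assert leaf.left_tip == pytest.approx(-half_chord, abs=1e-3)
            assert leaf.right_tip == pytest.approx(half_chord, abs=1e-3)

    def test_row_missing_polygon_stays_closed(self):
        # Extent spans two rows but the second row's midline lies above the apex.
        triangle = AperturePolygon([(0, 0), (2, 0), (1, 0.6)])
        bank = fit_leaf_positions(triangle, leaf_width=0.5)
        assert [leaf.open for leaf in bank.leaves] == [True, False]

    def test_rows_tile_polygon_extent(self):
        poly = gen_aperture(seed=2)
        bank = fit_leaf_positions(poly, leaf_width=0.5)
        miny = poly.to_shapely().bounds[1]
        maxy = poly.to_shapely().bounds[3]
        assert bank.leaves[0].row_min == pytest.approx(miny)
        assert bank.leaves[-1].row_max >= maxy - 1e-12
        widths = [leaf.row_max - leaf.row_min for leaf in bank.leaves]
        assert widths == pytest.approx([0.5] * len(widths))

    @pytest.mark.parametrize("seed", range(5))
    def test_midpoint_rule_tips_on_boundary(self, seed):
        """Each open leaf tip, at the row midline, lies on the aperture outline."""
        poly = gen_aperture(seed=seed, irregularity=0.2)
        boundary = poly.to_shapely().exterior
        bank = fit_leaf_positions(poly, leaf_width=0.5)
        assert bank.open_leaves()
        for leaf in bank.open_leaves():
            y_mid = 0.5 * (leaf.row_min + leaf.row_max)
            for tip in (leaf.left_tip, leaf.right_tip):
                assert boundary.distance(shapely.Point(tip, y_mid)) < 1e-9

    def test_outermost_crossings_for_nonconvex_row(self):
        # A U-shape crosses the midline of its bottom row four times; the
        # single leaf pair spans the outermost pair of crossings.
        u_shape = AperturePolygon(
            [(0, 0), (3, 0), (3, 2), (2, 2), (2, 0.5), (1, 0.5), (1, 2), (0, 2)]
        )
        bank = fit_leaf_positions(u_shape, leaf_width=0.5)
        bottom = bank.leaves[0]
        assert bottom.left_tip == pytest.approx(0.0, abs=1e-12)
        assert bottom.right_tip == pytest.approx(3.0, abs=1e-12)

    def test_anchor_registration_shifts_rows(self):
        poly = circle_polygon()
        bank = fit_leaf_positions(poly, leaf_width=0.5, anchor=0.1)
        assert (bank.leaves[0].row_min - 0.1) % 0.5 == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ApertureError):
            fit_leaf_positions(circle_polygon(), leaf_width=0.0)
        with pytest.raises(ApertureError):
            fit_leaf_positions(circle_polygon(), orientation="diagonal")


class TestAreaError:
    def test_circle_matches_rasterization_oracle(self):
        poly = circle_polygon(2.5)
        bank = fit_leaf_positions(poly, leaf_width=0.5)
        analytic = aperture_area_error(poly, bank)
        oracle = rasterized_area_error(poly, bank, cell=0.01)
        assert analytic == pytest.approx(oracle, rel=0.01)

    def test_halving_leaf_width_never_increases_error_for_convex(self, rng):
        for _ in range(20):
            poly = random_convex_polygon(rng)
            errors = [
                aperture_area_error(poly, fit_leaf_positions(poly, leaf_width=w))
                for w in (1.0, 0.5, 0.25, 0.125)
            ]
            assert np.all(np.diff(errors) <= 1e-9)

    def test_coverage_of_midline_chords_convex(self, rng):
        """For convex apertures the open leaves contain every midline chord."""
        poly = random_convex_polygon(rng)
        bank = fit_leaf_positions(poly, leaf_width=0.5)
        opening = bank.opening()
        shape = poly.to_shapely()
        minx, _, maxx, _ = shape.bounds
        for leaf in bank.open_leaves():
            y_mid = 0.5 * (leaf.row_min + leaf.row_max)
            chord = shape.intersection(
                shapely.LineString([(minx - 1, y_mid), (maxx + 1, y_mid)])
            )
            assert chord.within(opening.buffer(1e-9))


class TestOrientationVariants:
    def test_square_both_orientations_exact(self):
        square = AperturePolygon([(0, 0), (3, 0), (3, 3), (0, 3)])
        result = orientation_variants(square, leaf_width=0.5)
        assert result.error_y == pytest.approx(0.0, abs=1e-12)
        assert result.error_x == pytest.approx(0.0, abs=1e-12)

    def test_circle_orientations_agree_by_symmetry(self):
        result = orientation_variants(circle_polygon(2.5), leaf_width=0.5)
        assert result.error_y == pytest.approx(result.error_x, abs=1e-6)

    def test_ellipse_reports_both_errors(self):
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        ellipse = AperturePolygon(np.column_stack([4 * np.cos(theta), 2 * np.sin(theta)]))
        result = orientation_variants(ellipse, leaf_width=0.5)
        for bank, error in ((result.bank_y, result.error_y), (result.bank_x, result.error_x)):
            assert error > 0
            assert error == pytest.approx(rasterized_area_error(ellipse, bank, cell=0.02), rel=0.02)
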