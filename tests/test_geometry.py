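"""Skeleton/line/ellipse primitives and the two biometric pipelines."""

import numpy as np
import pytest

from fourchamber import (
    BinaryMask,
    DegenerateGeometryError,
    Ellipse,
    LabelMap,
    Line2D,
    PhantomSpec,
    angle_between,
    ellipse_area,
    extract_contour,
    fit_ellipse,
    fit_line_tls,
    generate_phantom,
    mass_center,
    measure_cax,
    measure_ctr,
    skeletonize,
    thoracic_ap_axis,
)
from fourchamber.geometry import prune_to_longest_path


def _mask(grid):
    return BinaryMask(grid=np.asarray(grid, bool))


def _sample_ellipse(center, major, minor, rot_deg, n=360):
    """Forward-sample exact boundary points of an ellipse in (row, col)."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    th = np.deg2rad(rot_deg)
    u = np.array([np.sin(th), np.cos(th)])  # major-axis direction (row, col)
    v = np.array([np.cos(th), -np.sin(th)])
    return (
        np.asarray(center)[None, :]
        + np.outer(np.cos(t) * major / 2, u)
        + np.outer(np.sin(t) * minor / 2, v)
    )


class TestSkeletonize:
    def test_single_pixel(self):
        grid = np.zeros((10, 10), bool)
        grid[4, 7] = True
        pts = skeletonize(_mask(grid))
        np.testing.assert_array_equal(pts, [[4, 7]])

    def test_thick_bar_reduces_to_middle_row(self):
        grid = np.zeros((20, 60), bool)
        grid[9:12, 5:55] = True  # 3 rows thick, length 50
        pts = skeletonize(_mask(grid))
        interior = pts[(pts[:, 1] > 8) & (pts[:, 1] < 51)]
        assert len(interior) > 30
        assert np.all(interior[:, 0] == 10)
        # every skeleton point lies inside the mask
        assert grid[pts[:, 0], pts[:, 1]].all()

    def test_tilted_rectangle_direction(self):
        # oracle: principal axis of the full rectangle's pixel coordinates
        rr, cc = np.indices((200, 200))
        r0, c0 = 100, 100
        th = np.deg2rad(30)
        u = (rr - r0) * -np.sin(th) + (cc - c0) * np.cos(th)
        v = (rr - r0) * np.cos(th) + (cc - c0) * np.sin(th)
        rect = (np.abs(u) <= 60) & (np.abs(v) <= 8)
        pix = np.argwhere(rect)
        oracle = fit_line_tls(pix)
        sk = prune_to_longest_path(skeletonize(_mask(rect)))
        line = fit_line_tls(sk)
        assert angle_between(line, oracle) < 2.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            skeletonize(_mask(np.zeros((8, 8))))


class TestPruneLongestPath:
    def test_spur_is_removed(self):
        # an L of 30+30 pixels with a 4-pixel side spur off the corner
        pts = (
            [(0, c) for c in range(30)]
            + [(r, 29) for r in range(1, 30)]
            + [(r, 10) for r in range(1, 5)]
        )
        pruned = prune_to_longest_path(np.array(pts))
        pruned_set = set(map(tuple, pruned))
        assert (4, 10) not in pruned_set
        assert (0, 0) in pruned_set and (29, 29) in pruned_set


class TestFitLineTLS:
    def test_diagonal_points(self):
        line = fit_line_tls(np.array([(0, 0), (1, 1), (2, 2)]))
        assert line.point == pytest.approx((1, 1))
        assert abs(abs(np.dot(line.direction, (1, 1) / np.sqrt(2))) - 1) < 1e-12

    def test_vertical_points(self):
        # ordinary regression cannot represent a vertical-in-image line
        line = fit_line_tls(np.array([(0, 5), (1, 5), (2, 5)]))
        assert abs(line.direction[0]) == pytest.approx(1.0)
        assert line.direction[1] == pytest.approx(0.0)

    def test_noisy_line_within_one_degree_of_svd_oracle(self, rng):
        th = np.deg2rad(37.0)
        t = rng.uniform(-50, 50, 200)
        pts = np.column_stack([t * np.sin(th), t * np.cos(th)])
        pts += rng.normal(0, 0.5, pts.shape)
        line = fit_line_tls(pts)
        # independent oracle: SVD of centered coordinates
        _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
        oracle = Line2D(point=(0, 0), direction=tuple(vt[0]))
        assert angle_between(line, oracle) < 1e-9
        truth = Line2D(point=(0, 0), direction=(np.sin(th), np.cos(th)))
        assert angle_between(line, truth) < 1.0

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_line_tls(np.array([(3, 3), (3, 3)]))
        with pytest.raises(DegenerateGeometryError):
            # perfectly isotropic square of 4 points
            fit_line_tls(np.array([(0, 0), (0, 1), (1, 0), (1, 1)]))

    def test_minimizes_orthogonal_residual_monte_carlo(self, rng):
        pts = rng.normal(0, 1, (60, 2)) @ np.array([[3.0, 0.5], [0.5, 1.0]])
        line = fit_line_tls(pts)
        centroid = pts.mean(axis=0)
        centered = pts - centroid

        def sse(direction):
            d = np.asarray(direction) / np.hypot(*direction)
            ortho = centered - np.outer(centered @ d, d)
            return float((ortho**2).sum())

        best = sse(line.direction)
        for th in rng.uniform(0, np.pi, 1000):
            assert best <= sse((np.sin(th), np.cos(th))) + 1e-9


class TestMassCenter:
    def test_centered_disc(self):
        rr, cc = np.indices((11, 11))
        disc = (rr - 5) ** 2 + (cc - 5) ** 2 <= 16
        assert mass_center(_mask(disc)) == pytest.approx((5, 5))

    def test_rectangle_analytic(self):
        grid = np.zeros((10, 10), bool)
        grid[2:6, 0:10] = True
        assert mass_center(_mask(grid)) == pytest.approx((3.5, 4.5))

    def test_matches_brute_force(self, rng):
        grid = rng.random((30, 30)) < 0.4
        grid[0, 0] = True
        r, c = mass_center(_mask(grid))
        rows, cols = np.nonzero(grid)
        assert r == pytest.approx(sum(rows) / len(rows))
        assert c == pytest.approx(sum(cols) / len(cols))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mass_center(_mask(np.zeros((8, 8))))


class TestAPAxisAndAngles:
    def _disc(self, shape, center, radius):
        rr, cc = np.indices(shape)
        return _mask((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2)

    def test_axis_points_from_spine_to_thorax(self):
        spine = self._disc((80, 80), (50, 30), 3)
        thorax = self._disc((80, 80), (30, 30), 10)
        line = thoracic_ap_axis(thorax, spine)
        assert line.direction == pytest.approx((-1.0, 0.0))

    def test_swapping_roles_flips_sign_but_not_angle(self):
        spine = self._disc((80, 80), (50, 32), 3)
        thorax = self._disc((80, 80), (30, 30), 10)
        fwd = thoracic_ap_axis(thorax, spine)
        rev = thoracic_ap_axis(spine, thorax)
        assert np.allclose(np.asarray(fwd.direction), -np.asarray(rev.direction))
        ref = Line2D(point=(0, 0), direction=(0, 1))
        assert angle_between(fwd, ref) == pytest.approx(angle_between(rev, ref))

    def test_coincident_centroids_raise(self):
        d = self._disc((40, 40), (20, 20), 5)
        with pytest.raises(DegenerateGeometryError):
            thoracic_ap_axis(d, d)

    @pytest.mark.parametrize(
        "d1,d2,expected",
        [
            ((1, 0), (1, 0), 0.0),
            ((1, 0), (0, 1), 90.0),
            # directions at 30 and 170 degrees: acute angle of 140 is 40
            ((np.sin(np.deg2rad(30)), np.cos(np.deg2rad(30))),
             (np.sin(np.deg2rad(170)), np.cos(np.deg2rad(170))), 40.0),
        ],
    )
    def test_angle_between_analytic(self, d1, d2, expected):
        a = Line2D(point=(0, 0), direction=d1)
        b = Line2D(point=(0, 0), direction=d2)
        assert angle_between(a, b) == pytest.approx(expected, abs=1e-9)
        assert angle_between(b, a) == pytest.approx(angle_between(a, b))

    def test_angle_bounds(self, rng):
        for _ in range(50):
            th1, th2 = rng.uniform(0, 2 * np.pi, 2)
            a = Line2D(point=(0, 0), direction=(np.sin(th1), np.cos(th1)))
            b = Line2D(point=(0, 0), direction=(np.sin(th2), np.cos(th2)))
            assert 0.0 <= angle_between(a, b) <= 90.0
        assert angle_between(a, a) == pytest.approx(0.0, abs=1e-6)


class TestContour:
    def test_single_pixel(self):
        grid = np.zeros((10, 10), bool)
        grid[3, 4] = True
        np.testing.assert_array_equal(extract_contour(_mask(grid)), [[3, 4]])

    def test_filled_square_has_36_border_pixels(self):
        grid = np.zeros((20, 20), bool)
        grid[5:15, 5:15] = True
        contour = extract_contour(_mask(grid))
        assert len(np.unique(contour, axis=0)) == 36
        assert contour[:, 0].min() == 5 and contour[:, 0].max() == 14
        on_border = (
            (contour[:, 0] == 5) | (contour[:, 0] == 14)
            | (contour[:, 1] == 5) | (contour[:, 1] == 14)
        )
        assert on_border.all()

    def test_contour_points_foreground_and_touching_background(self, rng):
        rr, cc = np.indices((60, 60))
        blob = (rr - 30) ** 2 / 400 + (cc - 28) ** 2 / 225 <= 1
        contour = extract_contour(_mask(blob))
        padded = np.pad(blob, 1)
        for r, c in contour:
            assert blob[r, c]
            neigh = [padded[r, c + 1], padded[r + 2, c + 1],
                     padded[r + 1, c], padded[r + 1, c + 2]]
            assert not all(neigh)  # 4-adjacent to background or image edge

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            extract_contour(_mask(np.zeros((8, 8))))


class TestFitEllipse:
    @pytest.mark.parametrize(
        "center,major,minor,rot",
        [((60, 80), 90, 40, 25), ((0, 0), 50, 50, 0), ((10, -5), 30, 29.5, 140)],
    )
    def test_exact_recovery_from_sampled_points(self, center, major, minor, rot):
        pts = _sample_ellipse(center, major, minor, rot)
        e = fit_ellipse(pts)
        assert e.center == pytest.approx(center, abs=1e-6)
        assert e.major_axis == pytest.approx(major, rel=1e-6)
        assert e.minor_axis == pytest.approx(minor, rel=1e-6)
        if major - minor > 1e-6:
            diff = abs(e.rotation_deg - rot % 180)
            assert min(diff, 180 - diff) < 1e-6

    def test_circle_radius_10(self):
        pts = _sample_ellipse((5, 5), 20, 20, 0)
        e = fit_ellipse(pts)
        assert e.major_axis == pytest.approx(20, rel=1e-6)
        assert e.minor_axis == pytest.approx(20, rel=1e-6)

    def test_matches_skimage_ellipse_model(self):
        # independent implementation of the same direct least-squares fit
        EllipseModel = pytest.importorskip("skimage.measure").EllipseModel
        pts = _sample_ellipse((40, 55), 70, 30, 65) + np.array([0.01, -0.02])
        e = fit_ellipse(pts)
        model = EllipseModel.from_estimate(pts[:, ::-1])
        assert bool(model)
        assert e.center == pytest.approx((model.center[1], model.center[0]), abs=1e-8)
        assert e.major_axis == pytest.approx(2 * model.axis_lengths[0], rel=1e-8)
        assert e.minor_axis == pytest.approx(2 * model.axis_lengths[1], rel=1e-8)

    def test_too_few_or_collinear_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_ellipse(np.array([(0, 0), (1, 1), (2, 0), (0, 2)]))
        line_pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError):
            fit_ellipse(line_pts)


class TestEllipseArea:
    def test_analytic_values(self):
        e = Ellipse(center=(0, 0), major_axis=20, minor_axis=10, rotation_deg=0)
        assert ellipse_area(e) == pytest.approx(50 * np.pi)
        c = Ellipse(center=(0, 0), major_axis=10, minor_axis=10, rotation_deg=0)
        assert ellipse_area(c) == pytest.approx(25 * np.pi)

    def test_rasterized_pixel_count_within_2_percent(self):
        rr, cc = np.indices((200, 200))
        inside = ((rr - 100) / 30) ** 2 + ((cc - 100) / 45) ** 2 <= 1
        analytic = np.pi * 30 * 45
        assert inside.sum() == pytest.approx(analytic, rel=0.02)

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            Ellipse(center=(0, 0), major_axis=5, minor_axis=10, rotation_deg=0)


class TestMeasureCAx:
    def test_aligned_septum_gives_zero(self):
        out = generate_phantom(PhantomSpec.from_targets(0.0, 0.30, seed=3))
        assert measure_cax(out.bundle).angle_deg <= 1.0

    def test_45_degree_phantom(self):
        out = generate_phantom(PhantomSpec.from_targets(45.0, 0.30, seed=3))
        assert measure_cax(out.bundle).angle_deg == pytest.approx(45.0, abs=2.0)

    def test_missing_spine_names_label(self, phantom_256, scheme):
        grid = phantom_256.anatomy_map.grid.copy()
        grid[grid == scheme.id_of("Spine")] = 0
        broken = LabelMap(grid=grid, scheme=scheme)
        with pytest.raises(ValueError, match="Spine"):
            measure_cax(broken)

    def test_signed_angle_magnitude_matches(self, phantom_512):
        res = measure_cax(phantom_512.bundle)
        assert abs(res.signed_angle_deg) == pytest.approx(res.angle_deg)


class TestMeasureCTR:
    def test_heart_identical_to_thorax_gives_ratio_one(self, scheme):
        rr, cc = np.indices((128, 128))
        region = ((rr - 64) / 40) ** 2 + ((cc - 64) / 50) ** 2 <= 1
        # heart area annotated; thorax falls back to the union of foreground,
        # which is the same region -> both ellipses identical
        grid = np.where(region, scheme.id_of("Heart Area"), 0).astype(np.int32)
        res = measure_ctr(LabelMap(grid=grid, scheme=scheme))
        assert res.ratio == pytest.approx(1.0, abs=1e-6)

    def test_analytic_axis_ratio(self):
        spec = PhantomSpec(
            image_size=(256, 256), thorax_axes=(160, 120), heart_axes=(60, 40),
            true_cax_deg=20.0, septum_thickness=6, spine_radius=8, seed=5,
        )
        out = generate_phantom(spec)
        assert out.true_ctr == pytest.approx(0.125)
        assert measure_ctr(out.bundle).ratio == pytest.approx(0.125, rel=0.03)

    def test_ratio_invariant_under_90_degree_rotation(self, phantom_512):
        base = measure_ctr(phantom_512.bundle).ratio
        rot = LabelMap(
            grid=np.rot90(phantom_512.area_map.grid).copy(),
            scheme=phantom_512.area_map.scheme,
        )
        assert measure_ctr(rot).ratio == pytest.approx(base, abs=1e-3)

    def test_ctr_result_consistency(self, phantom_512):
        res = measure_ctr(phantom_512.bundle)
        assert res.ratio == pytest.approx(
            ellipse_area(res.heart_ellipse) / ellipse_area(res.thorax_ellipse),
            abs=1e-12,
        )
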