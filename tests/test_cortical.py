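"""Cortical geometry: peripheral box tiling, microtubule box counts against
a sampling oracle, tip-to-edge distances against a per-edge oracle,
residence lifetimes, displacement and signal-fraction summaries."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from adhesiomics.cortical import (
    displacement_stats,
    membrane_residence,
    mt_box_counts,
    patch_quantify,
    peripheral_boxes,
    signal_fraction,
    tip_edge_distance,
)


def point_segment_distance(p, a, b):
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.hypot(*(a + t * ab - p)))


def polygon_edge_distance(p, vertices):
    """Min distance from p to any polygon edge (brute-force per edge)."""
    v = np.asarray(vertices)
    closed = np.vstack([v, v[:1]])
    return min(
        point_segment_distance(p, closed[i], closed[i + 1]) for i in range(len(v))
    )


def ray_casting_inside(p, vertices, eps=1e-9):
    v = np.asarray(vertices, dtype=float)
    x, y = p
    inside = False
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xint:
                inside = not inside
    return inside


class TestPeripheralBoxes:
    def test_square_cell_40um(self):
        sq = [(0, 0), (40, 0), (40, 40), (0, 40)]
        boxes = peripheral_boxes(sq, length_um=5, depth_um=2)
        assert len(boxes) == 32
        assert not any(b.short for b in boxes)
        for b in boxes:
            assert b.arc_length == pytest.approx(5.0)
            assert b.polygon.area == pytest.approx(10.0)

    def test_box_depth(self):
        sq = [(0, 0), (40, 0), (40, 40), (0, 40)]
        box = peripheral_boxes(sq)[0].polygon  # bottom edge, away from corners
        ys = [y for _, y in box.exterior.coords]
        assert max(ys) - min(ys) == pytest.approx(2.0)

    def test_arc_coverage_equals_perimeter(self):
        tri = [(0, 0), (12, 0), (6, 9)]
        peri = Polygon(tri).exterior.length
        boxes = peripheral_boxes(tri, length_um=5, depth_um=2)
        assert sum(b.arc_length for b in boxes) == pytest.approx(peri)
        assert boxes[-1].short == (peri % 5 > 1e-9)

    def test_degenerate_polygon_errors(self):
        with pytest.raises(ValueError):
            peripheral_boxes([(0, 0), (1, 0), (2, 0)])


class TestMtBoxCounts:
    @pytest.fixture
    def square_boxes(self):
        return peripheral_boxes([(0, 0), (40, 0), (40, 40), (0, 40)])

    def test_single_crossing_counts_once(self, square_boxes):
        # vertical segment crossing only the first bottom box
        counts, _, _ = mt_box_counts([[(2.5, 0.5), (2.5, 5.0)]], square_boxes)
        assert counts[0] == 1
        assert counts.sum() == 1

    def test_shared_border_counts_in_both(self, square_boxes):
        # segment along the border between bottom boxes 0 and 1 (x = 5)
        counts, _, _ = mt_box_counts([[(5.0, 0.0), (5.0, 1.5)]], square_boxes)
        assert counts[0] == 1 and counts[1] == 1

    def test_matches_sampling_oracle(self, square_boxes):
        rng = np.random.default_rng(12)
        segments = []
        for _ in range(12):
            p = rng.uniform(1, 39, size=2)
            q = p + rng.uniform(-6, 6, size=2)
            q = np.clip(q, 0.2, 39.8)
            segments.append([tuple(p), tuple(q)])
        counts, _, _ = mt_box_counts(segments, square_boxes)
        # oracle: dense sampling along the segment, point-in-polygon by ray
        # casting against each box's vertex ring (tolerance via tiny jitter)
        oracle = np.zeros(len(square_boxes), dtype=int)
        for seg in segments:
            a, b = map(np.asarray, seg)
            samples = a + np.linspace(0, 1, 2001)[:, None] * (b - a)
            for j, box in enumerate(square_boxes):
                ring = list(box.polygon.exterior.coords)[:-1]
                if any(
                    ray_casting_inside(s, ring)
                    or polygon_edge_distance(s, ring) < 1e-9
                    for s in samples
                ):
                    oracle[j] += 1
        assert (counts == oracle).all()

    def test_total_at_least_band_crossers(self, square_boxes):
        rng = np.random.default_rng(5)
        segments = [
            [(x, 0.5), (x, 6.0)] for x in rng.uniform(1, 39, size=8)
        ]  # all enter the 2 um band
        counts, _, _ = mt_box_counts(segments, square_boxes)
        assert counts.sum() >= len(segments)


class TestTipEdgeDistance:
    def test_boundary_vertex_and_centre(self, unit_square):
        d = tip_edge_distance([[0.0, 0.0], [5.0, 5.0]], unit_square)
        assert d[0] == pytest.approx(0.0)
        assert d[1] == pytest.approx(5.0)

    def test_matches_per_edge_oracle_in_triangle(self):
        tri = [(0, 0), (10, 0), (4, 8)]
        rng = np.random.default_rng(8)
        pts = []
        while len(pts) < 20:
            p = rng.uniform(0, 10, size=2)
            if ray_casting_inside(p, tri):
                pts.append(p)
        d = tip_edge_distance(np.array(pts), tri)
        oracle = [polygon_edge_distance(p, tri) for p in pts]
        assert np.allclose(d, oracle)

    def test_rigid_motion_invariance(self):
        tri = np.array([(0, 0), (10, 0), (4, 8)], dtype=float)
        pts = np.array([(3, 2), (5, 1), (4, 4)], dtype=float)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([13.0, -4.0])
        d1 = tip_edge_distance(pts, tri)
        d2 = tip_edge_distance(pts @ rot.T + shift, tri @ rot.T + shift)
        assert np.allclose(d1, d2)

    def test_outside_point_strict_errors(self, unit_square):
        with pytest.raises(ValueError, match="frames \\[0\\]"):
            tip_edge_distance([[20.0, 20.0]], unit_square)
        d = tip_edge_distance([[20.0, 20.0]], unit_square, strict=False)
        assert d[0] < 0


class TestMembraneResidence:
    def test_worked_series(self):
        lifetime, _ = membrane_residence([5, 1.5, 1.5, 1.5, 5], band_um=2, dt_s=10)
        assert lifetime == pytest.approx(30.0)

    def test_never_within_band(self):
        assert membrane_residence([5, 6, 7])[0] == 0.0

    def test_entire_series_within_band(self):
        assert membrane_residence([1.0] * 7)[0] == pytest.approx(70.0)

    def test_longest_run_not_cumulative(self):
        lifetime, _ = membrane_residence([1, 1, 5, 1, 1, 1], band_um=2, dt_s=10)
        assert lifetime == pytest.approx(30.0)

    def test_monotone_in_band(self):
        rng = np.random.default_rng(2)
        series = rng.uniform(0, 6, size=50)
        lifetimes = [membrane_residence(series, band_um=b)[0] for b in (1.0, 2.0, 4.0)]
        assert lifetimes == sorted(lifetimes)
        assert lifetimes[-1] <= len(series) * 10.0

    def test_bin_labels(self):
        _, label = membrane_residence([1.0] * 3, bins=[20, 60])
        assert label == "<=60"

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            membrane_residence([])


class TestDisplacementStats:
    def make_tracks(self, coords):
        rows = [
            ("mt0", f, f * 10.0, x, y) for f, (x, y) in enumerate(coords)
        ]
        return pd.DataFrame(rows, columns=["mt_id", "frame", "t_s", "x_um", "y_um"])

    def test_stationary_track(self):
        out = displacement_stats(self.make_tracks([(1, 1)] * 5))
        assert out.loc["mt0", "mean_displacement_um"] == pytest.approx(0.0)
        assert out.loc["mt0", "n_excursions"] == 0

    def test_straight_track_unit_speed(self):
        out = displacement_stats(self.make_tracks([(i, 0) for i in range(6)]))
        assert out.loc["mt0", "mean_displacement_um"] == pytest.approx(1.0)
        assert out.loc["mt0", "excursion_speed_um"] == pytest.approx(1.0)

    def test_pause_splits_excursions(self):
        coords = [(0, 0), (1, 0), (2, 0), (2.01, 0), (3, 0), (4, 0)]
        out = displacement_stats(self.make_tracks(coords))
        assert out.loc["mt0", "n_excursions"] == 2


class TestPatchQuantify:
    def test_flat_field_near_zero(self):
        img = np.full((64, 64), 40.0)
        out = patch_quantify(img, [(6.0, 6.0)], pixel_size_um=0.25, rolling_ball_px=10)
        assert abs(out["mean_intensity"].iloc[0]) <= 0.01 * 40.0

    def test_categories_from_segments(self):
        img = np.zeros((64, 64))
        centre = (8.0, 8.0)
        crossing = [[(4.0, 8.0), (12.0, 8.0)]]
        out0 = patch_quantify(
            img, [centre], pixel_size_um=0.25, rolling_ball_px=5, segments=[]
        )
        out1 = patch_quantify(
            img, [centre], pixel_size_um=0.25, rolling_ball_px=5, segments=crossing
        )
        out3 = patch_quantify(
            img, [centre], pixel_size_um=0.25, rolling_ball_px=5, segments=crossing * 3
        )
        assert out0["category"].iloc[0] == "none"
        assert out1["category"].iloc[0] == "1-2"
        assert out3["category"].iloc[0] == "several"

    def test_patch_outside_image_errors(self):
        with pytest.raises(ValueError):
            patch_quantify(np.zeros((32, 32)), [(100.0, 100.0)], pixel_size_um=0.25)


class TestSignalFraction:
    def test_half_positive_region(self):
        mask = np.zeros((10, 20), dtype=bool)
        mask[:, :10] = True  # half of the region positive
        region = np.ones((10, 20), dtype=bool)  # 200 px * 0.5um2 px = 100 um2... use 1um px
        pct = signal_fraction(mask, [region], pixel_size_um=1.0, min_area_um2=40)
        assert pct == pytest.approx(50.0)

    def test_small_region_excluded(self):
        mask = np.ones((10, 10), dtype=bool)
        big = np.zeros((10, 10), dtype=bool)
        big[:7, :7] = True  # 49 um2 at 1 um pixels
        small = np.zeros((10, 10), dtype=bool)
        small[0:3, 0:3] = True  # 9 um2, below the 40 um2 floor
        pct = signal_fraction(mask, [big, small], pixel_size_um=1.0)
        assert pct == pytest.approx(100.0)

    def test_no_retained_region_errors(self):
        with pytest.raises(ValueError):
            signal_fraction(np.ones((4, 4), bool), [np.ones((4, 4), bool)], pixel_size_um=1.0)
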