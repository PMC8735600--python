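import datetime as dt

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString

from kelpcanopy.geo_core import (
    BANDS,
    GeometryError,
    Grid,
    Scene,
    assign_to_segments,
    coast_distance,
    read_coastline_geojson,
    read_scene,
    resample_mean,
    segment_coastline,
    write_coastline_geojson,
    write_scene,
)


def make_scene(grid, reflectance=None, **kw):
    shape = grid.shape
    refl = reflectance if reflectance is not None else np.full((6,) + shape, 0.02)
    return Scene(grid=grid, reflectance=refl,
                 land_mask=kw.pop("land_mask", np.zeros(shape, bool)),
                 cloud_mask=kw.pop("cloud_mask", np.zeros(shape, bool)),
                 sensor=kw.pop("sensor", "OLI"),
                 acquired_at=kw.pop("acquired_at", dt.datetime(2010, 3, 1)), **kw)


class TestSegmentCoastline:
    @pytest.mark.parametrize("length,expected", [
        (3000.0, [1000.0, 1000.0, 1000.0]),
        (2500.0, [1000.0, 1000.0, 500.0]),
    ])
    def test_straight_line_cut_lengths(self, length, expected):
        line = np.array([[0.0, 0.0], [length, 0.0]])
        cs = segment_coastline(line, 1000.0)
        assert [s[2] for s in cs.segments] == pytest.approx(expected)
        assert [s[0] for s in cs.segments] == list(range(len(expected)))

    def test_corner_spanning_segment(self):
        # L-shape: 900 m east then 800 m north = 1700 m total; the first cut
        # falls 100 m past the corner, so segment 0 spans it.
        line = np.array([[0.0, 0.0], [900.0, 0.0], [900.0, 800.0]])
        cs = segment_coastline(line, 1000.0)
        lengths = [s[2] for s in cs.segments]
        assert lengths == pytest.approx([1000.0, 700.0])
        seg0 = cs.segments[0][1]
        assert seg0.shape[0] == 3  # start, corner, interpolated cut
        np.testing.assert_allclose(seg0[-1], [900.0, 100.0])

    def test_arclengths_conserve_total_length(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            verts = np.cumsum(rng.uniform(-300, 300, size=(15, 2)), axis=0)
            cs = segment_coastline(verts, 1000.0)
            total = LineString(verts).length
            assert cs.total_length() == pytest.approx(total, rel=1e-6)
            assert all(s[2] == pytest.approx(1000.0) for s in cs.segments[:-1])

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(GeometryError):
            segment_coastline(np.array([[5.0, 5.0], [5.0, 5.0]]), 1000.0)


class TestCoastDistance:
    def test_point_line_distances(self, grid30):
        cs = segment_coastline(np.array([[0.0, 100.0], [0.0, -2000.0]]), 1000.0)
        df = coast_distance(grid30, cs)
        # every cell center is due east of the x=0 line: distance = x
        X, _ = grid30.cell_centers()
        np.testing.assert_allclose(df.distance, X)
        assert df.distance[0, 0] == pytest.approx(15.0)

    def test_cell_on_line_is_zero(self):
        grid = Grid(4, 4, 0.0, 0.0, 30.0)
        cs = segment_coastline(np.array([[15.0, 50.0], [15.0, -2000.0]]), 1000.0)
        df = coast_distance(grid, cs)
        assert df.distance[:, 0] == pytest.approx(0.0)

    def test_corner_distance_matches_dense_sampling(self):
        # near a convex corner the nearest point is the vertex itself
        verts = np.array([[0.0, 0.0], [500.0, 0.0], [500.0, -500.0]])
        cs = segment_coastline(verts, 1000.0)
        grid = Grid(10, 10, 520.0, 120.0, 30.0)
        df = coast_distance(grid, cs)
        line = LineString(verts)
        dense = [line.interpolate(d) for d in np.linspace(0, line.length, 20001)]
        dense_xy = np.array([[p.x, p.y] for p in dense])
        X, Y = grid.cell_centers()
        for r in range(0, 10, 3):
            for c in range(0, 10, 3):
                brute = np.min(np.hypot(dense_xy[:, 0] - X[r, c],
                                        dense_xy[:, 1] - Y[r, c]))
                assert df.distance[r, c] == pytest.approx(brute, abs=0.01)

    def test_lipschitz_between_adjacent_cells(self, grid30):
        rng = np.random.default_rng(3)
        verts = np.column_stack([600 + rng.uniform(-200, 200, 30),
                                 np.linspace(100, -1900, 30)])
        df = coast_distance(grid30, segment_coastline(verts, 1000.0))
        bound = grid30.pixel_size * np.sqrt(2) + 1e-9
        assert np.max(np.abs(np.diff(df.distance, axis=0))) <= bound
        assert np.max(np.abs(np.diff(df.distance, axis=1))) <= bound

    def test_crs_mismatch_rejected(self, grid30, straight_coastline):
        bad = Grid(4, 4, 0.0, 0.0, 30.0, crs_id="other-proj")
        with pytest.raises(GeometryError):
            coast_distance(bad, straight_coastline)


class TestAssignToSegments:
    def test_midpoint_assignment(self, straight_coastline):
        # segment 1 of the x=600 coastline spans y in [-1000, -2000]
        sid = assign_to_segments(np.array([[640.0, -1500.0]]), straight_coastline)
        assert sid.tolist() == [1]

    def test_tie_breaks_to_lower_id(self, straight_coastline):
        # equidistant from segments 0 and 1 (boundary at y = -1000)
        sid = assign_to_segments(np.array([[900.0, -1000.0]]), straight_coastline)
        assert sid.tolist() == [0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        verts = np.cumsum(rng.uniform(-400, 400, size=(12, 2)), axis=0)
        cs = segment_coastline(verts, 1000.0)
        pts = rng.uniform(verts.min() - 500, verts.max() + 500, size=(100, 2))
        got = assign_to_segments(pts, cs)
        # oracle: densely sample every segment and take the nearest point
        dense = []
        for sid, sverts, _ in cs.segments:
            line = LineString(sverts)
            for d in np.linspace(0, line.length, 2000):
                p = line.interpolate(d)
                dense.append((sid, p.x, p.y))
        dense = np.array([[s, x, y] for s, x, y in dense])
        for i, (px, py) in enumerate(pts):
            dists = np.hypot(dense[:, 1] - px, dense[:, 2] - py)
            order = np.lexsort((dense[:, 0], dists))
            assert got[i] == int(dense[order[0], 0])


class TestResampleMean:
    def setup_method(self):
        self.src_grid = Grid(6, 6, 0.0, 0.0, 10.0)
        self.dst_grid = Grid(2, 2, 0.0, 0.0, 30.0)

    def test_block_means(self):
        src = np.zeros((6, 6))
        src[:3, :3] = 1.0                      # all ones -> 1.0
        src[0, 3:6] = 1.0                      # 3 ones, 6 zeros -> 1/3
        src[3:5, :2] = np.nan                  # 4 missing, 3 ones, 2 zeros -> 0.6
        src[5, :3] = 1.0
        out = resample_mean(src, self.src_grid, self.dst_grid)
        assert out[0, 0] == pytest.approx(1.0)
        assert out[0, 1] == pytest.approx(1 / 3)
        assert out[1, 0] == pytest.approx(0.6)

    def test_all_missing_block_stays_missing(self):
        src = np.full((6, 6), np.nan)
        src[:3, 3:] = 0.5
        out = resample_mean(src, self.src_grid, self.dst_grid)
        assert np.isnan(out[0, 0]) and out[0, 1] == pytest.approx(0.5)

    def test_conserves_global_sum(self):
        rng = np.random.default_rng(5)
        src = rng.uniform(0, 1, (6, 6))
        out = resample_mean(src, self.src_grid, self.dst_grid)
        assert out.sum() * 9 == pytest.approx(src.sum())

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(GeometryError):
            resample_mean(np.zeros((6, 6)), self.src_grid,
                          Grid(2, 2, 0.0, 0.0, 25.0))

    def test_misaligned_origin_rejected(self):
        with pytest.raises(GeometryError):
            resample_mean(np.zeros((6, 6)), self.src_grid,
                          Grid(2, 2, 5.0, 0.0, 30.0))


class TestSceneIO:
    def test_round_trip_bit_exact(self, tmp_path):
        grid = Grid(64, 64, 1000.0, 2000.0, 30.0)
        rng = np.random.default_rng(0)
        # int16-scaled reflectance: quantize first so round-trip is exact
        refl = np.round(rng.uniform(-0.05, 1.2, (6, 64, 64)), 4)
        scene = make_scene(grid, refl, tide_height=0.4)
        scene.land_mask[:10] = True
        write_scene(scene, tmp_path / "scene")
        back = read_scene(tmp_path / "scene")
        # exact at the int16 fixed-point representation (scale 1e-4)
        np.testing.assert_array_equal(np.round(back.reflectance / 1e-4),
                                      np.round(refl / 1e-4))
        np.testing.assert_allclose(back.reflectance, refl, atol=5e-5)
        np.testing.assert_array_equal(back.land_mask, scene.land_mask)
        assert back.sensor == "OLI"
        assert back.acquired_at == scene.acquired_at
        assert back.tide_height == pytest.approx(0.4)

    def test_scale_convention(self, tmp_path):
        grid = Grid(2, 2, 0.0, 0.0, 30.0)
        refl = np.full((6, 2, 2), 0.1234)
        write_scene(make_scene(grid, refl), tmp_path / "s")
        back = read_scene(tmp_path / "s")
        assert back.reflectance[0, 0, 0] == pytest.approx(0.1234, abs=1e-9)

    def test_mismatched_band_shapes_rejected(self):
        grid = Grid(4, 4, 0.0, 0.0, 30.0)
        with pytest.raises(GeometryError):
            make_scene(grid, np.zeros((6, 4, 5)))

    def test_unknown_sensor_rejected(self):
        grid = Grid(4, 4, 0.0, 0.0, 30.0)
        with pytest.raises(ValueError, match="sensor"):
            make_scene(grid, sensor="MSI")


def test_coastline_geojson_round_trip(tmp_path, straight_coastline):
    path = tmp_path / "coast.geojson"
    write_coastline_geojson(straight_coastline, path)
    back = read_coastline_geojson(path)
    assert back.n_segments == straight_coastline.n_segments
    for (sa, va, la), (sb, vb, lb) in zip(straight_coastline.segments, back.segments):
        assert sa == sb and la == pytest.approx(lb)
        np.testing.assert_allclose(va, vb)
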