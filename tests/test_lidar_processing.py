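"""Ground classification, DEM/CHM rasterization and plot metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from acdpipe import lidar_processing as lp
from acdpipe.synthetic_forest import (
    LidarSimConfig,
    PointCloud,
    StandConfig,
    Terrain,
    generate_stand,
    simulate_point_cloud,
)


def make_cloud(x, y, z, label="vegetation", rn=1):
    n = len(x)
    return PointCloud(pd.DataFrame({
        "x": np.asarray(x, float), "y": np.asarray(y, float),
        "z": np.asarray(z, float),
        "return_number": np.full(n, rn), "n_returns": np.full(n, rn),
        "class": np.full(n, label, dtype=object),
    }))


class TestClassifyGround:
    def test_flat_ground_fully_recalled(self, rng):
        x, y = rng.uniform(0, 50, (2, 2000))
        cloud = make_cloud(x, y, np.full(2000, 100.0), label="vegetation")
        out = lp.classify_ground(cloud)
        assert (out.points["class"] == "ground").all()

    def test_precision_recall_against_simulator_truth(self, small_cloud):
        out = lp.classify_ground(small_cloud)
        truth = small_cloud.points["class"].to_numpy()
        pred = out.points["class"].to_numpy()
        tp = np.sum((truth == "ground") & (pred == "ground"))
        precision = tp / np.sum(pred == "ground")
        recall = tp / np.sum(truth == "ground")
        assert precision >= 0.95
        assert recall >= 0.95

    def test_passthrough_keeps_labels(self, small_cloud):
        out = lp.classify_ground(small_cloud, passthrough=True)
        assert (out.points["class"] == small_cloud.points["class"]).all()

    def test_gross_outliers_flagged_as_noise(self, small_cloud):
        out = lp.classify_ground(small_cloud)
        truth = small_cloud.points["class"].to_numpy()
        pred = out.points["class"].to_numpy()
        assert np.mean(pred[truth == "noise"] == "noise") > 0.95


class TestDemAndNormalization:
    def test_planar_terrain_gives_flat_dem(self, rng):
        x, y = rng.uniform(0, 40, (2, 3000))
        cloud = make_cloud(x, y, np.full(3000, 100.0), label="ground")
        dem = lp.build_dem(cloud, pixel_size=2.0)
        np.testing.assert_allclose(dem.values, 100.0, atol=1e-9)
        npc = lp.normalize_heights(cloud, dem)
        np.testing.assert_allclose(npc.points["height_above_ground"], 0.0,
                                   atol=1e-9)

    def test_tilted_plane_normalization(self, rng):
        # ground follows z = 100 + 0.1 x; vegetation offsets must survive
        gx, gy = rng.uniform(0, 40, (2, 8000))
        ground = make_cloud(gx, gy, 100 + 0.1 * gx, label="ground")
        vx, vy = rng.uniform(2, 38, (2, 200))
        offset = rng.uniform(3, 15, 200)
        veg = make_cloud(vx, vy, 100 + 0.1 * vx + offset, label="vegetation")
        cloud = PointCloud(pd.concat([ground.points, veg.points],
                                     ignore_index=True))
        dem = lp.build_dem(cloud, pixel_size=2.0)
        npc = lp.normalize_heights(cloud, dem)
        hag = npc.points["height_above_ground"].to_numpy()[-200:]
        # bilinear DEM error on a plane is bounded by pixel slope
        np.testing.assert_allclose(hag, offset, atol=2 * 0.1 * 2.0)

    def test_too_few_ground_points_rejected(self):
        cloud = make_cloud([0, 1], [0, 1], [5, 5], label="ground")
        with pytest.raises(ValueError, match="3 ground"):
            lp.build_dem(cloud)


class TestRasterizeChm:
    def test_single_and_mean_pixel_rules(self):
        pts = make_cloud([0.5, 2.5, 2.6], [0.5, 0.5, 0.5], [0, 0, 0])
        pts.points["height_above_ground"] = [12.5, 10.0, 20.0]
        chm = lp.rasterize_chm(pts, pixel_size=1.0, bounds=(0, 0, 3, 1))
        assert chm.values[0, 0] == pytest.approx(12.5)   # single point
        assert chm.values[0, 2] == pytest.approx(15.0)   # mean of 10 and 20

    def test_idw_noop_on_complete_grid(self, rng):
        n = 400
        x = np.repeat(np.arange(20) + 0.5, 20)
        y = np.tile(np.arange(20) + 0.5, 20)
        pts = make_cloud(x, y, np.zeros(n))
        pts.points["height_above_ground"] = rng.uniform(0, 20, n)
        chm = lp.rasterize_chm(pts, pixel_size=1.0, bounds=(0, 0, 20, 20))
        expected = pts.points["height_above_ground"].to_numpy().reshape(20, 20)
        # raster rows index y, columns index x; the fixture enumerates x slowly
        np.testing.assert_allclose(chm.values, expected.T, atol=1e-12)

    def test_ground_only_cells_are_zero(self):
        pts = make_cloud([0.5, 1.5], [0.5, 0.5], [0, 0], label="ground")
        pts.points["height_above_ground"] = [0.0, 0.0]
        chm = lp.rasterize_chm(pts, pixel_size=1.0, bounds=(0, 0, 2, 1))
        np.testing.assert_array_equal(chm.values, [[0.0, 0.0]])


class TestExtractTch:
    def test_constant_field(self):
        chm = lp.RasterGrid((0, 0), 1.0, np.full((30, 30), 10.0))
        assert lp.extract_tch(chm, box(2, 2, 22, 22)) == pytest.approx(10.0)

    def test_checkerboard_averages_to_half(self):
        vals = np.indices((20, 20)).sum(0) % 2 * 10.0
        chm = lp.RasterGrid((0, 0), 1.0, vals)
        assert lp.extract_tch(chm, box(0, 0, 20, 20)) == pytest.approx(5.0)

    def test_matches_cell_enumeration_oracle(self, rng):
        vals = rng.uniform(0, 25, (40, 40))
        chm = lp.RasterGrid((0, 0), 1.0, vals)
        poly = box(3, 7, 23, 27)
        acc = []
        for r in range(40):
            for c in range(40):
                cx, cy = c + 0.5, r + 0.5
                if poly.contains_properly(
                        __import__("shapely").Point(cx, cy)):
                    acc.append(vals[r, c])
        assert lp.extract_tch(chm, poly) == pytest.approx(np.mean(acc),
                                                          rel=1e-12)
        assert len(acc) == 400  # 20 m plot at 1 m pixels

    def test_disjoint_polygon_errors(self):
        chm = lp.RasterGrid((0, 0), 1.0, np.ones((5, 5)))
        with pytest.raises(ValueError):
            lp.extract_tch(chm, box(100, 100, 120, 120))


class TestPercentiles:
    def test_matches_sorted_interpolation_oracle(self, rng):
        h = rng.uniform(2.01, 30, 1000)
        got = lp.height_percentiles(h, cutoff=2.0)
        srt = np.sort(h)
        for lv in (25, 50, 75, 90, 95):
            pos = (len(srt) - 1) * lv / 100
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expected = srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
            assert got[f"h{lv}"] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_distribution(self):
        got = lp.height_percentiles(np.full(50, 7.5))
        assert all(v == pytest.approx(7.5) for v in got.values())

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(2.1, 40.0), min_size=1, max_size=200))
    def test_quantile_monotonicity(self, heights):
        got = lp.height_percentiles(np.array(heights))
        vals = [got[f"h{lv}"] for lv in (25, 50, 75, 90, 95)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_no_qualifying_returns_marks_undefined(self):
        got = lp.height_percentiles(np.array([0.5, 1.0]), cutoff=2.0)
        assert all(np.isnan(v) for v in got.values())


class TestDensityAndCover:
    def test_uniform_heights_match_analytic_limit(self, rng):
        h = rng.uniform(0, 20, 200_000)
        got = lp.density_percentiles(h)
        for lv in (25, 50, 75, 90, 95):
            assert got[f"d{lv}"] == pytest.approx(1 - lv / 100, abs=0.01)

    def test_nested_thresholds(self, rng):
        h = rng.gamma(2, 3, 500)
        got = lp.density_percentiles(h)
        vals = [got[f"d{lv}"] for lv in (25, 50, 75, 90, 95)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_zero_max_height_gives_zero_densities(self):
        got = lp.density_percentiles(np.zeros(10))
        assert all(v == 0.0 for v in got.values())

    def test_full_cover_when_all_first_returns_high(self):
        assert lp.canopy_cover(np.full(30, 10.0), np.ones(30)) == 1.0


class TestPlotMetricsTable:
    def test_orphan_plot_ids_rejected(self, small_npc, small_chm, small_stand,
                                      small_summaries):
        bad = small_summaries.copy()
        bad.loc[0, "plot_id"] = "ZZZ"
        with pytest.raises(ValueError, match="ZZZ"):
            lp.plot_metrics_table(small_npc, small_chm, small_stand.plots, bad)

    def test_recomputation_idempotent_and_invariants(self, small_npc, small_chm,
                                                     small_stand, small_summaries):
        t1 = lp.plot_metrics_table(small_npc, small_chm, small_stand.plots,
                                   small_summaries)
        t2 = lp.plot_metrics_table(small_npc, small_chm, small_stand.plots,
                                   small_summaries)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == len(small_stand.plots)
        # ordering invariants of the metric families
        for _, r in t1.iterrows():
            assert r.h25 <= r.h50 <= r.h75 <= r.h90 <= r.h95
            assert r.d25 >= r.d50 >= r.d75 >= r.d90 >= r.d95
            assert 0 <= r.cc <= 1
        # TCH cannot exceed the highest CHM cell in its plot
        for pid, poly in small_stand.plots.items():
            gx, gy = small_chm.cell_centers()
            import shapely
            inside = shapely.contains_xy(poly, gx, gy)
            cap = small_chm.values.ravel()[inside].max()
            assert t1.set_index("plot_id").loc[pid, "tch"] <= cap + 1e-12


class TestSceneInvariants:
    def test_tch_below_cone_apex_on_single_tree_scenes(self):
        # averaging over cone flanks always pulls TCH below apex height
        for seed, apex in ((1, 12.0), (2, 16.0), (3, 20.0)):
            cfg = StandConfig(n_plots=1, stems_per_plot=(1, 1),
                              height_curve=(1.1, 0.85, 0.0), site_sd=0.0,
                              veteran_rate=0.0, terrain=(100.0, 0.0),
                              rng_seed=seed)
            stand = generate_stand(cfg)
            d = ((apex - 1.3) / 1.1) ** (1 / 0.85)
            stand.trees = stand.trees.iloc[:1].assign(
                x=10.0, y=10.0, dbh_cm=d, height_m=apex, crown_base_m=4.0,
                crown_radius_m=3.0)
            cloud = simulate_point_cloud(
                stand, Terrain(100.0, 0.0),
                LidarSimConfig(pulse_density=10.0, vertical_noise_sd=0.0,
                               noise_fraction=0.0, rng_seed=seed))
            classified = lp.classify_ground(cloud)
            dem = lp.build_dem(classified)
            npc = lp.normalize_heights(classified, dem)
            chm = lp.rasterize_chm(npc, 1.0, bounds=(0, 0, 20, 20))
            tch = lp.extract_tch(chm, stand.plots["P001"])
            assert tch < apex

    def test_chm_refinement_stabilizes(self, small_npc, small_stand):
        # successive pixel halvings change the surface less and less
        bounds = small_stand.extent
        chm1 = lp.rasterize_chm(small_npc, 1.0, bounds=bounds)
        chm05 = lp.rasterize_chm(small_npc, 0.5, bounds=bounds)
        chm025 = lp.rasterize_chm(small_npc, 0.25, bounds=bounds)
        up1 = np.repeat(np.repeat(chm1.values, 2, 0), 2, 1)
        d10 = np.mean(np.abs(up1 - chm05.values))
        up05 = np.repeat(np.repeat(chm05.values, 2, 0), 2, 1)
        d05 = np.mean(np.abs(up05 - chm025.values))
        assert d10 >= d05
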