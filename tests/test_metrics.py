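"""Metric extraction, mode classification, normalization, clustering."""

import numpy as np
import pandas as pd
import pytest

from spherochip.geometry import Region, build_domain, closed_box_grid
from spherochip.metrics import (DOMINANCE_RATIO, METRIC_NAMES, MetricVector,
                                TransportMode, build_design_matrix,
                                classify_transport_mode, cluster_designs,
                                compute_metrics, design_query, heatmap_export,
                                minmax_normalize, volume_average)
from conftest import make_design


def mv(adv, dif, conc=1e-3, vel=1e-6, shear=1e-3) -> MetricVector:
    return MetricVector(concentration=conc, velocity=vel, shear_rate=shear,
                        advective_flux=adv, diffusive_flux=dif)


class TestVolumeAverage:
    def test_uniform_field(self):
        g = build_domain(make_design(), spacing_um=20)
        field = np.full(g.shape, 7.5)
        assert volume_average(field, g, Region.SPHEROID) == pytest.approx(7.5)

    def test_symmetric_field_gives_region_centroid(self):
        g = build_domain(make_design(), spacing_um=10)
        _, _, z = g.cell_centers_um()
        field = np.broadcast_to(z[None, None, :], g.shape)
        # the spheroid is symmetric about the chip mid-height
        assert volume_average(field, g, Region.SPHEROID) == pytest.approx(
            50.0, abs=g.spacing_um / 2)

    def test_matches_direct_summation_oracle(self):
        g = build_domain(make_design(), spacing_um=20)
        rng = np.random.default_rng(7)
        field = rng.random(g.shape)
        mask = g.region_mask(Region.WELL)
        oracle = float(sum(field[i] for i in zip(*np.nonzero(mask))) / mask.sum())
        assert volume_average(field, g, Region.WELL) == pytest.approx(oracle)

    def test_empty_region_rejected(self):
        g = closed_box_grid((4, 4, 4), 10.0)
        with pytest.raises(ValueError):
            volume_average(np.zeros(g.shape), g, Region.SPHEROID)


class TestComputeMetrics:
    def test_zero_flow_zero_drug_all_zero(self):
        from spherochip.transport import TransportProperties, solve_transport
        from test_transport import zero_flow

        g = build_domain(make_design(), spacing_um=20)
        props = TransportProperties(inlet_concentration=0.0)
        hist = solve_transport(g, zero_flow(g), props, t_end_s=20.0, dt_s=10.0)
        m = compute_metrics(g, zero_flow(g), hist, props)
        assert all(v == 0.0 for v in m.as_dict().values())

    def test_pure_diffusion_isolates_modes(self):
        from spherochip.transport import TransportProperties, solve_transport
        from test_transport import zero_flow

        g = build_domain(make_design(), spacing_um=20)
        props = TransportProperties()
        hist = solve_transport(g, zero_flow(g), props, t_end_s=600.0, dt_s=10.0)
        m = compute_metrics(g, zero_flow(g), hist, props)
        assert m.velocity == 0.0 and m.shear_rate == 0.0
        assert m.advective_flux == 0.0
        assert m.concentration > 0.0 and m.diffusive_flux > 0.0
        assert classify_transport_mode(m) is TransportMode.DIFFUSION_DOMINANT

    def test_flow_metrics_scale_linearly_with_rate(self, ref_dsc_run, unequal_dsc_run):
        # doubling Q1 only changes the field; the steady metrics of one run
        # scale exactly when both rates double (checked at solver level in
        # test_flow); here: metrics are finite, non-negative, bounded by c_in
        grid, flow, hist = ref_dsc_run
        from spherochip.transport import TransportProperties
        m = compute_metrics(grid, flow, hist, TransportProperties())
        assert 0.0 <= m.concentration <= hist.c_in * (1 + 1e-7)
        assert all(np.isfinite(v) and v >= 0 for v in m.as_dict().values())


class TestClassification:
    def test_strong_advection_ratio(self):
        assert classify_transport_mode(mv(23.0, 1.0)) is TransportMode.ADVECTION_DOMINANT

    def test_moderate_diffusion_excess_is_mixed(self):
        assert classify_transport_mode(mv(1.0, 2.3)) is TransportMode.MIXED

    def test_boundary_ratio_inclusive(self):
        assert classify_transport_mode(mv(10.0, 1.0)) is TransportMode.ADVECTION_DOMINANT
        assert classify_transport_mode(mv(1.0, 10.0)) is TransportMode.DIFFUSION_DOMINANT
        assert classify_transport_mode(mv(9.99, 1.0)) is TransportMode.MIXED

    def test_one_sided_zero_flux(self):
        assert classify_transport_mode(mv(1.0, 0.0)) is TransportMode.ADVECTION_DOMINANT
        assert classify_transport_mode(mv(0.0, 1.0)) is TransportMode.DIFFUSION_DOMINANT

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            classify_transport_mode(mv(0.0, 0.0))


class TestNormalization:
    def test_simple_column(self):
        df = pd.DataFrame({"concentration": [1.0, 3.0, 5.0]})
        out = minmax_normalize(df)
        assert out["concentration"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({"velocity": [7.0, 7.0]})
        assert minmax_normalize(df)["velocity"].tolist() == [0.0, 0.0]

    def test_idempotent_on_nonconstant_columns(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((6, 5)), columns=list(METRIC_NAMES))
        once = minmax_normalize(df)
        twice = minmax_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_range_attained(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.random((8, 5)), columns=list(METRIC_NAMES))
        out = minmax_normalize(df)
        assert np.allclose(out.min(axis=0), 0.0)
        assert np.allclose(out.max(axis=0), 1.0)


def brute_force_complete_linkage(X: np.ndarray) -> list[float]:
    """O(n^3) agglomerative oracle: merge the closest pair under
    farthest-point (complete) inter-cluster distance; return merge heights."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(np.linalg.norm(X[i] - X[j])
                        for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[0.2] * 5, [0.2] * 5, [0.9] * 5],
                          columns=list(METRIC_NAMES))
        tree = cluster_designs(df)
        assert tree.heights[0] == pytest.approx(0.0)

    def test_hand_computed_1d_example(self):
        df = pd.DataFrame({"concentration": [0.0, 1.0, 10.0]})
        tree = cluster_designs(df)
        assert tree.heights.tolist() == pytest.approx([1.0, 10.0])

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.random((12, 5)), columns=list(METRIC_NAMES))
        tree = cluster_designs(df)
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.random((8, 5))
            tree = cluster_designs(pd.DataFrame(X, columns=list(METRIC_NAMES)))
            oracle = brute_force_complete_linkage(X)
            assert tree.heights.tolist() == pytest.approx(oracle)

    def test_single_row_rejected(self):
        df = pd.DataFrame([[0.5] * 5], columns=list(METRIC_NAMES))
        with pytest.raises(ValueError):
            cluster_designs(df)


class TestHeatmapExport:
    def test_artifacts_roundtrip_and_order(self, tmp_path):
        rng = np.random.default_rng(5)
        raw = pd.DataFrame(rng.random((6, 5)), columns=list(METRIC_NAMES),
                           index=[f"D{i}" for i in range(6)])
        dm = build_design_matrix(raw)
        tree = cluster_designs(dm)
        paths = heatmap_export(dm, tree, tmp_path / "demo")
        back = pd.read_csv(paths["matrix"], index_col=0,
                           float_precision="round_trip")
        expected = dm.normalized.iloc[tree.leaf_order]
        assert list(back.index) == list(expected.index)
        assert np.array_equal(back.to_numpy(), expected.to_numpy())  # bit-exact
        merges = pd.read_csv(paths["merges"])
        assert list(merges.columns) == ["step", "left", "right", "height", "size"]
        assert paths["heatmap"].stat().st_size > 0


class TestDesignQuery:
    def _matrices(self):
        cols = list(METRIC_NAMES)
        a = pd.DataFrame([[1, 1, 1.0, 1, 1],
                          [1, 1, 1.0, 1, 1],
                          [1, 1, 2.0, 1, 1]],
                         columns=cols, index=["g0", "g1", "g2"], dtype=float)
        b = pd.DataFrame([[1.05, 1, 3.0, 1.02, 1],   # planted: shear x3 only
                          [2.0, 1, 3.0, 1.0, 1],     # other metrics move too
                          [1, 1, 2.2, 1, 1]],
                         columns=cols, index=["g0", "g1", "g2"], dtype=float)
        return a, b

    def test_planted_geometry_found(self):
        a, b = self._matrices()
        hits = design_query(a, b, "shear_rate", min_change=2.5,
                            max_other_change=1.1)
        assert hits == ["g0"]

    def test_infinite_threshold_empty(self):
        a, b = self._matrices()
        assert design_query(a, b, "shear_rate", min_change=np.inf) == []

    def test_loosening_tolerance_grows_result(self):
        a, b = self._matrices()
        tight = design_query(a, b, "shear_rate", 2.5, max_other_change=1.1)
        loose = design_query(a, b, "shear_rate", 2.5, max_other_change=3.0)
        assert set(tight) <= set(loose)
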