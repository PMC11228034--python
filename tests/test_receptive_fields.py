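"""Skeleton-to-column coverage, spherical hulls, projection, composites."""

import numpy as np
import pytest

from calyxwire import (
    ConnectivityMatrix,
    EyeMap,
    PlantedRF,
    ProjectionConfig,
    calibrate_rf_threshold,
    covered_columns,
    effective_rf,
    generate_visual_system,
    make_hex_eye,
    mollweide_project,
    rf_from_columns,
)
from calyxwire.receptive_fields import rf_size_weight_correlation


class TestCoveredColumns:
    def test_point_on_marker_covered(self, hex_eye):
        pts = hex_eye.marker_positions["M5"][[10]]
        assert hex_eye.column_ids[10] in covered_columns(pts, hex_eye, "M5", 1.0)

    def test_zero_threshold_only_exact_coincidence(self, hex_eye):
        pts = hex_eye.marker_positions["M5"][[3]]
        cov = covered_columns(pts, hex_eye, "M5", 0.0)
        assert cov == {hex_eye.column_ids[3]}

    def test_coverage_monotone_in_threshold(self, hex_eye, rng):
        pts = hex_eye.marker_positions["M5"][:5] + rng.normal(scale=500.0, size=(5, 3))
        prev = set()
        for t in (0.0, 500.0, 2000.0, 8000.0, 32_000.0):
            cov = covered_columns(pts, hex_eye, "M5", t)
            assert prev <= cov
            prev = cov

    def test_empty_skeleton_gives_empty_set(self, hex_eye):
        assert covered_columns(np.empty((0, 3)), hex_eye, "M5", 1e4) == set()


class TestRFFromColumns:
    def test_single_column_degenerate_hull(self, hex_eye):
        rf = rf_from_columns({hex_eye.column_ids[0]}, hex_eye)
        assert rf.size == 1
        np.testing.assert_allclose(rf.centroid, hex_eye.directions[0], atol=1e-12)

    def test_three_columns_hull_contains_them(self, hex_eye):
        picks = {hex_eye.column_ids[i] for i in (0, 40, 90)}
        rf = rf_from_columns(picks, hex_eye)
        assert picks <= rf.hull_columns
        assert rf.size >= 3

    def test_full_coverage_equals_all_columns(self, full_eye):
        rf = rf_from_columns(set(full_eye.column_ids), full_eye)
        assert rf.size == 759

    def test_covered_subset_of_hull_and_centroid_unit(self, hex_eye):
        picks = {hex_eye.column_ids[i] for i in range(0, 60, 7)}
        rf = rf_from_columns(picks, hex_eye)
        assert rf.covered <= rf.hull_columns
        assert np.linalg.norm(rf.centroid) == pytest.approx(1.0, abs=1e-12)

    def test_wide_field_rejected(self):
        # Two clusters of columns 160 degrees apart exceed the gnomonic
        # validity range.
        angles = np.radians([0.0, 5.0, 160.0, 165.0])
        dirs = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(4)])
        eye = EyeMap(
            column_ids=[f"c{i}" for i in range(4)],
            directions=dirs,
            marker_positions={"M5": dirs * 1e5},
        )
        with pytest.raises(ValueError, match="150"):
            rf_from_columns({"c0", "c1", "c2", "c3"}, eye)

    def test_empty_covered_rejected(self, hex_eye):
        with pytest.raises(ValueError, match="empty"):
            rf_from_columns(set(), hex_eye)


class TestThresholdCalibration:
    def test_planted_system_recovers_a_maximizing_threshold(self, full_eye):
        eye = make_hex_eye(759)
        rfs = [PlantedRF(f"n{i}", center_column=(i * 61) % 400, radius_deg=7.0) for i in range(5)]
        vs = generate_visual_system(eye, rfs, true_threshold_nm=4000.0, seed=11)
        gt = [(vs.skeletons[r.neuron_id], vs.true_covered[r.neuron_id]) for r in rfs]
        grid = [500.0, 1000.0, 2000.0, 4000.0, 8000.0, 16_000.0]
        best, scores = calibrate_rf_threshold(gt, full_eye, "M5", grid)
        assert scores[best] == max(scores.values())
        # planted fields recovered essentially exactly at the optimum
        assert scores[best] >= 0.9

    def test_grid_of_one_returns_that_value(self, hex_eye):
        pts = hex_eye.marker_positions["M5"][[0]]
        best, _ = calibrate_rf_threshold(
            [(pts, {hex_eye.column_ids[0]})], hex_eye, "M5", [1234.0]
        )
        assert best == 1234.0

    def test_exact_annotation_prefers_smallest_threshold(self, hex_eye):
        # Points exactly at the annotated markers: every threshold below
        # the inter-column spacing attains Jaccard 1; ties break low.
        ann = {hex_eye.column_ids[i] for i in (0, 1, 2)}
        pts = hex_eye.marker_positions["M5"][[0, 1, 2]]
        best, scores = calibrate_rf_threshold(
            [(pts, ann)], hex_eye, "M5", [0.0, 10.0, 100.0]
        )
        assert best == 0.0
        assert scores[0.0] == 1.0

    def test_empty_ground_truth_rejected(self, hex_eye):
        with pytest.raises(ValueError):
            calibrate_rf_threshold([], hex_eye, "M5", [1.0])


class TestMollweide:
    def test_analytic_anchor_points(self):
        cfg = ProjectionConfig(R=1.0)
        s2 = np.sqrt(2.0)
        dirs = np.array(
            [
                [1.0, 0.0, 0.0],  # equator, frontal midline
                [0.0, 0.0, 1.0],  # north pole
                [0.0, 0.0, -1.0],  # south pole
            ]
        )
        xy = mollweide_project(dirs, cfg)
        np.testing.assert_allclose(xy[0], [0.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(xy[1], [0.0, s2], atol=1e-9)
        np.testing.assert_allclose(xy[2], [0.0, -s2], atol=1e-9)

    def test_antimeridian_on_equator(self):
        # lambda = +/- pi on the equator maps to (+/- 2 sqrt(2) R, 0).
        eps = 1e-12
        dirs = np.array([[-1.0, eps, 0.0], [-1.0, -eps, 0.0]])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        xy = mollweide_project(dirs, ProjectionConfig(R=1.0))
        np.testing.assert_allclose(xy[0], [2 * np.sqrt(2), 0.0], atol=1e-9)
        np.testing.assert_allclose(xy[1], [-2 * np.sqrt(2), 0.0], atol=1e-9)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            mollweide_project(np.array([[2.0, 0.0, 0.0]]))

    def test_equal_area_property_on_latitude_bands(self):
        # The projected area of a latitude band must equal its sphere
        # fraction times the total map area (4 pi R^2 worth).
        cfg = ProjectionConfig(R=1.0)
        for phi1, phi2 in [(-0.3, 0.4), (0.1, 1.2), (-1.4, -0.2)]:
            frac = (np.sin(phi2) - np.sin(phi1)) / 2.0
            lam = np.linspace(-np.pi + 1e-9, np.pi - 1e-9, 4000)

            def band_edge(phi, lam_arr):
                phi = np.asarray(phi, dtype=float)
                d = np.column_stack(
                    [
                        np.cos(phi) * np.cos(lam_arr),
                        np.cos(phi) * np.sin(lam_arr),
                        np.sin(phi) * np.ones_like(lam_arr),
                    ]
                )
                return mollweide_project(d, cfg)

            top = band_edge(phi2, lam)
            bottom = band_edge(phi1, lam[::-1])
            # close the polygon along the elliptical map boundary at
            # lambda = +/- pi
            phi_r = np.linspace(phi2, phi1, 2000)
            right = band_edge(phi_r, np.full_like(phi_r, np.pi - 1e-9))
            phi_l = np.linspace(phi1, phi2, 2000)
            left = band_edge(phi_l, np.full_like(phi_l, -np.pi + 1e-9))
            poly = np.vstack([top, right, bottom, left])
            x, y = poly[:, 0], poly[:, 1]
            area = 0.5 * abs(np.sum(x * np.roll(y, -1) - y * np.roll(x, -1)))
            assert area == pytest.approx(4 * np.pi * frac, rel=1e-4)


class TestEffectiveRF:
    def _toy_setup(self, hex_eye):
        rf_a = rf_from_columns({hex_eye.column_ids[i] for i in (0, 1, 2)}, hex_eye)
        rf_b = rf_from_columns({hex_eye.column_ids[i] for i in (50, 51, 52)}, hex_eye)
        return {"vpnA": rf_a, "vpnB": rf_b}

    def test_single_vpn_field_is_scaled_indicator(self, hex_eye):
        rfs = self._toy_setup(hex_eye)
        m = ConnectivityMatrix(["vpnA"], ["kc1"], np.array([[7.0]]))
        f = effective_rf("kc1", m, None, None, rfs, hex_eye)
        expected_cols = {hex_eye.column_ids.index(c) for c in rfs["vpnA"].hull_columns}
        assert set(np.flatnonzero(f["direct"])) == expected_cols
        assert np.unique(f["direct"][f["direct"] > 0]).tolist() == [7.0]

    def test_disjoint_equal_weight_rfs_equal_field(self, hex_eye):
        # Two single-column (hence disjoint) fields with equal weights
        # produce equal field values on both supports.
        rfs = {
            "vpnA": rf_from_columns({hex_eye.column_ids[0]}, hex_eye),
            "vpnB": rf_from_columns({hex_eye.column_ids[120]}, hex_eye),
        }
        assert not rfs["vpnA"].hull_columns & rfs["vpnB"].hull_columns
        m = ConnectivityMatrix(["vpnA", "vpnB"], ["kc1"], np.array([[5.0], [5.0]]))
        f = effective_rf("kc1", m, None, None, rfs, hex_eye)
        vals = f["direct"][f["direct"] > 0]
        assert len(vals) == 2 and np.unique(vals).tolist() == [5.0]

    def test_normalized_fields_sum_to_one(self, hex_eye):
        rfs = self._toy_setup(hex_eye)
        m = ConnectivityMatrix(["vpnA", "vpnB"], ["kc1"], np.array([[5.0], [8.0]]))
        f = effective_rf("kc1", m, None, None, rfs, hex_eye, normalize=True)
        assert f["direct"].sum() == pytest.approx(1.0)

    def test_indirect_component_normalized_per_lvin(self, hex_eye):
        rfs = self._toy_setup(hex_eye)
        lvin_to_kc = ConnectivityMatrix(["lvin1"], ["kc1"], np.array([[6.0]]))
        vpn_to_lvin = ConnectivityMatrix(
            ["vpnA", "vpnB"], ["lvin1"], np.array([[10.0], [30.0]])
        )
        direct = ConnectivityMatrix(["vpnA"], ["kc1"], np.array([[0.0]]))
        f = effective_rf("kc1", direct, lvin_to_kc, vpn_to_lvin, rfs, hex_eye)
        # LVIN field normalized to 1, then scaled by 6 synapses.
        assert f["indirect"].sum() == pytest.approx(6.0)

    def test_kc_without_visual_input_gets_empty_fields(self, hex_eye):
        rfs = self._toy_setup(hex_eye)
        m = ConnectivityMatrix(["vpnA"], ["kc1"], np.array([[0.0]]))
        f = effective_rf("kc1", m, None, None, rfs, hex_eye)
        assert not f["direct"].any() and not f["indirect"].any()

    def test_pearson_hook_matches_bruteforce_covariance(self, rng):
        sizes = rng.integers(10, 700, size=30).astype(float)
        syn = 2.0 * sizes + rng.normal(scale=50.0, size=30)
        r = rf_size_weight_correlation(sizes, syn)
        cx = sizes - sizes.mean()
        cy = syn - syn.mean()
        brute = float(np.sum(cx * cy) / np.sqrt(np.sum(cx**2) * np.sum(cy**2)))
        assert r == pytest.approx(brute, abs=1e-12)


class TestRFMonotonicity:
    def test_rf_size_monotone_in_threshold_for_every_planted_neuron(self, full_eye):
        eye = make_hex_eye(759)
        rfs = [PlantedRF(f"n{i}", center_column=(i * 97) % 300, radius_deg=6.0) for i in range(4)]
        vs = generate_visual_system(eye, rfs, seed=12)
        for nid, pts in vs.skeletons.items():
            sizes = []
            for t in (500.0, 1000.0, 2000.0, 4000.0, 8000.0):
                cov = covered_columns(pts, full_eye, "M5", t)
                sizes.append(rf_from_columns(cov, full_eye).size if cov else 0)
            assert sizes == sorted(sizes)
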