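"""Synthetic BOLD generator: atlas construction, determinism, spectral
content, planted-edge calibration, and achievability limits."""

import numpy as np
import pytest
from scipy.signal import periodogram

from actfc.synthdata import (
    SimulationDesign,
    component_layout,
    make_toy_atlas,
    max_achievable_delta,
    plan_edges_between_regions,
    simulate_group,
    simulate_study,
)


def _pair_corr(run, a, b):
    lin = run.linear_index
    ia, ib = np.searchsorted(lin, [a, b])
    return np.corrcoef(run.data[ia], run.data[ib])[0, 1]


class TestToyAtlas:
    def test_two_by_two_partition(self):
        d = SimulationDesign(grid_shape=(2, 2, 1), n_regions=2, n_components=1,
                             activation_fraction=0.5)
        atlas = make_toy_atlas(d)
        assert sorted(atlas.sizes.values()) == [2, 2]
        assert set(np.unique(atlas.label_volume)) == {1, 2}

    def test_sizes_sum_to_voxel_count(self):
        d = SimulationDesign()
        atlas = make_toy_atlas(d)
        assert len(atlas.sizes) == 12
        assert sum(atlas.sizes.values()) == d.n_voxels
        assert min(atlas.sizes.values()) >= 12

    def test_deterministic(self):
        d = SimulationDesign(seed=77)
        a1, a2 = make_toy_atlas(d), make_toy_atlas(d)
        np.testing.assert_array_equal(a1.label_volume, a2.label_volume)

    def test_too_many_regions_rejected(self):
        d = SimulationDesign(grid_shape=(2, 2, 1), n_regions=2, n_components=1,
                             activation_fraction=0.5)
        d.n_regions = 5
        with pytest.raises(ValueError, match="too small"):
            make_toy_atlas(d)


class TestLayoutAndMasks:
    def test_common_mask_is_intersection(self, small_design):
        _, truth = simulate_group(small_design, "A")
        inter = np.intersect1d(truth.planted_masks["A"], truth.planted_masks["B"])
        np.testing.assert_array_equal(truth.planted_common_mask, inter)

    def test_groups_have_distinct_masks(self, small_design):
        _, truth = simulate_group(small_design, "A")
        assert not np.array_equal(truth.planted_masks["A"], truth.planted_masks["B"])

    def test_supports_disjoint_within_group(self, small_layout, small_design):
        for g in small_design.group_ids:
            allv = np.concatenate(small_layout["supports"][g])
            assert len(np.unique(allv)) == len(allv)


class TestDeterminism:
    def test_identical_seed_bit_identical(self):
        d = SimulationDesign(grid_shape=(5, 4, 3), n_regions=3, subjects_per_group=2,
                             n_volumes=60, n_components=2, activation_fraction=0.3,
                             seed=9)
        r1, t1 = simulate_group(d, "B")
        r2, t2 = simulate_group(d, "B")
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(t1.planted_common_mask, t2.planted_common_mask)

    def test_different_seed_differs(self):
        kw = dict(grid_shape=(5, 4, 3), n_regions=3, subjects_per_group=1,
                  n_volumes=60, n_components=2, activation_fraction=0.3)
        r1, _ = simulate_group(SimulationDesign(seed=1, **kw), "A")
        r2, _ = simulate_group(SimulationDesign(seed=2, **kw), "A")
        assert not np.allclose(r1[0].data, r2[0].data)


class TestSpectralContent:
    def test_source_power_in_band(self, small_design):
        runs, truth = simulate_group(
            SimulationDesign(grid_shape=(6, 6, 4), n_regions=4, subjects_per_group=1,
                             n_volumes=300, n_components=3, activation_fraction=0.3,
                             noise_sigma=1e-6, seed=4),
            "A",
        )
        sup = np.flatnonzero(truth.component_maps["A"][0])
        lin = runs[0].linear_index
        src = runs[0].data[np.searchsorted(lin, sup[0])]
        freqs, pxx = periodogram(src, fs=0.5)
        inband = (freqs >= 0.01) & (freqs <= 0.08)
        assert pxx[inband].sum() / pxx.sum() > 0.90


class TestEdgeCalibration:
    def test_noiseless_same_support_correlation_one(self):
        d = SimulationDesign(grid_shape=(4, 3, 2), n_regions=2, subjects_per_group=1,
                             n_volumes=80, n_components=1, activation_fraction=0.5,
                             noise_sigma=1e-9, seed=3)
        runs, truth = simulate_group(d, "A")
        sup = truth.planted_masks["A"]
        r = _pair_corr(runs[0], int(sup[0]), int(sup[1]))
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_planted_delta_recovered_monte_carlo(self):
        """200 subjects/group: mean correlation difference within 0.4 +/- 0.05."""
        base = dict(grid_shape=(6, 5, 5), n_regions=4, subjects_per_group=200,
                    n_volumes=150, n_components=3, activation_fraction=0.3, seed=11)
        lay = component_layout(SimulationDesign(**base))
        a = int(lay["supports"]["A"][0][0])
        b = int(lay["supports"]["A"][1][0])
        d = SimulationDesign(planted_edges=[(a, b, 0.4)], **base)
        ra = np.mean([_pair_corr(r, a, b) for r in simulate_group(d, "A")[0]])
        rb = np.mean([_pair_corr(r, a, b) for r in simulate_group(d, "B")[0]])
        assert rb - ra == pytest.approx(0.4, abs=0.05)

    def test_null_design_no_mean_difference(self):
        """No planted edges: between-group delta of a cross-component edge
        stays within +/-0.03 at 500 subjects/group (Monte-Carlo null)."""
        base = dict(grid_shape=(4, 4, 2), n_regions=2, subjects_per_group=500,
                    n_volumes=150, n_components=3, activation_fraction=0.4, seed=21)
        d = SimulationDesign(**base)
        lay = component_layout(d)
        a = int(lay["supports"]["A"][0][0])
        b = int(lay["supports"]["A"][1][0])
        ra = np.mean([_pair_corr(r, a, b) for r in simulate_group(d, "A")[0]])
        rb = np.mean([_pair_corr(r, a, b) for r in simulate_group(d, "B")[0]])
        assert abs(rb - ra) < 0.03

    def test_unachievable_delta_rejected_naming_edge(self, small_layout):
        sup = small_layout["supports"]["A"]
        a, b = int(sup[0][0]), int(sup[1][0])
        # at sigma=0.5 the ceiling is 0.2, so delta 0.5 must be rejected
        d = SimulationDesign(
            grid_shape=(6, 6, 4), n_regions=4, subjects_per_group=2,
            n_volumes=150, n_components=4, activation_fraction=0.3,
            noise_sigma=0.5, seed=101, planted_edges=[(a, b, 0.5)],
        )
        with pytest.raises(ValueError, match=f"{a}, {b}"):
            simulate_group(d, "A")

    def test_same_component_edge_rejected(self, small_design, small_layout):
        sup = small_layout["supports"]["A"][0]
        d = SimulationDesign(
            grid_shape=(6, 6, 4), n_regions=4, subjects_per_group=2,
            n_volumes=150, n_components=4, activation_fraction=0.3,
            noise_sigma=1.0, seed=101,
            planted_edges=[(int(sup[0]), int(sup[1]), 0.3)],
        )
        with pytest.raises(ValueError, match="share a component"):
            simulate_group(d, "A")

    def test_achievability_bound(self):
        assert max_achievable_delta(1.0) == pytest.approx(0.5)
        assert max_achievable_delta(0.5) == pytest.approx(0.2)


class TestPlanEdges:
    def test_edges_land_in_requested_regions(self, small_design, small_atlas):
        edges = plan_edges_between_regions(small_design, small_atlas, 1, 2, 3, 0.4)
        labels = small_atlas.labels_flat
        assert len(edges) == 3
        for a, b, d in edges:
            assert {int(labels[a]), int(labels[b])} == {1, 2}
            assert d == 0.4

    def test_requesting_too_many_edges_fails(self, small_design, small_atlas):
        with pytest.raises(ValueError, match="plantable"):
            plan_edges_between_regions(small_design, small_atlas, 1, 2, 500, 0.4)


def test_simulate_study_returns_both_groups(small_design):
    groups, truth = simulate_study(small_design)
    assert set(groups) == {"A", "B"}
    assert len(groups["A"]) == small_design.subjects_per_group
    assert truth.planted_common_mask.size > 0
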