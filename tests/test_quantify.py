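"""Cluster statistics, pooling, group comparison, cell fluorescence."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cracquant import (
    CFP,
    YFP,
    FieldOfView,
    GroupCountError,
    Image2D,
    IncompatibleTablesError,
    SegmentationParams,
    TirfSimParams,
    cluster_metrics,
    compare_groups,
    label_clusters,
    metric_histogram,
    pool_clusters,
    segment_cells,
    segment_image,
    simulate_tirf_fov,
    total_cell_fluorescence,
)
from cracquant.quantify import ClusterTable


def _fov(cfp, yfp, cell_id="c", condition="g"):
    return FieldOfView(
        cell_id=cell_id,
        condition=condition,
        images={CFP: Image2D(np.asarray(cfp, float)), YFP: Image2D(np.asarray(yfp, float))},
    )


def exact_mannwhitney_oracle(x, y):
    """Independent oracle: U by direct pairwise counting, p by enumerating
    every assignment of pooled values to the first group."""
    def u_stat(a, b):
        return sum(
            1.0 if ai > bi else (0.5 if ai == bi else 0.0) for ai in a for bi in b
        )

    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    d_obs = abs(u_stat(x, y) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        grp = [pooled[i] for i in combo]
        if abs(u_stat(grp, rest) - mu) >= d_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


class TestClusterMetrics:
    def test_uniform_square_cluster(self):
        lab = np.zeros((8, 8), dtype=int)
        lab[2:5, 2:5] = 1
        labeled = label_clusters(lab > 0, min_area_px=1)
        fov = _fov(np.full((8, 8), 6.0), np.full((8, 8), 3.0))
        table = cluster_metrics(labeled, fov)
        row = table.records.iloc[0]
        assert row.area_px == 9
        assert row.mean_cfp == pytest.approx(6.0)
        assert row.mean_yfp == pytest.approx(3.0)
        assert row.ratio_cfp_yfp == pytest.approx(2.0)
        assert (row.centroid_row, row.centroid_col) == (3.0, 3.0)

    def test_ratio_scales_linearly_with_cfp_gain(self):
        fov, _ = simulate_tirf_fov(TirfSimParams(
            image_height_px=128, image_width_px=128, n_spots=10,
            background_base=0.0, background_gradient=(0.0, 0.0),
            photon_gain=1.0, read_noise_sd=0.0, seed=2,
        ))
        labeled = segment_image(fov[YFP])
        base = cluster_metrics(labeled, fov)
        scaled_fov = FieldOfView(
            cell_id=fov.cell_id, condition=fov.condition,
            images={CFP: Image2D(3.0 * fov[CFP].pixels), YFP: fov[YFP]},
        )
        tripled = cluster_metrics(labeled, scaled_fov)
        np.testing.assert_allclose(
            tripled.records.ratio_cfp_yfp, 3.0 * base.records.ratio_cfp_yfp
        )
        np.testing.assert_array_equal(tripled.records.area_px, base.records.area_px)

    def test_means_equal_explicit_per_pixel_summation(self):
        fov, _ = simulate_tirf_fov(TirfSimParams(
            image_height_px=96, image_width_px=96, n_spots=5, seed=6,
        ))
        labeled = segment_image(fov[YFP])
        table = cluster_metrics(labeled, fov)
        for _, row in table.records.iterrows():
            sel = labeled.labels == row.cluster_id
            assert row.mean_cfp == pytest.approx(fov[CFP].pixels[sel].mean())
            assert row.mean_yfp == pytest.approx(fov[YFP].pixels[sel].mean())
            assert row.area_px == sel.sum()

    def test_dimension_mismatch_rejected(self):
        labeled = label_clusters(np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError, match="dimensions"):
            cluster_metrics(labeled, _fov(np.ones((9, 8)), np.ones((9, 8))))

    def test_zero_yfp_cluster_has_nan_ratio(self):
        lab = np.zeros((6, 6), dtype=int)
        lab[1:3, 1:3] = 1
        labeled = label_clusters(lab > 0, min_area_px=1)
        table = cluster_metrics(labeled, _fov(np.full((6, 6), 2.0), np.zeros((6, 6))))
        assert np.isnan(table.records.ratio_cfp_yfp.iloc[0])


class TestPooling:
    def _table(self, n, cell="c", cond="g", params=None):
        df = pd.DataFrame({
            "cluster_id": np.arange(1, n + 1), "cell_id": cell, "condition": cond,
            "area_px": np.full(n, 5), "mean_cfp": 1.0, "mean_yfp": 2.0,
            "ratio_cfp_yfp": 0.5, "centroid_row": 0.0, "centroid_col": 0.0,
        })
        return ClusterTable(df, params or SegmentationParams())

    def test_counts_are_additive_and_fields_verbatim(self):
        pooled = pool_clusters([self._table(10, "a"), self._table(15, "b")])
        assert len(pooled) == 25
        assert list(pooled.records.cell_id.unique()) == ["a", "b"]
        pd.testing.assert_frame_equal(
            pooled.records.iloc[:10].reset_index(drop=True), self._table(10, "a").records
        )

    def test_empty_list_rejected(self):
        with pytest.raises(IncompatibleTablesError):
            pool_clusters([])

    def test_mixed_parameters_rejected(self):
        other = SegmentationParams(tile_px=64)
        with pytest.raises(IncompatibleTablesError):
            pool_clusters([self._table(3), self._table(3, params=other)])


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        df = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3, "v": [1, 2, 3, 1, 2, 3]})
        cmp = compare_groups(df, "v")
        assert cmp.p_value >= 0.99
        assert cmp.direction == 0

    def test_fully_separated_small_groups_exact_p(self):
        df = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3, "v": [1, 2, 3, 4, 5, 6]})
        cmp = compare_groups(df, "v")
        assert cmp.p_value == pytest.approx(0.1)
        assert cmp.test_name == "mannwhitney-exact"
        assert cmp.direction == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        # half the cases use discrete values to force ties
        if seed % 2:
            x = rng.choice([1.0, 2.0, 3.0], n1)
            y = rng.choice([1.0, 2.0, 3.0], n2)
        else:
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
        df = pd.DataFrame({"condition": ["a"] * n1 + ["b"] * n2,
                           "v": np.concatenate([x, y])})
        cmp = compare_groups(df, "v")
        assert cmp.p_value == pytest.approx(exact_mannwhitney_oracle(x, y))

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "condition": ["a"] * 40 + ["b"] * 40,
            "v": np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)]),
        })
        cmp = compare_groups(df, "v")
        assert cmp.test_name == "mannwhitney-asymptotic"
        ref = stats.mannwhitneyu(
            df.v[:40], df.v[40:], alternative="two-sided", method="asymptotic"
        )
        assert cmp.p_value == pytest.approx(float(ref.pvalue))

    def test_sem_uses_n_minus_one(self):
        df = pd.DataFrame({"condition": ["a"] * 2 + ["b"] * 2, "v": [1.0, 3.0, 5.0, 5.0]})
        cmp = compare_groups(df, "v")
        assert cmp.sem[0] == pytest.approx(np.std([1, 3], ddof=1) / np.sqrt(2))

    def test_wrong_group_count_rejected(self):
        with pytest.raises(GroupCountError):
            compare_groups(pd.DataFrame({"condition": ["a"] * 3, "v": [1, 2, 3]}), "v")
        df3 = pd.DataFrame({"condition": ["a", "b", "c"], "v": [1, 2, 3]})
        with pytest.raises(GroupCountError):
            compare_groups(df3, "v")

    def test_welch_alternative_available(self):
        df = pd.DataFrame({"condition": ["a"] * 5 + ["b"] * 5,
                           "v": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]})
        cmp = compare_groups(df, "v", test="welch")
        assert cmp.test_name == "welch-t"
        assert 0 < cmp.p_value < 0.05


class TestHistogram:
    def test_explicit_edges_count_correctly(self):
        df = pd.DataFrame({"condition": "g", "area_px": [4, 5, 100]})
        hist = metric_histogram(df, "area_px", [0, 10, 1000])
        np.testing.assert_array_equal(hist["count_g"], [2, 1])

    def test_counts_conserved_and_match_bruteforce_binning(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 100, 500)
        df = pd.DataFrame({"condition": "g", "m": vals})
        edges = np.linspace(0, 100.0001, 11)
        hist = metric_histogram(df, "m", edges)
        assert hist["count_g"].sum() == 500
        # brute-force re-binning by explicit comparison loop
        expected = [
            sum(1 for v in vals if lo <= v < hi) for lo, hi in zip(edges[:-2], edges[1:-1])
        ]
        expected.append(sum(1 for v in vals if edges[-2] <= v <= edges[-1]))
        np.testing.assert_array_equal(hist["count_g"], expected)

    def test_non_monotone_edges_rejected(self):
        df = pd.DataFrame({"condition": "g", "m": [1.0]})
        with pytest.raises(ValueError):
            metric_histogram(df, "m", [0, 5, 5, 10])


class TestCellFluorescence:
    def _disk_image(self, centers, radius=10, level=1.0, shape=(128, 128)):
        img = np.zeros(shape)
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        for r, c in centers:
            img[(rows - r) ** 2 + (cols - c) ** 2 <= radius**2] = level
        return img

    def test_single_disk_segments_as_one_cell(self):
        img = self._disk_image([(40, 40)])
        cells = segment_cells(img, min_cell_area_px=50)
        assert cells.n_clusters == 1
        assert cells.mask.sum() == (img > 0).sum()

    def test_two_disks_segment_as_two_cells(self):
        cells = segment_cells(self._disk_image([(30, 30), (90, 90)]), min_cell_area_px=50)
        assert cells.n_clusters == 2

    def test_blank_image_gives_no_cells(self):
        assert segment_cells(np.zeros((64, 64))).n_clusters == 0

    def test_total_fluorescence_constant_cell(self):
        lab = np.zeros((10, 10), dtype=int)
        lab[0, :] = 1  # 10-px cell
        cells = label_clusters(lab > 0, min_area_px=1)
        out = total_cell_fluorescence(cells, np.full((10, 10), 7.0), background=2.0)
        assert out.total_fluorescence.iloc[0] == pytest.approx(50.0)
        assert not out.flagged_negative.iloc[0]

    def test_negative_total_flagged_not_clamped(self):
        lab = np.zeros((10, 10), dtype=int)
        lab[0, :] = 1
        cells = label_clusters(lab > 0, min_area_px=1)
        out = total_cell_fluorescence(cells, np.full((10, 10), 1.0), background=2.0)
        assert out.total_fluorescence.iloc[0] == pytest.approx(-10.0)
        assert bool(out.flagged_negative.iloc[0])

    def test_totals_match_explicit_summation_loop(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 100, (64, 64))
        marker = self._disk_image([(20, 20), (45, 45)], radius=8, shape=(64, 64))
        cells = segment_cells(marker, min_cell_area_px=50)
        out = total_cell_fluorescence(cells, img, background=10.0)
        for _, row in out.iterrows():
            sel = cells.labels == row.cell_id
            assert row.total_fluorescence == pytest.approx((img[sel] - 10.0).sum())
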