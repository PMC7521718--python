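import numpy as np
import pandas as pd
import pytest
import scipy.interpolate
import scipy.stats

import zonerecon as zr
from zonerecon.containers import CellOrder, ZonationProfile
from zonerecon.profiles import (
    assign_groups,
    compare_datasets,
    correlate_profiles,
    group_profile,
    posterior_weighted_profile,
    scale_profile,
    smooth_profile,
    test_zonation_kruskal as kruskal_zonation_test,
    test_zonation_linear as linear_zonation_test,
)


def bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up: adj_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.minimum.accumulate((m / np.arange(m, 0, -1)) * p[order][::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _matrix(values, gene_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    return zr.ExpressionMatrix(values, gene_ids, [f"c{i}" for i in range(values.shape[1])])


class TestAssignGroups:
    @pytest.mark.parametrize(
        "n,expected_sizes",
        [
            (18, [2] * 9),
            (20, [3, 3, 2, 2, 2, 2, 2, 2, 2]),
            (66, [8, 8, 8, 7, 7, 7, 7, 7, 7]),
        ],
    )
    def test_remainder_goes_to_first_groups(self, n, expected_sizes):
        labels = assign_groups(CellOrder(np.arange(n)))
        sizes = [int((labels == j).sum()) for j in range(1, 10)]
        assert sizes == expected_sizes

    def test_partition_contiguous_along_order(self):
        order = CellOrder(np.random.default_rng(0).permutation(30))
        labels = assign_groups(order)
        along = labels[order.permutation]
        assert np.all(np.diff(along) >= 0)  # non-decreasing blocks
        assert set(labels) == set(range(1, 10))

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            assign_groups(CellOrder(np.arange(5)))


class TestGroupProfile:
    def test_mean_vs_median_on_skewed_group(self):
        m = _matrix([[1, 2, 9]])
        groups = np.array([1, 1, 1])
        assert group_profile(m, groups, "mean").values[0, 0] == pytest.approx(4.0)
        assert group_profile(m, groups, "median").values[0, 0] == pytest.approx(2.0)

    def test_singleton_group_returns_cell_value(self):
        m = _matrix([[7.0, 1.0]])
        groups = np.array([1, 2])
        for stat in ("mean", "median"):
            assert group_profile(m, groups, stat).values[0, 0] == 7.0

    def test_constant_gene_constant_profile(self):
        m = _matrix([np.full(9, 3.0)])
        prof = group_profile(m, np.arange(1, 10), "mean")
        assert np.all(prof.values == 3.0)


class TestPosteriorProfile:
    def test_hard_posterior_reduces_to_mean_profile(self):
        m = _matrix([[1, 2, 3, 4]])
        groups = np.array([1, 1, 2, 2])
        post = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        soft = posterior_weighted_profile(m, post)
        hard = group_profile(m, groups, "mean")
        np.testing.assert_allclose(soft.values, hard.values)

    def test_uniform_posterior_gives_grand_mean(self):
        m = _matrix([[2, 4, 6]])
        post = np.full((3, 9), 1 / 9)
        out = posterior_weighted_profile(m, post)
        np.testing.assert_allclose(out.values, 4.0)

    def test_hand_arithmetic_two_cells(self):
        m = _matrix([[4.0, 8.0]])
        post = np.array([[0.75, 0.25], [0.25, 0.75]])
        out = posterior_weighted_profile(m, post)
        np.testing.assert_allclose(out.values, [[5.0, 7.0]])

    def test_bad_row_sums_rejected(self):
        m = _matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            posterior_weighted_profile(m, np.array([[0.5, 0.4], [0.5, 0.5]]))


class TestScaleProfile:
    def _profile(self, rows):
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return ZonationProfile([f"g{i}" for i in range(rows.shape[0])], rows, "mean")

    def test_linear_row_hits_zero_one(self):
        prof = scale_profile(self._profile(np.arange(1.0, 19.0, 2.0)))  # 1,3,..,17
        assert prof.values.min() == 0.0 and prof.values.max() == 1.0
        assert prof.values[0, 1] == pytest.approx(2 / 16)

    def test_constant_row_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            prof = scale_profile(self._profile(np.full(9, 5.0)))
        assert np.all(prof.values == 0.0)

    def test_scaling_scaled_profile_rejected(self):
        prof = scale_profile(self._profile(np.arange(9.0)))
        with pytest.raises(ValueError):
            scale_profile(prof)

    def test_min_max_invariant_on_random_rows(self):
        rng = np.random.default_rng(3)
        prof = scale_profile(self._profile(rng.normal(size=(20, 9)) ** 2))
        np.testing.assert_allclose(prof.values.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.values.max(axis=1), 1.0, atol=1e-12)


class TestSmoothProfile:
    def _profile(self, rows):
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return ZonationProfile([f"g{i}" for i in range(rows.shape[0])], rows, "mean")

    def test_constant_profile_reproduced(self):
        out = smooth_profile(self._profile(np.full(9, 2.0)), effective_df=4)
        np.testing.assert_allclose(out, 2.0, atol=1e-9)

    def test_linear_profile_in_penalty_null_space(self):
        y = 0.5 + 0.25 * np.arange(9.0)
        out = smooth_profile(self._profile(y), effective_df=4)
        np.testing.assert_allclose(out[0], y, atol=1e-6)

    def test_df_near_nine_interpolates(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=9)
        out = smooth_profile(self._profile(y), effective_df=9 - 1e-8)
        # oracle: the natural-cubic interpolant passes through every point
        interp = scipy.interpolate.CubicSpline(np.arange(9), y, bc_type="natural")
        np.testing.assert_allclose(out[0], interp(np.arange(9)), atol=1e-6)

    def test_df_four_shrinks_a_noisy_profile(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=9)
        out = smooth_profile(self._profile(y), effective_df=4)
        assert np.var(out[0] - out[0].mean()) < np.var(y - y.mean())

    @pytest.mark.parametrize("df", [0.5, 1.0, 9.5, 2.0])
    def test_df_out_of_range_rejected(self, df):
        with pytest.raises(ValueError):
            smooth_profile(self._profile(np.arange(9.0)), effective_df=df)


class TestCorrelateProfiles:
    def _scaled(self, rows, gene_ids=None):
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        ids = gene_ids or [f"g{i}" for i in range(rows.shape[0])]
        return scale_profile(ZonationProfile(ids, rows, "mean"))

    def test_identical_profiles_r_one(self):
        rng = np.random.default_rng(6)
        a = self._scaled(rng.normal(size=(5, 9)))
        table, median_r, dropped = correlate_profiles(a, a)
        assert np.allclose(table["r"], 1.0) and median_r == pytest.approx(1.0)
        assert not dropped

    def test_reversed_linear_profile_r_minus_one(self):
        a = self._scaled(np.arange(9.0))
        b = self._scaled(np.arange(9.0)[::-1])
        table, median_r, _ = correlate_profiles(a, b)
        assert median_r == pytest.approx(-1.0)

    def test_degenerate_genes_dropped_and_reported(self):
        with pytest.warns(UserWarning):
            a = self._scaled([[1, 2, 3, 4, 5, 6, 7, 8, 9], [1] * 9], ["lin", "flat"])
        b = self._scaled([np.arange(9.0), np.arange(9.0)], ["lin", "flat"])
        table, _, dropped = correlate_profiles(a, b)
        assert dropped == ["flat"] and list(table["gene_id"]) == ["lin"]

    def test_no_shared_genes_rejected(self):
        a = self._scaled(np.arange(9.0), ["a"])
        b = self._scaled(np.arange(9.0), ["b"])
        with pytest.raises(ValueError):
            correlate_profiles(a, b)


class TestLinearZonationTest:
    def test_exact_linear_gene_saturates(self):
        n = 10
        m = _matrix([np.arange(1.0, n + 1)])
        tab = linear_zonation_test(m, CellOrder(np.arange(n)), alpha=0.05)
        assert tab["slope"][0] == pytest.approx(1.0)
        assert tab["fit_mse"][0] == pytest.approx(0.0, abs=1e-20)
        assert 0 < tab["p_value"][0] <= np.finfo(float).tiny

    def test_constant_gene_convention(self):
        m = _matrix([np.full(8, 3.0), np.arange(8.0)])
        tab = linear_zonation_test(m, CellOrder(np.arange(8)))
        row = tab.set_index("gene_id").loc["g0"]
        assert row["slope"] == 0.0 and row["p_value"] == 1.0 and row["direction"] == "none"

    def test_direction_by_slope_sign(self):
        rng = np.random.default_rng(8)
        n = 40
        up = np.arange(n) + rng.normal(0, 0.5, n)
        down = n - np.arange(n) + rng.normal(0, 0.5, n)
        m = _matrix(np.vstack([up - up.min(), down - down.min()]), ["pp", "pc"])
        tab = linear_zonation_test(m, CellOrder(np.arange(n)), alpha=0.05).set_index("gene_id")
        assert tab.loc["pp", "direction"] == "periportal"
        assert tab.loc["pc", "direction"] == "pericentral"

    def test_bh_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.04)
        np.testing.assert_allclose(bh_oracle([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_bh_matches_step_up_oracle_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1], bh_oracle(p), atol=1e-12)

    def test_adj_p_at_least_p(self, deep_matrix, deep_order):
        tab = linear_zonation_test(deep_matrix, deep_order)
        assert np.all(tab["adj_p"] >= tab["p_value"] - 1e-15)


class TestKruskal:
    def test_hand_rank_sum_value(self):
        m = _matrix([[1, 2, 3, 4, 5, 6]])
        groups = np.array([1, 1, 2, 2, 3, 3])
        tab = kruskal_zonation_test(m, groups)
        assert tab["H"][0] == pytest.approx(4.571, abs=1e-3)

    def test_all_ties_convention(self):
        m = _matrix([np.full(6, 2.0)])
        tab = kruskal_zonation_test(m, np.array([1, 1, 2, 2, 3, 3]))
        assert tab["H"][0] == 0.0 and tab["p_value"][0] == 1.0

    def test_null_p_values_uniform(self):
        # exchangeable continuous data: p should be ~Uniform(0,1)
        rng = np.random.default_rng(10)
        m = _matrix(rng.exponential(size=(1000, 90)))
        groups = np.repeat([1, 2, 3], 30)
        tab = kruskal_zonation_test(m, groups)
        stat = scipy.stats.kstest(tab["p_value"], "uniform").statistic
        assert stat < 0.0515  # 1% KS critical value at n=1000


class TestCompareDatasets:
    def _dataset(self, values, gene_ids):
        m = _matrix(values, gene_ids)
        order = CellOrder(np.arange(m.n_cells))
        return m, linear_zonation_test(m, order, alpha=0.1)

    def test_identical_datasets_have_empty_exclusive_sets(self):
        rng = np.random.default_rng(11)
        vals = np.abs(rng.normal(size=(5, 12))) + np.arange(12)
        m, res = self._dataset(vals, [f"g{i}" for i in range(5)])
        report = compare_datasets({"a": res, "b": res}, {"a": m, "b": m})
        assert all(len(v) == 0 for v in report.exclusive.values())

    def test_gene_significant_in_a_zero_in_b_is_exclusive(self):
        n = 20
        gene_ids = ["zonated", "other"]
        va = np.vstack([np.arange(1.0, n + 1), np.ones(n)])
        vb = np.vstack([np.zeros(n), np.ones(n)])
        ma, ra = self._dataset(va, gene_ids)
        mb, rb = self._dataset(vb, gene_ids)
        report = compare_datasets({"A": ra, "B": rb}, {"A": ma, "B": mb})
        assert report.exclusive[("A", "B")] == ["zonated"]
        assert report.exclusive[("B", "A")] == []

    def test_disjoint_universes_rejected(self):
        ma, ra = self._dataset(np.ones((2, 12)) * np.arange(12), ["a1", "a2"])
        mb, rb = self._dataset(np.ones((2, 12)) * np.arange(12), ["b1", "b2"])
        with pytest.raises(ValueError):
            compare_datasets({"A": ra, "B": rb}, {"A": ma, "B": mb})
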