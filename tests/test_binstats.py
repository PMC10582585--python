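import numpy as np
import pytest
from scipy import stats

from polyqvoc.binstats import (
    SCHEMES,
    BinScheme,
    anova_oneway,
    assign_bins,
    compare_groups,
    correlate_group_means,
)
from polyqvoc.errors import BinningError, DegenerateDataError


class TestAssignBins:
    @pytest.mark.parametrize(
        "scheme,value,expected",
        [
            ("char_freq", 25, 1),
            ("char_freq", 95, 8),
            ("char_freq", 30, 1),   # first bin closed at its upper edge
            ("char_freq", 30.01, 2),
            ("ratio_10bin", 0.8, 1),
            ("ratio_10bin", 5.5, 10),
            ("ratio_10bin", 1.0, 1),
            ("min_freq", 20, 1),
            ("min_freq", 81, 8),
            ("bandwidth", 5, 1),
            ("bandwidth", 41, 9),
            ("ratio_6bin", 3.0, 1),
            ("ratio_6bin", 5.1, 6),
        ],
    )
    def test_threshold_examples(self, scheme, value, expected):
        assert assign_bins([value], SCHEMES[scheme]) == [expected]

    def test_missing_values_get_no_label(self):
        assert assign_bins([25, None, np.nan], SCHEMES["char_freq"]) == [1, None, None]

    def test_threshold_partition_dense_grid(self):
        """Every real value receives exactly one label in [1, n_bins]."""
        for scheme in (SCHEMES["char_freq"], SCHEMES["ratio_10bin"], SCHEMES["bandwidth"]):
            grid = np.linspace(-5, 150, 2000)
            labels = assign_bins(grid.tolist(), scheme)
            assert all(lbl is not None and 1 <= lbl <= scheme.n_bins for lbl in labels)
            # labels are non-decreasing along an increasing grid
            assert all(a <= b for a, b in zip(labels, labels[1:]))

    def test_rank_mode_chunks_equal_groups(self, rng):
        values = rng.uniform(0.13, 0.37, size=40).tolist()
        labels = assign_bins(values, SCHEMES["cwbw_rank5"])
        counts = {lbl: labels.count(lbl) for lbl in set(labels)}
        assert counts == {i: 5 for i in range(1, 9)}
        # group label order follows value order
        order = np.argsort(values)
        sorted_labels = [labels[i] for i in order]
        assert sorted_labels == sorted(sorted_labels)

    def test_rank_mode_non_divisible_errors(self):
        with pytest.raises(BinningError, match="7.*5"):
            assign_bins(list(range(7)), SCHEMES["cwbw_rank5"])

    def test_rank_mode_stable_on_ties(self):
        labels = assign_bins([1.0, 1.0, 1.0, 1.0], BinScheme("t", "RANK_EQUAL_SIZE", group_size=2))
        assert labels == [1, 1, 2, 2]

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            BinScheme("bad", "THRESHOLD", edges=(3, 2))
        with pytest.raises(ValueError):
            BinScheme("bad", "RANK_EQUAL_SIZE", group_size=1)


class TestCorrelateGroupMeans:
    def test_two_groups_give_plus_minus_one(self):
        result, _ = correlate_group_means(
            [1, 1, 5, 5], [2, 4, 9, 11], [1, 1, 2, 2]
        )
        assert result.r == 1.0
        result, _ = correlate_group_means(
            [1, 1, 5, 5], [11, 9, 4, 2], [1, 1, 2, 2]
        )
        assert result.r == -1.0

    def test_exact_linear_relation(self):
        x = [0, 1, 2, 3, 4, 5]
        y = [3 - 2 * v for v in x]
        result, summaries = correlate_group_means(x, y, [1, 1, 2, 2, 3, 3])
        assert result.r == pytest.approx(-1.0)
        assert len(summaries) == 3

    def test_matches_brute_force_pearson(self, rng):
        """Independent oracle: Pearson's formula applied by hand to the
        group-mean pairs."""
        x = rng.uniform(0, 10, 60)
        y = 2 - 0.5 * x + rng.normal(0, 1, 60)
        labels = rng.integers(1, 7, 60).tolist()
        result, summaries = correlate_group_means(x.tolist(), y.tolist(), labels)
        mx = np.array([g.mean_x for g in summaries])
        my = np.array([g.mean_y for g in summaries])
        num = np.sum((mx - mx.mean()) * (my - my.mean()))
        den = np.sqrt(np.sum((mx - mx.mean()) ** 2) * np.sum((my - my.mean()) ** 2))
        assert result.r == pytest.approx(num / den, rel=1e-12)
        # p from the two-sided t distribution with n_groups - 2 df
        n = len(mx)
        t = result.r * np.sqrt((n - 2) / (1 - result.r**2))
        assert result.p_value == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-9)

    def test_log10_transform_applied_per_value(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [10.0, 100.0, 1000.0, 10000.0]
        result, summaries = correlate_group_means(
            x, y, [1, 1, 2, 2], transform_y="LOG10"
        )
        # log10 before group means: means are (1.5, 3.5) not log of mean
        assert summaries[0].mean_y == pytest.approx(1.5)
        assert result.r == 1.0

    def test_missing_pairs_dropped(self):
        result, summaries = correlate_group_means(
            [1, None, 2, 5, 6], [1, 1, 2, 5, None], [1, 1, 1, 2, 2]
        )
        assert sum(g.n for g in summaries) == 3

    def test_relabeling_and_affine_invariance(self, rng):
        x = rng.uniform(0, 5, 30).tolist()
        y = rng.uniform(0, 5, 30).tolist()
        labels = rng.integers(1, 5, 30).tolist()
        r0 = correlate_group_means(x, y, labels)[0].r
        relabeled = [f"bin_{l}" for l in labels]
        assert correlate_group_means(x, y, relabeled)[0].r == pytest.approx(r0)
        y_aff = [3.0 * v + 7.0 for v in y]
        assert correlate_group_means(x, y_aff, labels)[0].r == pytest.approx(r0)

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(DegenerateDataError):
            correlate_group_means([1, 2], [1, 2], [1, 1])

    def test_degenerate_means_errors(self):
        with pytest.raises(DegenerateDataError, match="degenerate_means"):
            correlate_group_means([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 2, 2])


class TestCompareGroups:
    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        values = np.concatenate([a, b])
        labels = ["a"] * 12 + ["b"] * 15
        comp = compare_groups(values, labels)
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert comp.f_stat == pytest.approx(t**2, rel=1e-10)

    def test_anova_matches_scipy(self, rng):
        groups = [rng.normal(m, 1, n) for m, n in [(0, 8), (0.5, 12), (1.2, 10)]]
        f, df_b, df_w, p = anova_oneway(groups)
        f_ref, p_ref = stats.f_oneway(*groups)
        assert f == pytest.approx(f_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)
        assert (df_b, df_w) == (2, 27)

    def test_extreme_separation_snk_isolates_third_group(self, rng):
        values = np.concatenate(
            [rng.normal(0, 0.01, 10), rng.normal(0, 0.01, 10), rng.normal(10, 0.01, 10)]
        )
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        comp = compare_groups(values, labels)
        assert comp.p_value < 1e-6
        assert comp.posthoc[("a", "c")] and comp.posthoc[("b", "c")]
        assert not comp.posthoc[("a", "b")]

    def test_posthoc_only_when_omnibus_significant(self, rng):
        values = rng.normal(0, 1, 30)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        comp = compare_groups(values, labels, alpha=1e-6)
        assert comp.posthoc == {}

    def test_degenerate_groups_error(self):
        with pytest.raises(DegenerateDataError):
            compare_groups([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])

    def test_too_small_groups_error(self):
        with pytest.raises(DegenerateDataError):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])
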