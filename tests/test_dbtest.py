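import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cssq
from conftest import bh_stepup_oracle, enumerate_partitions_oracle, pooled_p_oracle
from cssq.dbtest import (
    GroupDesign,
    analyze_signal,
    bh_adjust,
    enumerate_null_groupings,
    estimate_row_variance,
    filter_regions,
    fold_change,
    null_grouping_count,
    null_statistics,
    pooled_pvalues,
    welch_statistic,
)
from cssq.signal import ClusterModel, ClusterModelEntry


class TestGroupDesign:
    def test_parse_shell_syntax(self):
        d = GroupDesign.from_string("J1,J2:C1,C2")
        assert d.group_j == ("J1", "J2") and d.group_c == ("C1", "C2")
        assert (d.n_j, d.n_c, d.n) == (2, 2, 4)

    @pytest.mark.parametrize("spec", ["J1:C1,C2", "J1,J2:C1", "J1,J2:J1,C2"])
    def test_invalid_designs_rejected(self, spec):
        with pytest.raises(ValueError):
            GroupDesign.from_string(spec)


class TestFilterRegions:
    def _raw(self, values):
        from cssq.quantify import signal_from_frame

        values = np.asarray(values, dtype=float)
        return signal_from_frame(
            pd.DataFrame(values, index=[f"r{i}" for i in range(len(values))])
        )

    def test_all_zero_rows_dropped_positive_kept(self):
        keep = filter_regions(self._raw([[0, 0, 0, 0], [0, 0, 0.1, 0], [1, 1, 1, 1]]))
        assert keep.tolist() == [False, True, True]

    def test_all_positive_is_identity(self):
        keep = filter_regions(self._raw(np.ones((5, 4))))
        assert keep.all()

    def test_no_signal_errors(self):
        with pytest.raises(ValueError, match="no signal"):
            filter_regions(self._raw(np.zeros((3, 4))))


class TestEnumerateNullGroupings:
    def test_worked_example_2v2(self):
        d = GroupDesign(("J1", "J2"), ("C1", "C2"))
        groupings = enumerate_null_groupings(d)
        assert len(groupings) == 2 == null_grouping_count(2, 2)
        as_sets = {frozenset((frozenset(j), frozenset(c))) for j, c in groupings}
        assert as_sets == {
            frozenset((frozenset({"J1", "C1"}), frozenset({"J2", "C2"}))),
            frozenset((frozenset({"J1", "C2"}), frozenset({"J2", "C1"}))),
        }

    def test_3v3_count(self):
        d = GroupDesign(tuple("abc"), tuple("def"))
        assert len(enumerate_null_groupings(d)) == 9 == null_grouping_count(3, 3)

    @pytest.mark.parametrize("n_j,n_c", [(2, 2), (2, 3), (3, 3), (2, 4), (3, 4), (4, 4), (2, 6)])
    def test_matches_brute_force_partition_enumeration(self, n_j, n_c):
        ids = tuple(f"d{i}" for i in range(n_j + n_c))
        d = GroupDesign(ids[:n_j], ids[n_j:])
        groupings = enumerate_null_groupings(d)
        assert len(groupings) == null_grouping_count(n_j, n_c)
        # never the identity partition, all pairwise distinct
        keys = set()
        oracle = enumerate_partitions_oracle(ids, n_j)
        for j, c in groupings:
            assert set(j) != set(ids[:n_j])
            key = (
                frozenset((frozenset(j), frozenset(c)))
                if n_j == n_c
                else frozenset(j)
            )
            keys.add(key)
            assert key in oracle
        assert len(keys) == len(groupings)
        # brute-force count: all distinct partitions minus the original
        assert len(groupings) == len(oracle) - 1

    def test_too_many_replicates_errors(self):
        ids = tuple(f"d{i}" for i in range(14))
        with pytest.raises(ValueError, match="subsample"):
            enumerate_null_groupings(GroupDesign(ids[:7], ids[7:]))


class TestWelchStatistic:
    def test_hand_evaluated_example(self):
        assert welch_statistic(0.6, 0.2, 0.01, 0.01, 2, 2) == pytest.approx(4.0)

    def test_identical_groups_give_zero(self):
        assert welch_statistic(0.4, 0.4, 0.02, 0.03, 2, 2) == 0.0

    def test_swapping_groups_negates(self):
        t = welch_statistic(0.7, 0.2, 0.01, 0.04, 2, 3)
        assert welch_statistic(0.2, 0.7, 0.04, 0.01, 3, 2) == pytest.approx(-t)

    def test_zero_variance_sentinels(self):
        assert welch_statistic(0.5, 0.5, 0.0, 0.0, 2, 2) == 0.0
        assert welch_statistic(0.6, 0.2, 0.0, 0.0, 2, 2) == np.inf
        assert welch_statistic(0.2, 0.6, 0.0, 0.0, 2, 2) == -np.inf


class TestEstimateRowVariance:
    def _model(self, variances_by_ds, u=1.0):
        model = ClusterModel()
        for ds, variances in variances_by_ds.items():
            model.entries[ds] = ClusterModelEntry(
                dataset_id=ds,
                means=np.arange(4, dtype=float),
                variances=np.asarray(variances, dtype=float),
                sizes=np.full(4, 10),
                mins=np.zeros(4),
                maxs=np.ones(4),
                u=u,
            )
        return model

    def test_average_of_cluster_variances(self):
        model = self._model(
            {"J1": [0, 0.01, 0, 0], "J2": [0, 0, 0.03, 0]}, u=1.0
        )
        assert estimate_row_variance({"J1": "M", "J2": "H"}, model) == pytest.approx(0.02)

    def test_same_cluster_equal_variance_is_identity(self):
        model = self._model({"J1": [0, 0.05, 0, 0], "J2": [0, 0.05, 0, 0]})
        assert estimate_row_variance({"J1": 1, "J2": 1}, model) == pytest.approx(0.05)

    def test_three_replicates_average(self):
        model = self._model(
            {"a": [0.01, 0, 0, 0], "b": [0.02, 0, 0, 0], "c": [0.06, 0, 0, 0]}
        )
        assert estimate_row_variance({"a": "L", "b": "L", "c": "L"}, model) == pytest.approx(0.03)

    def test_u_rescaling_to_normalized_scale(self):
        model = self._model({"J1": [0, 4.0, 0, 0]}, u=2.0)
        assert estimate_row_variance({"J1": "M"}, model) == pytest.approx(1.0)
        assert estimate_row_variance({"J1": "M"}, model, normalized=False) == pytest.approx(4.0)


class TestPooledPvalues:
    def test_boundaries_and_hand_count(self):
        nulls = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(
            pooled_pvalues(np.array([2.5, 5.0, 0.5]), nulls), [0.5, 0.0, 1.0]
        )

    def test_ties_count_as_not_greater(self):
        nulls = np.array([[1.0, 2.0, 2.0, 3.0]])
        assert pooled_pvalues(np.array([2.0]), nulls)[0] == pytest.approx(0.25)

    def test_matches_double_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            q, z = rng.integers(1, 50), rng.integers(1, 8)
            t_obs = rng.standard_t(3, size=q)
            t_null = rng.standard_t(3, size=(q, z))
            np.testing.assert_allclose(
                pooled_pvalues(t_obs, t_null), pooled_p_oracle(t_obs, t_null)
            )

    def test_infinite_sentinels(self):
        nulls = np.array([[1.0, np.inf]])
        p = pooled_pvalues(np.array([np.inf, 0.5]), nulls)
        assert p[0] == 0.0  # inf is not > inf
        assert p[1] == 1.0

    def test_pseudo_count_option(self):
        nulls = np.array([[1.0, 2.0]])
        assert pooled_pvalues(np.array([3.0]), nulls, pseudo=True)[0] == pytest.approx(1 / 3)

    def test_empty_null_pool_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pooled_pvalues(np.array([1.0]), np.empty((0, 0)))


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_and_constant_vectors_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust(np.full(5, 0.4)), np.full(5, 0.4))

    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=100,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle(self, p):
        p = np.array(p)
        np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_monotone_and_at_least_p(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()


class TestFoldChange:
    @pytest.mark.parametrize(
        "mean_c,mean_j,expected",
        [(0.5, 0.25, 2.0), (0.2, 0.4, -2.0), (0.3, 0.3, 1.0)],
    )
    def test_branches(self, mean_c, mean_j, expected):
        assert fold_change(mean_c, mean_j) == pytest.approx(expected)

    def test_zero_denominator_uses_epsilon(self):
        assert fold_change(0.5, 0.0, eps=0.01) == pytest.approx(50.0)
        assert fold_change(0.0, 0.5, eps=0.01) == pytest.approx(-50.0)

    def test_both_zero_is_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            assert fold_change(0.0, 0.0, eps=0.01) == pytest.approx(1.0)


class TestAnalyzeSignal:
    def test_duplicated_columns_yield_no_significant_calls(self, design_2v2):
        rng = np.random.default_rng(21)
        col = np.concatenate([rng.normal(m, s, n).clip(0) for m, s, n in
                              ((0, 1, 240), (20, 3, 80), (60, 5, 50), (150, 12, 30))])
        df = pd.DataFrame(
            {ds: col for ds in ("J1", "J2", "C1", "C2")},
            index=[f"r{i}" for i in range(col.size)],
        )
        res, _ = analyze_signal(cssq.signal_from_frame(df), design_2v2, seed=5)
        assert res["significant"].sum() == 0
        retained_t = res.loc[res["retained"], "T_obs"]
        np.testing.assert_allclose(retained_t, 0.0)

    def test_group_swap_negates_t_and_preserves_p(self, small_experiment):
        raw = cssq.signal_from_frame(small_experiment.counts)
        d = GroupDesign(("J1", "J2"), ("C1", "C2"))
        d_swapped = GroupDesign(("C1", "C2"), ("J1", "J2"))
        res, _ = analyze_signal(raw, d, seed=9)
        res_sw, _ = analyze_signal(raw, d_swapped, seed=9)
        m = res["retained"].to_numpy()
        np.testing.assert_allclose(
            res.loc[m, "T_obs"], -res_sw.loc[m, "T_obs"].to_numpy(), rtol=1e-9
        )
        np.testing.assert_allclose(res.loc[m, "p"], res_sw.loc[m, "p"].to_numpy())
        np.testing.assert_allclose(res.loc[m, "p_adj"], res_sw.loc[m, "p_adj"].to_numpy())
        # FC maps to the sign-flipped reciprocal branch
        fc, fc_sw = res.loc[m, "FC"].to_numpy(), res_sw.loc[m, "FC"].to_numpy()
        both_change = (np.abs(fc) > 1) & (np.abs(fc_sw) > 1)
        np.testing.assert_allclose(fc[both_change], -fc_sw[both_change], rtol=1e-9)

    def test_results_in_input_region_order_with_dropped_marked(self, analyzed_small, small_experiment):
        res, _ = analyzed_small
        assert res["region_id"].tolist() == list(small_experiment.counts.index)
        dropped = ~res["retained"]
        assert dropped.any()
        assert res.loc[dropped, "p"].isna().all()
        assert not res.loc[dropped, "significant"].any()

    def test_significance_matches_threshold(self, analyzed_small):
        res, _ = analyzed_small
        m = res["retained"]
        np.testing.assert_array_equal(
            res.loc[m, "significant"], res.loc[m, "p_adj"] < 0.05
        )

    def test_unknown_dataset_in_design_errors(self, small_experiment):
        raw = cssq.signal_from_frame(small_experiment.counts)
        with pytest.raises(ValueError, match="unknown"):
            analyze_signal(raw, GroupDesign(("J1", "J2"), ("C1", "X9")), seed=0)


def test_null_statistics_shape_and_degenerate_input(design_2v2):
    rng = np.random.default_rng(31)
    col = np.concatenate([rng.normal(m, 1, 30).clip(0) for m in (0, 10, 25, 50)])
    df = pd.DataFrame({ds: col for ds in ("J1", "J2", "C1", "C2")},
                      index=[f"r{i}" for i in range(col.size)])
    raw = cssq.signal_from_frame(df)
    norm, model = cssq.preprocess(raw, seed=1)
    groupings = enumerate_null_groupings(design_2v2)
    t_null = null_statistics(norm, model, groupings, 2, 2)
    assert t_null.shape == (raw.q, 2)
    # identical columns -> every regrouped statistic is exactly 0
    np.testing.assert_allclose(t_null, 0.0)
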