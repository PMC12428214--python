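"""Filters, normalization laws, DEM calls, top lists and ddCt arithmetic."""

import numpy as np
import pandas as pd
import pytest

from spliceomir.annotation_io import CountMatrix, ReadAlignment
from spliceomir.expression_stats import (
    DdCtRecord, cpm, delta_delta_ct, detection_sets, exclude_mirnas,
    family_aggregate, filter_reads, fold_change_dem, size_factors,
    summarize_expression, top_lists,
)


def _reads(lengths):
    return [ReadAlignment(f"r{i}", "c1", "+", 0, n) for i, n in enumerate(lengths)]


class TestFilterReads:
    def test_min17_threshold(self):
        kept = filter_reads(_reads([16, 17, 18]))
        assert sorted(r.length for r in kept) == [17, 18]

    def test_identity_when_all_long_enough(self):
        reads = _reads([17, 25, 30])
        assert filter_reads(reads) == reads

    def test_empty_input(self):
        assert filter_reads([]) == []


def _matrix(data, groups=None):
    df = pd.DataFrame(data)
    groups = groups or {c: c.rsplit("_", 1)[0] for c in df.columns}
    return CountMatrix(df, groups)


class TestExcludeMirnas:
    def test_blacklisted_row_dropped_before_normalization(self):
        m = _matrix({"A_r1": [10, 30, 60]},
                    groups={"A_r1": "A"})
        m.counts.index = ["hsa-miR-6087", "m1", "m2"]
        out = exclude_mirnas(m)
        assert "hsa-miR-6087" not in out.counts.index
        assert out.counts["A_r1"].sum() == 90

    def test_absent_blacklist_entry_is_noop(self):
        m = _matrix({"A_r1": [1, 2]}, groups={"A_r1": "A"})
        out = exclude_mirnas(m)
        assert out.counts.equals(m.counts)

    def test_exclusion_order_changes_every_cpm(self):
        """Two-order comparison on a toy matrix: excluding a nonzero row
        first gives different CPMs than normalizing first."""
        df = pd.DataFrame({"s1": [50, 30, 20], "s2": [10, 60, 30]},
                          index=["hsa-miR-6087", "m1", "m2"])
        excl_then_cpm = cpm(df.drop(index="hsa-miR-6087"))
        cpm_then_excl = cpm(df).drop(index="hsa-miR-6087")
        assert (excl_then_cpm != cpm_then_excl).all().all()

    def test_refuses_normalized_input(self):
        m = _matrix({"A_r1": [1.0], "A_r2": [2.0]})
        m.normalization_state = "cpm"
        with pytest.raises(ValueError, match="raw"):
            exclude_mirnas(m)


class TestCpm:
    def test_arithmetic(self):
        df = pd.DataFrame({"s": [10, 30, 60]})
        assert cpm(df)["s"].tolist() == [100000.0, 300000.0, 600000.0]

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(0, 500, size=(20, 4)),
                          columns=list("abcd")) + 1
        assert np.allclose(cpm(df).sum(axis=0), 1e6, rtol=1e-9)

    def test_scale_invariance(self):
        df = pd.DataFrame({"s": [5, 10, 25]})
        assert np.allclose(cpm(df), cpm(df * 2))

    def test_zero_total_column_names_the_sample(self):
        df = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            cpm(df)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [5, 10, 20, 7, 9], "b": [5, 10, 20, 7, 9]})
        assert np.allclose(size_factors(df), [1.0, 1.0])

    def test_doubled_column_gives_sqrt2_normalized_pair(self):
        df = pd.DataFrame({"a": [5, 10, 20, 7, 9]})
        df["b"] = 2 * df["a"]
        f = size_factors(df)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])
        assert np.isclose(f["b"] / f["a"], 2.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.integers(1, 100, size=(10, 3)), columns=list("abc"))
        perm = df.sample(frac=1, random_state=2)
        assert np.allclose(size_factors(df), size_factors(perm))

    def test_no_all_positive_row_is_an_error(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="filter"):
            size_factors(df)


class TestDetectionSets:
    def test_threshold_zero_detects_all_nonzero(self):
        pooled = pd.DataFrame({"A": [0.0, 5.0], "B": [3.0, 0.0]},
                              index=["m1", "m2"])
        sets, _ = detection_sets(pooled, detect_threshold=1e-9)
        assert sets == {"A": {"m2"}, "B": {"m1"}}

    def test_partition_counts_sum_to_per_line_totals(self):
        rng = np.random.default_rng(3)
        pooled = pd.DataFrame(rng.uniform(0, 100, size=(50, 3)),
                              columns=["A", "B", "C"],
                              index=[f"m{i}" for i in range(50)])
        sets, sections = detection_sets(pooled, 30)
        from spliceomir.segmental_profiler import venn_set_totals
        totals = venn_set_totals(sections)
        for line in "ABC":
            assert totals[line] == len(sets[line])
        union = set().union(*sets.values())
        assert sum(v for k, v in sections.items() if k) == len(union)


class TestFoldChangeDem:
    def test_pseudo_count_matters_near_boundary(self):
        pooled = pd.DataFrame({"A": [500.0], "B": [100.0]}, index=["m1"])
        t = fold_change_dem(pooled, ("A", "B"), pseudo=1.0)
        assert t.loc["m1", "fold"] == pytest.approx(501 / 101)
        assert not t.loc["m1", "dem"]  # 4.96 < 5

    def test_equal_values_not_dem(self):
        pooled = pd.DataFrame({"A": [42.0], "B": [42.0]}, index=["m1"])
        t = fold_change_dem(pooled, ("A", "B"))
        assert t.loc["m1", "fold"] == 1.0 and not t.loc["m1", "dem"]

    def test_contrast_swap_symmetry(self):
        rng = np.random.default_rng(4)
        pooled = pd.DataFrame({"A": rng.uniform(0, 1000, 30),
                               "B": rng.uniform(0, 1000, 30)})
        ab = fold_change_dem(pooled, ("A", "B"))
        ba = fold_change_dem(pooled, ("B", "A"))
        assert np.allclose(ab["fold"] * ba["fold"], 1.0)
        assert (ab["dem"] == ba["dem"]).all()
        flipped = ab[ab["fold"] != 1.0]
        assert (flipped["direction"] != ba.loc[flipped.index, "direction"]).all()


class TestTopLists:
    def test_min_reads_threshold(self):
        pooled = pd.DataFrame({"A": [100.0, 90.0], "B": [60.0, 50.0]},
                              index=["keep", "drop"])
        out = top_lists(pooled, min_reads=150)
        assert list(out.index) == ["keep"]
        assert out.loc["keep", "total"] == 160.0

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(5)
        pooled = pd.DataFrame(rng.uniform(1, 500, size=(20, 3)), columns=list("ABC"))
        out = top_lists(pooled, min_reads=50)
        shares = out[[c for c in out.columns if c.endswith("_pct")]]
        assert np.allclose(shares.sum(axis=1), 100.0)
        # independent brute-force filter count
        assert len(out) == int((pooled.sum(axis=1) >= 50).sum())

    def test_ranked_by_total_descending(self):
        pooled = pd.DataFrame({"A": [10.0, 500.0, 90.0]}, index=list("xyz"))
        out = top_lists(pooled, 0)
        assert out["total"].is_monotonic_decreasing


class TestFamilyAggregate:
    def test_single_member_family(self):
        pooled = pd.DataFrame({"A": [100.0, 50.0]},
                              index=["hsa-mir-21", "hsa-let-7a"])
        res = family_aggregate(pooled, "mir-21")
        assert res["members"] == ["hsa-mir-21"]
        assert res["totals"] == {"A": 100.0}

    def test_dominant_member_and_bounded_shares(self):
        pooled = pd.DataFrame(
            {"A": [300.0, 50.0, 20.0], "B": [10.0, 90.0, 900.0]},
            index=["hsa-let-7a", "hsa-let-7b", "hsa-mir-21"],
        )
        res = family_aggregate(pooled, "let-7")
        assert res["dominant_member"] == {"A": "hsa-let-7a", "B": "hsa-let-7b"}
        assert all(0 <= v <= 100 for v in res["share_pct"].values())

    def test_unknown_family_returns_empty(self):
        pooled = pd.DataFrame({"A": [1.0]}, index=["hsa-mir-21"])
        res = family_aggregate(pooled, "mir-999")
        assert res["members"] == [] and res["totals"] == {}


class TestSummarizeExpression:
    def test_full_pass_on_simulated_counts(self, planted):
        from spliceomir.synthetic_data import simulate_counts
        *_, truth = planted
        matrix, _ = simulate_counts(truth, truth.config, seed=50)
        summ = summarize_expression(matrix)
        assert np.allclose(summ.cpm.counts.sum(axis=0), 1e6)
        assert np.isclose(np.exp(np.log(summ.size_factors).mean()), 1.0, atol=0.1)
        assert set(summ.pooled_cpm.columns) == set(truth.config.cell_lines)


class TestDeltaDeltaCt:
    def test_equal_conditions_give_fold_one(self):
        rec = DdCtRecord("t", (20.0, 20.0), (15.0, 15.0), (21.0,), (16.0,))
        out = delta_delta_ct([rec])
        assert out.loc["t", "fold"] == pytest.approx(1.0)

    def test_ddct_minus_one_doubles(self):
        rec = DdCtRecord("t", (19.0,), (15.0,), (21.0,), (16.0,))
        out = delta_delta_ct([rec])
        assert out.loc["t", "ddct"] == pytest.approx(-1.0)
        assert out.loc["t", "fold"] == pytest.approx(2.0)

    def test_replicate_triplets_near_1p5_fold(self):
        # ddCt = -0.585 -> fold = 2^0.585 ~ 1.5
        rec = DdCtRecord("t", (19.415, 19.415, 19.415), (15.0, 15.0, 15.0),
                         (20.0, 20.0, 20.0), (15.0, 15.0, 15.0))
        out = delta_delta_ct([rec])
        assert out.loc["t", "fold"] == pytest.approx(2 ** 0.585, rel=1e-6)
        assert out.loc["t", "fold"] == pytest.approx(1.5, rel=0.01)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            DdCtRecord("t", (19.0,), (), (21.0,), (16.0,))
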