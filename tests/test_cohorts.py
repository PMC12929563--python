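"""Boxplot summaries, Welch's t-test, cohort contrasts, Venn overlaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nucarray as na
from nucarray.cohorts import GeneSet, stars


def stats_table(nrls, gene_ids=None, qc=None):
    n = len(nrls)
    return pd.DataFrame(
        {
            "gene_id": gene_ids or [f"g{i}" for i in range(n)],
            "nrl_est": nrls,
            "regularity": np.linspace(0.7, 0.9, n),
            "best_offset": [60.0] * n,
            "window_coverage": [500.0] * n,
            "qc_pass": qc if qc is not None else [True] * n,
        }
    )


class TestBoxplotSummary:
    def test_symmetric_small_set(self):
        s = na.boxplot_summary([1, 2, 3, 4, 5])
        assert s["median"] == 3 and s["q1"] == 2 and s["q3"] == 4
        assert s["whisker_low"] == 1 and s["whisker_high"] == 5
        assert s["n_outliers"] == 0

    def test_constant_list(self):
        s = na.boxplot_summary([7.0] * 10)
        assert (
            s["median"] == s["q1"] == s["q3"]
            == s["whisker_low"] == s["whisker_high"] == 7.0
        )
        assert s["n_outliers"] == 0

    def test_outlier_flagged_by_hand_computation(self):
        # {1,2,3,100}: linear-interpolation quartiles Q1=1.75, Q3=27.25,
        # IQR=25.5, upper fence 27.25+38.25=65.5 -> 100 is the one outlier
        s = na.boxplot_summary([1, 2, 3, 100])
        assert s["q1"] == pytest.approx(1.75)
        assert s["q3"] == pytest.approx(27.25)
        assert s["median"] == pytest.approx(2.5)
        assert s["n_outliers"] == 1
        assert s["whisker_high"] == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            na.boxplot_summary([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=100))
    @settings(deadline=None, max_examples=100)
    def test_whiskers_within_data_range(self, values):
        s = na.boxplot_summary(values)
        assert min(values) <= s["whisker_low"] <= s["whisker_high"] <= max(values)
        assert s["q1"] <= s["median"] <= s["q3"]


class TestWelch:
    def test_identical_groups(self):
        res = na.welch_test([1, 2, 3], [1, 2, 3])
        assert res["welch_t"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)
        assert res["stars"] == "n.s."

    def test_closed_form_hand_computation(self):
        # a={165,166}, b={162,163}: s^2=0.5 each, se=sqrt(0.5/2+0.5/2),
        # t = 3/sqrt(0.5) = 4.2426, Welch-Satterthwaite df = 2,
        # p = 2*sf(4.2426, 2) = 0.0513 -> not significant
        res = na.welch_test([165, 166], [162, 163])
        assert res["welch_t"] == pytest.approx(4.2426, abs=1e-3)
        assert res["welch_df"] == pytest.approx(2.0, abs=1e-9)
        assert res["p_value"] == pytest.approx(0.0513, abs=1e-3)
        assert res["stars"] == "n.s."

    def test_both_groups_degenerate_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            na.welch_test([0, 0], [0, 0])

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            na.welch_test([1], [1, 2])

    def test_symmetry_under_group_swap(self):
        a, b = [165.2, 166.1, 164.9], [162.0, 163.4]
        r1, r2 = na.welch_test(a, b), na.welch_test(b, a)
        assert r1["welch_t"] == pytest.approx(-r2["welch_t"])
        assert r1["p_value"] == pytest.approx(r2["p_value"])
        assert r1["welch_df"] == pytest.approx(r2["welch_df"])

    @pytest.mark.parametrize(
        "p,expected",
        [(0.005, "**"), (0.0099, "**"), (0.01, "*"), (0.049, "*"),
         (0.05, "n.s."), (0.5, "n.s.")],
    )
    def test_star_thresholds(self, p, expected):
        assert stars(p) == expected


class TestCompareCohorts:
    def test_two_tier_shift_recovered(self):
        ids = [f"g{i}" for i in range(40)]
        wt = stats_table([165.0] * 40, gene_ids=ids)
        # members drop 4 bp, rest drop 2 bp
        mut_nrls = [161.0] * 15 + [163.0] * 25
        mut = stats_table(mut_nrls, gene_ids=ids)
        members = GeneSet("bound", frozenset(ids[:15]))
        res = na.compare_cohorts(wt, mut, members)
        assert res["in_set"]["delta_median"] == -4.0
        assert res["rest"]["delta_median"] == -2.0
        assert res["in_set"]["wt"]["n"] == 15
        assert res["rest"]["wt"]["n"] == 25

    def test_partition_covering_everything_rejected(self):
        ids = [f"g{i}" for i in range(10)]
        t = stats_table([165.0] * 10, gene_ids=ids)
        with pytest.raises(ValueError, match="complement is empty"):
            na.compare_cohorts(t, t, GeneSet("all", frozenset(ids)))

    def test_empty_member_side_rejected(self):
        t = stats_table([165.0] * 10)
        with pytest.raises(ValueError, match="no member genes"):
            na.compare_cohorts(t, t, GeneSet("none", frozenset(["absent"])))

    def test_universe_restricted_to_shared_qc_pass(self):
        ids = [f"g{i}" for i in range(6)]
        wt = stats_table([165.0] * 6, gene_ids=ids, qc=[True] * 5 + [False])
        mut = stats_table([163.0] * 6, gene_ids=ids)
        res = na.compare_cohorts(wt, mut, GeneSet("s", frozenset(ids[:2])))
        assert res["in_set"]["wt"]["n"] + res["rest"]["wt"]["n"] == 5


class TestAlteredSetAndVenn:
    def test_threshold_is_strict_and_absolute(self):
        d = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "delta_nrl": [-6.0, -1.0, 7.0]}
        )
        assert na.altered_nrl_set(d, 5.0).members == {"g1", "g3"}
        assert na.altered_nrl_set(d, 7.0).members == set()  # strict >
        assert na.altered_nrl_set(d, 100.0).members == set()

    def test_zero_threshold_rejected(self):
        d = pd.DataFrame({"gene_id": ["g1"], "delta_nrl": [1.0]})
        with pytest.raises(ValueError):
            na.altered_nrl_set(d, 0.0)

    def test_venn_worked_example(self):
        u = GeneSet("u", frozenset(f"g{i}" for i in range(1, 7)))
        a = GeneSet("a", frozenset(["g1", "g2", "g3"]))
        b = GeneSet("b", frozenset(["g2", "g3", "g4"]))
        assert na.venn_overlap(a, b, u) == {
            "a_only": 1, "b_only": 1, "both": 2, "neither": 2
        }

    def test_disjoint_and_equal_sets(self):
        u = GeneSet("u", frozenset(["g1", "g2", "g3", "g4"]))
        a = GeneSet("a", frozenset(["g1"]))
        b = GeneSet("b", frozenset(["g2"]))
        assert na.venn_overlap(a, b, u)["both"] == 0
        same = na.venn_overlap(a, a, u)
        assert same["a_only"] == same["b_only"] == 0

    def test_membership_outside_universe_rejected(self):
        u = GeneSet("u", frozenset(["g1"]))
        a = GeneSet("a", frozenset(["g1", "gX"]))
        with pytest.raises(ValueError, match="outside the universe"):
            na.venn_overlap(a, GeneSet("b", frozenset()), u)

    @given(
        st.sets(st.integers(0, 30)),
        st.sets(st.integers(0, 30)),
    )
    @settings(deadline=None, max_examples=100)
    def test_partition_identity(self, a, b):
        universe = GeneSet("u", frozenset(f"g{i}" for i in range(31)))
        sa = GeneSet("a", frozenset(f"g{i}" for i in a))
        sb = GeneSet("b", frozenset(f"g{i}" for i in b))
        counts = na.venn_overlap(sa, sb, universe)
        assert sum(counts.values()) == len(universe)


class TestGeneSetIO:
    def test_plain_list_and_tsv_first_column(self, tmp_path):
        p = tmp_path / "set.txt"
        p.write_text("gene_id\ng1\ng2\ng2\n")
        gs = na.read_gene_set(p, label="bound")
        assert gs.members == {"g1", "g2"} and gs.label == "bound"

    def test_replicate_median_test(self):
        wt = [stats_table([165.0, 166.0, 164.0]), stats_table([166.0, 167.0, 165.0])]
        mut = [stats_table([162.0, 163.0, 161.0]), stats_table([163.0, 164.0, 162.0])]
        res = na.replicate_median_test(wt, mut)
        assert res["medians_wt"] == [165.0, 166.0]
        assert res["medians_mut"] == [162.0, 163.0]
        assert res["welch_t"] > 0
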