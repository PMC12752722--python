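"""Repertoire statistics: summaries, CPK, clonality bins, group tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allobcr.records import RepertoireSample
from allobcr.stats import (
    ClonalityBinning, bin_clonality, compare_groups, gated_two_sample_test,
    isotype_proportions, rank_test, summarize,
)

from conftest import make_sample


class TestSummarize:
    def test_uniform_ighg1_sample(self):
        bases = "ACGT"
        rows = [
            (f"TGT{bases[i // 4]}{bases[i % 4]}CTGG", "IGHV3-23*01",
             "IGHJ4*01", "IGHG1", 100)
            for i in range(10)
        ]
        s = summarize(make_sample(rows))
        for level in ("total", "heavy", "IGHG", "IGHG1"):
            assert s.metric(level, "abundance") == 10
            assert s.metric(level, "reads") == 1000
            assert s.metric(level, "cpk") == pytest.approx(10.0)

    def test_single_expanded_clone(self):
        s = summarize(make_sample([("TGTAAATGG", "IGHV1-2", "IGHJ4", "IGHG1",
                                    1000)]))
        assert s.metric("total", "cpk") == pytest.approx(1.0)

    def test_heavy_light_split(self, heavy_light_sample):
        s = summarize(heavy_light_sample)
        assert (s.metric("heavy", "abundance"), s.metric("heavy", "reads"),
                s.metric("heavy", "cpk")) == (2, 10, pytest.approx(200.0))
        assert (s.metric("light", "abundance"), s.metric("light", "reads"),
                s.metric("light", "cpk")) == (3, 3, pytest.approx(1000.0))
        assert s.metric("total", "cpk") == pytest.approx(1000 * 5 / 13)

    def test_empty_sample_zero_counts_undefined_cpk(self):
        s = summarize(RepertoireSample("s", "STA"))
        assert s.metric("total", "abundance") == 0
        assert math.isnan(s.metric("total", "cpk"))

    def test_level_additivity(self):
        """total = heavy + light; parent reads >= sum of resolved children."""
        sample = make_sample([
            ("TGTAAATGG", "IGHV1-2", "IGHJ4", "IGHG1", 5),
            ("TGTCCCTGG", "IGHV1-2", "IGHJ4", "", 7),    # isotype-unresolved
            ("TGTGGGTGG", "IGKV1-5", "IGKJ1", "IGKC", 2),
        ])
        s = summarize(sample)
        assert s.metric("total", "abundance") == (
            s.metric("heavy", "abundance") + s.metric("light", "abundance")
        )
        iso_reads = sum(
            s.metric(level, "reads")
            for level in ("IGHA", "IGHD", "IGHE", "IGHG", "IGHM")
        )
        assert s.metric("heavy", "reads") >= iso_reads

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(1, 500), min_size=1, max_size=40))
    def test_cpk_at_most_1000(self, counts):
        rows = [
            (f"TGT{i:04d}TGG", "IGHV3-23", "IGHJ4", "IGHG1", c)
            for i, c in enumerate(counts)
        ]
        s = summarize(make_sample(rows))
        cpk = s.metric("total", "cpk")
        assert cpk <= 1000.0 + 1e-9
        if all(c == 1 for c in counts):
            assert cpk == pytest.approx(1000.0)

    def test_merge_invariance(self):
        """Splitting a record into two with the same key changes nothing."""
        rows = [("TGTAAATGG", "IGHV1-2", "IGHJ4", "IGHG1", 10),
                ("TGTCCCTGG", "IGKV1-5", "IGKJ1", "IGKC", 4)]
        split = [("TGTAAATGG", "IGHV1-2", "IGHJ4", "IGHG1", 3),
                 ("TGTAAATGG", "IGHV1-2", "IGHJ4", "IGHG1", 7),
                 ("TGTCCCTGG", "IGKV1-5", "IGKJ1", "IGKC", 4)]
        a, b = summarize(make_sample(rows)), summarize(make_sample(split))
        pd.testing.assert_frame_equal(a.table, b.table)


class TestClonalityBins:
    def test_default_partition_assignment(self):
        sample = make_sample([
            (f"TGT{i}TGG", "IGHV1-2", "IGHJ4", "IGHG1", c)
            for i, c in enumerate([1, 1, 60, 200])
        ])
        df = bin_clonality([sample])
        by_bin = df.set_index("bin")
        assert by_bin.loc["0-1", "n_clonotypes"] == 2
        assert by_bin.loc["0-1", "proportion"] == pytest.approx(0.5)
        assert by_bin.loc["2-10", "n_clonotypes"] == 0
        assert by_bin.loc["51-100", "proportion"] == pytest.approx(0.25)
        assert by_bin.loc[">=101", "proportion"] == pytest.approx(0.25)

    def test_all_singletons_in_lowest_bin(self):
        sample = make_sample([
            (f"TGT{i}TGG", "IGHV1-2", "IGHJ4", "IGHG1", 1) for i in range(5)
        ])
        df = bin_clonality([sample]).set_index("bin")
        assert df.loc["0-1", "proportion"] == pytest.approx(1.0)

    def test_empty_sample_flagged(self):
        df = bin_clonality([RepertoireSample("s", "STA")])
        assert df["proportion"].isna().all()

    def test_proportions_sum_to_one(self, heavy_light_sample):
        df = bin_clonality([heavy_light_sample])
        assert df["proportion"].sum() == pytest.approx(1.0)

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            ClonalityBinning(((0, 1), (3, 10), (11, None)))  # gap at 2
        with pytest.raises(ValueError):
            ClonalityBinning(((0, 1), (2, 10)))  # not open-ended


def summaries_from_values(values_by_group, level="total"):
    """Fabricate RepertoireSummary objects with given per-sample totals."""
    from allobcr.stats import RepertoireSummary
    from allobcr.records import LEVELS
    out = []
    i = 0
    for group, values in values_by_group.items():
        for v in values:
            table = pd.DataFrame(
                {"n_clonotypes": 0.0, "n_reads": 0.0, "cpk": math.nan},
                index=pd.Index(LEVELS, name="level"),
            )
            table.loc[level, "n_clonotypes"] = v
            table.loc[level, "n_reads"] = v
            table.loc[level, "cpk"] = v
            out.append(RepertoireSummary(f"s{i}", group, table))
            i += 1
    return out


class TestCompareGroups:
    def test_identical_groups(self):
        summ = summaries_from_values({"TCMR": [1, 2, 3], "STA": [1, 2, 3]})
        cmp = compare_groups(summ, "TCMR", "STA")
        assert cmp.fold == pytest.approx(1.0)
        assert cmp.p_value == pytest.approx(1.0)
        # midrank symmetry on the rank branch as well
        assert rank_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fold_scale(self):
        base = [3.0, 5.0, 8.0, 13.0, 21.0]
        summ = summaries_from_values(
            {"TCMR": [10 * v for v in base], "STA": base}
        )
        cmp = compare_groups(summ, "TCMR", "STA")
        assert cmp.fold == pytest.approx(10.0)

    def test_fold_equivariant_under_common_scaling(self):
        rng = np.random.default_rng(7)
        a = rng.lognormal(3, 0.5, 8)
        b = rng.lognormal(2, 0.5, 8)
        f1 = compare_groups(
            summaries_from_values({"TCMR": a, "STA": b}), "TCMR", "STA").fold
        f2 = compare_groups(
            summaries_from_values({"TCMR": 5 * a, "STA": 5 * b}),
            "TCMR", "STA").fold
        assert f1 == pytest.approx(f2)

    def test_separated_groups_tiny_p(self, rng):
        a = rng.normal(0, 1, 20)
        summ = summaries_from_values({"TCMR": a + 10, "STA": a})
        cmp = compare_groups(summ, "TCMR", "STA")
        assert cmp.p_value < 1e-6

    def test_too_few_values_error(self):
        summ = summaries_from_values({"TCMR": [1.0], "STA": [1.0, 2.0]})
        with pytest.raises(ValueError, match=">=2"):
            compare_groups(summ, "TCMR", "STA")

    def test_nan_metric_excluded_and_counted(self):
        summ = summaries_from_values(
            {"TCMR": [5.0, 6.0, 7.0], "STA": [1.0, 2.0, 3.0]}, level="IGHE",
        )
        summ[0].table.loc["IGHE", "cpk"] = math.nan
        cmp = compare_groups(summ, "TCMR", "STA", metric="cpk", level="IGHE")
        assert cmp.n_a == 2 and cmp.n_excluded == 1


class TestRankTestOracle:
    @staticmethod
    def exact_two_sided_p(a, b):
        """Enumerate every assignment of pooled ranks to group a."""
        pooled = np.concatenate([a, b])
        ranks = pd.Series(pooled).rank().to_numpy()
        n1 = len(a)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * len(b) / 2
        count = 0
        total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        return count / total

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (5, 8), (8, 8)])
    def test_matches_enumeration_without_ties(self, n1, n2, rng):
        for _ in range(3):
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.8, 1, n2)
            assert rank_test(a, b) == pytest.approx(
                self.exact_two_sided_p(a, b), abs=1e-12
            )

    def test_gate_prefers_t_for_normal_data(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.2, 1, 30)
        _, test = gated_two_sample_test(a, b)
        assert test == "t"

    def test_gate_falls_back_for_skewed_data(self, rng):
        a = rng.lognormal(0, 2, 30)
        b = rng.lognormal(0.3, 2, 30)
        _, test = gated_two_sample_test(a, b)
        assert test == "wilcoxon"


class TestIsotypeProportions:
    def make_summary(self, sid, group, reads_by_level):
        from allobcr.records import LEVELS
        from allobcr.stats import RepertoireSummary
        table = pd.DataFrame(
            {"n_clonotypes": 0.0, "n_reads": 0.0, "cpk": math.nan},
            index=pd.Index(LEVELS, name="level"),
        )
        for level, reads in reads_by_level.items():
            table.loc[level, "n_reads"] = reads
        return RepertoireSummary(sid, group, table)

    def test_single_isotype_share_is_one(self):
        s = self.make_summary("s1", "TCMR", {"IGHG": 100, "IGHG1": 100})
        df = isotype_proportions([s]).set_index("level")
        assert df.loc["IGHG1", "proportion"] == pytest.approx(1.0)

    def test_subclass_share_arithmetic(self):
        s = self.make_summary("s1", "TCMR", {
            "IGHG": 1000, "IGHG1": 919, "IGHG2": 50, "IGHG3": 21, "IGHG4": 10,
        })
        df = isotype_proportions([s]).set_index("level")
        assert df.loc["IGHG1", "proportion"] == pytest.approx(0.919)

    def test_pooled_vs_mean_of_samples(self):
        s1 = self.make_summary("s1", "TCMR", {"IGHG": 100, "IGHG1": 80})
        s2 = self.make_summary("s2", "TCMR", {"IGHG": 100, "IGHG1": 100})
        df = isotype_proportions([s1, s2])
        g1 = df[(df["level"] == "IGHG1") & (df["sample_id"] == "s1")].iloc[0]
        assert g1["pooled"] == pytest.approx(0.9)
        assert g1["mean_of_samples"] == pytest.approx(0.9)

    def test_zero_parent_reads_undefined(self):
        s = self.make_summary("s1", "TCMR", {"IGHG": 0, "IGHG1": 0})
        df = isotype_proportions([s]).set_index("level")
        assert math.isnan(df.loc["IGHG1", "proportion"])
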