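import math

import pandas as pd
import pytest

from bionerds.survey import (
    journal_overlap,
    long_tail_stats,
    normalized_frequencies,
    random_walk_bounds,
    relative_usage,
    sigma_delta,
    trajectory_exceeds,
    usage_table,
)


def meta(rows):
    return pd.DataFrame(rows, columns=["doc_id", "journal", "year"])


class TestRelativeUsage:
    def test_document_level_fraction(self):
        metadata = meta([(f"d{i}", "J", 2005) for i in range(10)])
        doc_lists = {f"d{i}": {"R": 2} for i in range(3)}
        s = relative_usage(doc_lists, metadata, "R", level="document")
        assert s.counts_by_year == {2005: 3}
        assert s.relative_by_year[2005] == pytest.approx(0.30)

    def test_never_mentioned_all_zero(self):
        metadata = meta([("d0", "J", 2004), ("d1", "J", 2005)])
        s = relative_usage({}, metadata, "FooTool")
        assert s.counts_by_year == {2004: 0, 2005: 0}
        assert all(v == 0.0 for v in s.relative_by_year.values())

    def test_mention_level_sums_counts(self):
        metadata = meta([("d0", "J", 2005), ("d1", "J", 2005)])
        doc_lists = {"d0": {"R": 2}, "d1": {"R": 3}}
        s = relative_usage(doc_lists, metadata, "R", level="mention")
        assert s.counts_by_year == {2005: 5}

    def test_document_without_year_excluded(self, caplog):
        metadata = meta([("d0", "J", 2005), ("d1", "J", None)])
        s = relative_usage({"d1": {"R": 1}}, metadata, "R")
        assert s.counts_by_year == {2005: 0}

    def test_relative_values_in_unit_interval(self):
        metadata = meta([(f"d{i}", "J", 2000 + i % 3) for i in range(12)])
        doc_lists = {f"d{i}": {"R": 1} for i in range(0, 12, 2)}
        s = relative_usage(doc_lists, metadata, "R")
        assert all(0.0 <= v <= 1.0 for v in s.relative_by_year.values())

    def test_name_grouping_casefolds(self):
        metadata = meta([("d0", "J", 2005)])
        s = relative_usage({"d0": {"blast": 1}}, metadata, "BLAST")
        assert s.counts_by_year == {2005: 1}


class TestSigmaDelta:
    def test_constant_series_zero(self):
        s = {y: 4.0 for y in range(2000, 2011)}
        assert sigma_delta(s, (2000, 2010)).sigma_delta == 0.0

    def test_small_example(self):
        s = {2000: 1, 2001: 3, 2002: 2}
        assert sigma_delta(s, (2000, 2002)).sigma_delta == 3.0

    def test_monotone_telescopes(self):
        s = {2000 + i: float(i * i) for i in range(8)}
        stat = sigma_delta(s, (2000, 2007))
        assert stat.sigma_delta == pytest.approx(s[2007] - s[2000])

    def test_reversal_invariance(self):
        values = [1.0, 5.0, 2.0, 8.0, 3.0]
        years = range(2000, 2005)
        fwd = dict(zip(years, values))
        rev = dict(zip(years, reversed(values)))
        assert (
            sigma_delta(fwd, (2000, 2004)).sigma_delta
            == sigma_delta(rev, (2000, 2004)).sigma_delta
        )

    def test_missing_years_are_zero(self):
        assert sigma_delta({2001: 2.0}, (2000, 2002)).sigma_delta == 4.0

    def test_short_range_rejected(self):
        with pytest.raises(ValueError):
            sigma_delta({2000: 1.0}, (2000, 2000))


class TestRandomWalkBounds:
    def test_zero_sd_collapses(self):
        b = random_walk_bounds([2.0, 2.0, 2.0], horizon=5)
        assert b.sd_step == 0.0
        for k in range(6):
            assert b.upper[k] == b.lower[k] == pytest.approx(k * 2.0)

    def test_unit_normal_closed_form(self):
        # sample mean 0, sample sd exactly 1
        b = random_walk_bounds([1.0, 0.0, -1.0], horizon=4)
        assert b.mean_step == pytest.approx(0.0)
        assert b.sd_step == pytest.approx(1.0)
        assert b.upper[4] == pytest.approx(4.0)
        assert b.lower[4] == pytest.approx(-4.0)

    def test_flat_variant(self):
        b = random_walk_bounds([1.0, 0.0, -1.0], horizon=4, cumulative=False)
        assert b.upper[4] == pytest.approx(2.0)
        assert b.lower[4] == pytest.approx(-2.0)

    def test_doubling_sd_doubles_half_width(self):
        base = random_walk_bounds([1.0, 0.0, -1.0], horizon=6)
        double = random_walk_bounds([2.0, 0.0, -2.0], horizon=6)
        for k in range(7):
            assert double.upper[k] - double.lower[k] == pytest.approx(
                2 * (base.upper[k] - base.lower[k])
            )

    def test_bounds_symmetric_about_cumulative_mean(self):
        b = random_walk_bounds([0.3, -0.1, 0.5, 0.2], horizon=8)
        for k in range(9):
            assert (b.upper[k] + b.lower[k]) / 2 == pytest.approx(k * b.mean_step)

    def test_trajectory_flagging(self):
        b = random_walk_bounds([1.0, 0.0, -1.0], horizon=4)
        inside = {k: 0.1 * k for k in range(5)}
        outside = {4: 10.0}
        assert not trajectory_exceeds(inside, b)
        assert trajectory_exceeds(outside, b)

    def test_too_few_changes_rejected(self):
        with pytest.raises(ValueError):
            random_walk_bounds([1.0], horizon=3)


class TestLongTail:
    def test_fraction_once(self):
        stats = long_tail_stats([10, 1, 1, 1])
        assert stats["fraction_once"] == 0.75

    def test_single_resource_top_share(self):
        stats = long_tail_stats([7], top_k=1)
        assert stats["top_k_share"] == 1.0

    def test_top_k_share(self):
        stats = long_tail_stats([5, 4, 3, 2, 1], top_k=2)
        assert stats["top_k_share"] == pytest.approx(9 / 15)

    def test_fraction_below_monotone_in_n(self):
        counts = [1, 1, 2, 3, 5, 8, 13]
        fractions = [
            long_tail_stats(counts, below_n=n)["fraction_below_n"]
            for n in range(1, 15)
        ]
        assert fractions == sorted(fractions)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            long_tail_stats([])


class TestJournalOverlap:
    def test_disjoint(self):
        r = journal_overlap({"x"}, {"y"}, {"x": 3, "y": 4})
        assert r["jaccard"] == 0.0
        assert r["intersection_share_total"] == 0.0

    def test_identical(self):
        r = journal_overlap({"x", "y"}, {"x", "y"}, {"x": 3, "y": 4})
        assert r["jaccard"] == 1.0
        assert r["intersection_share_total"] == 1.0

    def test_worked_example(self):
        counts = {"x": 10, "y": 1, "z": 1, "w": 1}
        r = journal_overlap({"x", "y", "z"}, {"x", "w"}, counts)
        assert r["jaccard"] == pytest.approx(1 / 4)
        assert r["intersection_share_total"] == pytest.approx(10 / 13)
        assert r["intersection_share_b"] == pytest.approx(10 / 11)
        assert r["intersection_share_a"] == pytest.approx(10 / 12)


class TestUsageTable:
    def test_tidy_counts_and_normalisation(self):
        metadata = meta([("d0", "J", 2004), ("d1", "J", 2004), ("d2", "J", 2005)])
        doc_lists = {
            "d0": {"R": 2, "BLAST": 1},
            "d1": {"R": 1},
            "d2": {"BLAST": 4},
        }
        table = usage_table(doc_lists, metadata, level="document")
        row = table[(table.resource == "r") & (table.year == 2004)]
        assert int(row["count"].iloc[0]) == 2
        norm = normalized_frequencies(table, top_n=2)
        for year, group in norm.groupby("year"):
            assert group["normalized"].sum() == pytest.approx(1.0)
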