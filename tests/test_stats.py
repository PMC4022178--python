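"""Genome and cohort statistics: medians, MADs, outlier thresholds, R²,
shares, and the subcategory breakdown."""

import math

import numpy as np
import pytest

from _oracles import pearson_r2, sorted_median_mad
from synologs.records import GenomeSynologSummary, SynologGroup
from synologs.stats import (
    cohort_summarize,
    linear_r2,
    median_mad,
    outlier_threshold,
    subcategory_breakdown,
    summarize_genome,
)
from synologs.records import ProteinRecord


def make_group(gid, members, subcategory=None, identity=0.95):
    return SynologGroup(
        group_id=gid, genome_id="g1", members=frozenset(members),
        min_identity=identity, mean_identity=identity,
        n_pairs=len(members) * (len(members) - 1) // 2,
        subcategory=subcategory,
    )


def make_records(n, genome="g1"):
    return [
        ProteinRecord(
            gene_id=f"x{i}", genome_id=genome, sequence="ACDEF", contig="c1",
            start=1 + 100 * i, end=100 * i + 18, strand="+",
        )
        for i in range(n)
    ]


def make_summary(genome_id, n_genes, n_groups, group_size=2, at_cutoff=None):
    s = n_groups * group_size
    return GenomeSynologSummary(
        genome_id=genome_id, n_genes=n_genes, n_synologs=s,
        n_groups=n_groups, synolog_fraction=100.0 * s / n_genes,
        mean_pair_identity=95.0 if n_groups else math.nan,
        n_groups_at_cutoff=at_cutoff,
    )


class TestMedianMad:
    @pytest.mark.parametrize(
        "values,expected",
        [([5], (5, 0)), ([1, 2, 3, 4, 100], (3, 1)), ([20, 20, 33, 7, 46], (20, 13))],
    )
    def test_known_values(self, values, expected):
        assert median_mad(values) == expected

    def test_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            vals = rng.integers(0, 50, size=rng.integers(1, 30)).tolist()
            assert median_mad(vals) == pytest.approx(sorted_median_mad(vals))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_mad([])

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=25).tolist()
        shuffled = list(vals)
        rng.shuffle(shuffled)
        assert median_mad(vals) == median_mad(shuffled)


class TestOutlierThreshold:
    def test_group_count_threshold(self):
        assert outlier_threshold(20.0, 13.0) == 46.0

    def test_fraction_threshold(self):
        assert outlier_threshold(30.0, 9.7) == pytest.approx(49.4)

    def test_degenerate(self):
        assert outlier_threshold(0, 0) == 0

    def test_negative_mad_rejected(self):
        with pytest.raises(ValueError):
            outlier_threshold(1.0, -0.1)


class TestLinearR2:
    def test_exact_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert linear_r2(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_matches_closed_form(self):
        x = [1.0, 2.0, 4.0, 7.0, 11.0]
        y = [2.0, 1.0, 5.0, 6.0, 14.0]
        assert linear_r2(x, y) == pytest.approx(pearson_r2(x, y))

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_r2([3, 3, 3], [1, 2, 3])

    def test_independent_permutation_near_zero(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=1000)
            y = rng.permutation(x)
            if linear_r2(x.tolist(), y.tolist()) < 0.05:
                hits += 1
        assert hits >= 19


class TestSummarizeGenome:
    def test_counts_from_group_sizes(self):
        groups = [make_group("g1:SG0001", [f"a{i}" for i in range(3)]),
                  make_group("g1:SG0002", ["b0", "b1"]),
                  make_group("g1:SG0003", ["c0", "c1"])]
        s = summarize_genome(groups, make_records(70))
        assert (s.n_synologs, s.n_groups) == (7, 3)
        assert s.synolog_fraction == pytest.approx(10.0)

    def test_no_groups(self):
        s = summarize_genome([], make_records(50))
        assert (s.n_synologs, s.n_groups, s.synolog_fraction) == (0, 0, 0.0)
        assert math.isnan(s.mean_pair_identity)

    def test_empty_scope_rejected(self):
        with pytest.raises(ValueError):
            summarize_genome([], [])

    def test_standard_fixture_matches_truth(self, standard_fixture, denovo_config):
        from synologs.detect import detect_synologs
        from synologs.simulate import planted_partition

        design, records, truth = standard_fixture
        groups, _, _ = detect_synologs(records, denovo_config)
        s = summarize_genome(groups, records)
        planted = planted_partition(truth)
        n_members = sum(len(v) for v in planted.values())
        assert s.n_groups == len(design.planted_groups) == 12
        assert s.n_synologs == n_members
        assert s.synolog_fraction == pytest.approx(
            100.0 * n_members / len(records)
        )


class TestSubcategoryBreakdown:
    def test_exact_tallies(self):
        groups = [make_group("a", ["a1", "a2"], "Monosaccharides"),
                  make_group("b", ["b1", "b2"], "Monosaccharides"),
                  make_group("c", ["c1", "c2"], "Fermentation"),
                  make_group("d", ["d1", "d2"], None)]
        counts = subcategory_breakdown(groups)
        assert counts == {"Monosaccharides": 2, "Fermentation": 1, "none": 1}
        assert sum(counts.values()) == len(groups)

    def test_majority_label_assigned_at_group_construction(self):
        from synologs.detect import build_groups
        from synologs.records import PairwiseHit

        records = []
        for gid, sub in [("a", "A"), ("b", "A"), ("c", "B")]:
            records.append(ProteinRecord(
                gene_id=gid, genome_id="g1", sequence="ACDEF", contig="c1",
                start=1, end=18, strand="+", subcategory=sub,
            ))
        pairs = [PairwiseHit("a", "b", 0.95, 1, 1, 9, 10, 10, 10, 40.0),
                 PairwiseHit("b", "c", 0.95, 1, 1, 9, 10, 10, 10, 40.0)]
        groups = build_groups(pairs, records)
        assert groups[0].subcategory == "A"
        assert subcategory_breakdown(groups) == {"A": 1}


class TestCohortSummarize:
    def test_single_genome_degenerate(self):
        s = make_summary("g1", 100, 5)
        cohort = cohort_summarize([s])
        m = cohort.metrics["n_groups"]
        assert m.median == m.min == m.max == 5
        assert m.mad == 0
        assert m.outlier_threshold == 5

    def test_zero_synolog_share(self):
        summaries = [make_summary(f"g{i}", 100, 0 if i < 46 else 3)
                     for i in range(943)]
        cohort = cohort_summarize(summaries)
        assert cohort.zero_synolog_share == 4.9

    def test_high_identity_share_integer_reporting(self):
        summaries = [
            make_summary(f"g{i}", 100, 3, at_cutoff=1 if i < 374 else 0)
            for i in range(943)
        ]
        cohort = cohort_summarize(summaries, share_decimals=0)
        assert cohort.high_identity_share == 40

    def test_medians_invariant_under_genome_permutation(self):
        rng = np.random.default_rng(3)
        summaries = [make_summary(f"g{i}", int(rng.integers(50, 200)),
                                  int(rng.integers(0, 10))) for i in range(40)]
        shuffled = list(summaries)
        rng.shuffle(shuffled)
        a = cohort_summarize(summaries)
        b = cohort_summarize(shuffled)
        assert a.metrics == b.metrics
        assert a.zero_synolog_share == b.zero_synolog_share

    def test_percentile_ranks_weak(self):
        summaries = [make_summary(f"g{i}", 100, g) for i, g in
                     enumerate([0, 1, 2, 3, 4, 5, 6, 7, 8, 9])]
        cohort = cohort_summarize(summaries)
        assert cohort.genome_ranks["g9"]["by_groups"] == 100.0
        assert cohort.genome_ranks["g0"]["by_groups"] == 10.0
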