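"""Detection: truncation filtering, candidate pairs, single-linkage groups,
prescreen losslessness, and family/de novo concordance."""

import numpy as np
import pytest

from conftest import small_design
from synologs.detect import (
    all_pair_hits,
    build_groups,
    candidate_pairs,
    detect_synologs,
    filter_truncated,
)
from synologs.records import DetectionConfig, PairwiseHit, ProteinRecord
from synologs.simulate import generate_genome, planted_partition, random_protein


def make_record(gene_id, seq, family=None, genome="g1", rank=0):
    return ProteinRecord(
        gene_id=gene_id, genome_id=genome, sequence=seq, contig="c1",
        start=1 + 1000 * rank, end=1000 * rank + 3 * len(seq) + 3,
        strand="+", family_id=family,
    )


def disjoint_mutants(ancestor, n_copies, n_subs, rng):
    """Copies differing from the ancestor at disjoint position sets, giving
    exact, independently controlled pairwise identities."""
    L = len(ancestor)
    positions = rng.permutation(L)
    copies = []
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for c in range(n_copies):
        out = list(ancestor)
        for p in positions[c * n_subs:(c + 1) * n_subs]:
            out[p] = next(x for x in alphabet if x != ancestor[p])
        copies.append("".join(out))
    return copies


class TestFilterTruncated:
    def test_short_family_member_flagged(self):
        rng = np.random.default_rng(0)
        seqs = [random_protein(n, rng) for n in (300, 302, 40)]
        records = [
            make_record(f"g{i}", s, family="F1", rank=i)
            for i, s in enumerate(seqs)
        ]
        cfg = DetectionConfig(mode="family", identity_threshold=None)
        kept, flagged = filter_truncated(records, cfg)
        assert flagged == ["g2"]
        assert [r.gene_id for r in kept] == ["g0", "g1"]

    def test_equal_lengths_none_flagged(self):
        rng = np.random.default_rng(1)
        records = [
            make_record(f"g{i}", random_protein(120, rng), family="F1", rank=i)
            for i in range(3)
        ]
        cfg = DetectionConfig(mode="family", identity_threshold=None)
        _, flagged = filter_truncated(records, cfg)
        assert flagged == []

    def test_denovo_mode_is_a_no_op(self):
        rng = np.random.default_rng(2)
        records = [make_record("a", random_protein(300, rng)),
                   make_record("b", random_protein(40, rng), rank=1)]
        kept, flagged = filter_truncated(records, DetectionConfig())
        assert len(kept) == 2 and flagged == []

    def test_planted_fragments_flagged_exactly(self, standard_fixture):
        _, records, truth = standard_fixture
        cfg = DetectionConfig(mode="family", identity_threshold=None)
        _, flagged = filter_truncated(records, cfg)
        expected = sorted(g for g, e in truth.items() if e.is_truncated)
        assert flagged == expected


class TestCandidatePairs:
    def test_unrelated_proteins_yield_nothing(self):
        rng = np.random.default_rng(3)
        records = [
            make_record(f"g{i}", random_protein(100, rng), rank=i)
            for i in range(5)
        ]
        assert candidate_pairs(records, DetectionConfig()) == []

    def test_identical_pair_found(self):
        rng = np.random.default_rng(4)
        seq = random_protein(90, rng)
        records = [make_record("a", seq), make_record("b", seq, rank=1),
                   make_record("c", random_protein(90, rng), rank=2)]
        pairs = candidate_pairs(records, DetectionConfig())
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a", "b")]
        assert pairs[0].identity == 1.0

    def test_planted_triple_gives_three_pairs(self):
        rng = np.random.default_rng(5)
        ancestor = random_protein(100, rng)
        # disjoint 3-residue substitution sets: pairwise identity 0.94
        copies = disjoint_mutants(ancestor, 3, 3, rng)
        records = [make_record(f"m{i}", s, rank=i) for i, s in enumerate(copies)]
        records += [make_record(f"bg{i}", random_protein(100, rng), rank=3 + i)
                    for i in range(4)]
        pairs = candidate_pairs(records, DetectionConfig())
        assert len(pairs) == 3
        assert {p.gene_a for p in pairs} | {p.gene_b for p in pairs} == \
            {"m0", "m1", "m2"}

    def test_family_mode_requires_labels(self):
        records = [make_record("a", "ACDEF"), make_record("b", "ACDEF", rank=1)]
        cfg = DetectionConfig(mode="family", identity_threshold=None)
        with pytest.raises(ValueError, match="family"):
            all_pair_hits(records, cfg)

    def test_duplicate_gene_id_rejected(self):
        records = [make_record("a", "ACDEF"), make_record("a", "ACDEF")]
        with pytest.raises(ValueError, match="duplicate"):
            all_pair_hits(records, DetectionConfig())


class TestBuildGroups:
    def test_single_linkage_transitivity(self):
        records = [make_record(x, "ACDEFGHIKL", rank=i)
                   for i, x in enumerate("abc")]
        pairs = [
            PairwiseHit("a", "b", 0.95, 1, 1, 9, 10, 10, 10, 40.0),
            PairwiseHit("b", "c", 0.92, 1, 1, 9, 10, 10, 10, 40.0),
        ]
        groups = build_groups(pairs, records)
        assert len(groups) == 1
        assert groups[0].members == frozenset("abc")
        assert groups[0].min_identity == 0.92

    def test_no_pairs_no_groups(self):
        assert build_groups([], []) == []

    def test_group_ids_deterministic(self):
        records = [make_record(x, "ACDEFGHIKL", rank=i)
                   for i, x in enumerate("abcd")]
        pairs = [
            PairwiseHit("c", "d", 0.95, 1, 1, 9, 10, 10, 10, 40.0),
            PairwiseHit("a", "b", 0.95, 1, 1, 9, 10, 10, 10, 40.0),
        ]
        groups = build_groups(pairs, records)
        assert [g.group_id for g in groups] == ["g1:SG0001", "g1:SG0002"]
        assert groups[0].members == frozenset("ab")

    def test_planted_partition_recovered(self, standard_fixture, denovo_config):
        _, records, truth = standard_fixture
        groups, _, _ = detect_synologs(records, denovo_config)
        detected = {g.members for g in groups}
        assert detected == set(planted_partition(truth).values())


class TestPrescreen:
    def test_prescreen_is_lossless_on_full_fixtures(self):
        """The 7-mer prescreen must reproduce the exhaustive all-vs-all
        passing-pair set exactly on complete synthetic genomes."""
        for seed in range(3):
            design = small_design(seed)
            records, _ = generate_genome(design)
            full = candidate_pairs(records, DetectionConfig(kmer_prescreen=False))
            pre = candidate_pairs(records, DetectionConfig(kmer_prescreen=True))
            assert [(p.gene_a, p.gene_b) for p in full] == \
                [(p.gene_a, p.gene_b) for p in pre]


class TestModeConcordance:
    def test_family_equals_denovo_on_planted_families(
        self, standard_fixture, denovo_config
    ):
        """With families defined as the planted groups, family mode at the
        0.90 cutoff and de novo mode at 0.90/0.90 find identical groups."""
        _, records, _ = standard_fixture
        denovo_groups, _, _ = detect_synologs(records, denovo_config)
        fam_cfg = DetectionConfig(mode="family", identity_threshold=0.90)
        family_groups, flagged, _ = detect_synologs(records, fam_cfg)
        assert {g.members for g in family_groups} == \
            {g.members for g in denovo_groups}

    def test_family_mode_no_cutoff_keeps_whole_family(self):
        rng = np.random.default_rng(6)
        ancestor = random_protein(100, rng)
        # two near-identical copies plus one diverged relative
        far = disjoint_mutants(ancestor, 1, 60, rng)[0]
        records = [
            make_record("a", ancestor, family="F1"),
            make_record("b", disjoint_mutants(ancestor, 1, 3, rng)[0],
                        family="F1", rank=1),
            make_record("c", far, family="F1", rank=2),
        ]
        no_cut = DetectionConfig(mode="family", identity_threshold=None)
        groups, _, _ = detect_synologs(records, no_cut)
        assert len(groups) == 1 and groups[0].members == frozenset("abc")
        with_cut = DetectionConfig(mode="family", identity_threshold=0.90)
        groups, _, _ = detect_synologs(records, with_cut)
        assert len(groups) == 1 and groups[0].members == frozenset("ab")
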