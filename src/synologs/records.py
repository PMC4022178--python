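"""Core domain types shared across the pipeline.

A :class:`ProteinRecord` is one translated protein-coding gene with its
genomic coordinates and optional family / functional-category labels.  A
:class:`PairwiseHit` is the outcome of aligning one intra-genome pair.  A
:class:`SynologGroup` is a connected set of two or more genes from the same
genome whose pairwise comparisons pass the synolog criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .alphabet import is_valid_sequence

STRANDS = ("+", "-")
MODES = ("denovo", "family")


@dataclass(frozen=True)
class ProteinRecord:
    """One gene: identifier, amino-acid sequence, coordinates, labels."""

    gene_id: str
    genome_id: str
    sequence: str
    contig: str
    start: int
    end: int
    strand: str
    family_id: Optional[str] = None
    category: Optional[str] = None
    subcategory: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not is_valid_sequence(self.sequence):
            raise ValueError(
                f"gene {self.gene_id}: sequence empty or contains residues "
                "outside the 20-letter alphabet plus X"
            )
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: require 1 <= start <= end, "
                f"got start={self.start} end={self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the synolog criterion and of detection bookkeeping.

    identity_threshold / coverage_threshold
        De novo mode declares a pair synologous when identity and both
        per-sequence coverages reach these fractions (defaults 0.90/0.90).
        In family mode ``identity_threshold=None`` disables the identity
        cutoff entirely (same-family membership alone defines synologs);
        a non-None value re-partitions each family by components of pairs
        passing the cutoff.
    truncation_fraction
        Family-mode truncation filter: members shorter than this fraction
        of the family median length are flagged and excluded.
    max_intervening
        Operational tandem definition: maximum number of non-member genes
        allowed between consecutive group members.
    kmer_prescreen
        Optional exact 7-mer prescreen for de novo all-vs-all; lossless at
        identity >= 0.90 with >= 0.90 coverage (see docs), off by default.
    """

    identity_threshold: Optional[float] = 0.90
    coverage_threshold: float = 0.90
    mode: str = "denovo"
    truncation_fraction: float = 0.5
    category_filter: Optional[str] = None
    max_intervening: int = 2
    rng_seed: int = 0
    kmer_prescreen: bool = False
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.identity_threshold is not None and not 0.0 <= self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must lie in [0, 1]")
        if not 0.0 <= self.coverage_threshold <= 1.0:
            raise ValueError("coverage_threshold must lie in [0, 1]")
        if not 0.0 < self.truncation_fraction <= 1.0:
            raise ValueError("truncation_fraction must lie in (0, 1]")
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")
        if self.mode == "denovo" and self.identity_threshold is None:
            raise ValueError("de novo mode requires an identity threshold")


@dataclass(frozen=True)
class PairwiseHit:
    """Alignment-derived quantities for one unordered intra-genome pair.

    ``identity`` uses the mode-appropriate denominator: all alignment
    columns inside a local alignment (blast-style, de novo mode) or
    residue-pair columns of the global alignment (family mode).
    ``coverage_x`` is the fraction of sequence x's full length inside the
    alignment.
    """

    gene_a: str
    gene_b: str
    identity: float
    coverage_a: float
    coverage_b: float
    n_matches: int
    n_columns: int
    aligned_len_a: int
    aligned_len_b: int
    score: float

    def swapped(self) -> "PairwiseHit":
        """The same hit viewed from (b, a); coverages swap."""
        return PairwiseHit(
            gene_a=self.gene_b,
            gene_b=self.gene_a,
            identity=self.identity,
            coverage_a=self.coverage_b,
            coverage_b=self.coverage_a,
            n_matches=self.n_matches,
            n_columns=self.n_columns,
            aligned_len_a=self.aligned_len_b,
            aligned_len_b=self.aligned_len_a,
            score=self.score,
        )


@dataclass(frozen=True)
class SynologGroup:
    """A maximal connected set of >= 2 intra-genome synologs."""

    group_id: str
    genome_id: str
    members: frozenset
    min_identity: float
    mean_identity: float
    n_pairs: int
    family_id: Optional[str] = None
    subcategory: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a synolog group needs at least two members")
        if not (self.min_identity <= self.mean_identity + 1e-12):
            raise ValueError("min_identity must not exceed mean_identity")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def sorted_members(self) -> list:
        return sorted(self.members)


@dataclass
class GenomeSynologSummary:
    """Per-genome counts: N genes in scope, S synologs, G groups, F = 100·S/N."""

    genome_id: str
    n_genes: int
    n_synologs: int
    n_groups: int
    synolog_fraction: float
    mean_pair_identity: float  # percent; NaN when the genome has no groups
    subcategory_group_counts: dict = field(default_factory=dict)
    n_groups_at_cutoff: Optional[int] = None
    n_proteins_total: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1 (synolog fraction undefined at 0)")
        if not 0 <= self.n_synologs <= self.n_genes:
            raise ValueError("require 0 <= n_synologs <= n_genes")
        if self.n_groups > 0 and self.n_groups > self.n_synologs // 2:
            raise ValueError("each group has >= 2 members, so G <= S/2")
        if (self.n_groups == 0) != (self.synolog_fraction == 0.0):
            raise ValueError("synolog_fraction is zero exactly when there are no groups")


@dataclass(frozen=True)
class MetricSummary:
    """Cohort location/spread for one per-genome metric."""

    median: float
    mad: float
    min: float
    max: float
    outlier_threshold: float  # median + 2*MAD


@dataclass
class CohortSummary:
    """Across-genome statistics: medians, MADs, outlier cutoffs, R² couplings."""

    n_genomes: int
    metrics: dict  # metric name -> MetricSummary
    r2_pairs: dict  # "x_vs_y" -> R² of the simple linear regression
    genome_ranks: dict  # genome_id -> {"by_groups": pct, "by_fraction": pct}
    zero_synolog_share: float  # percent of genomes with G = 0
    high_identity_share: Optional[float]  # percent with >= 1 group at the cutoff


@dataclass(frozen=True)
class ContextCall:
    """Genomic-arrangement classification of one synolog group."""

    group_id: str
    arrangement: str  # tandem | dispersed | mixed
    contig_count: int
    neighbor_profile: dict
    window: int

    def __post_init__(self) -> None:
        if self.arrangement not in ("tandem", "dispersed", "mixed"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.arrangement == "tandem" and self.contig_count != 1:
            raise ValueError("a tandem group occupies exactly one contig")


def is_nan(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)
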