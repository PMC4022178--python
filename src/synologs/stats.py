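"""Per-genome and cohort synolog statistics.

Per genome: N genes in scope, S genes belonging to synolog groups, G groups,
the synolog fraction F = 100·S/N, the mean pairwise identity over within-group
pairs, and a per-subcategory group breakdown.  Across genomes: median, MAD
(median absolute deviation, unscaled), min/max, the median + 2·MAD outlier
threshold, squared-correlation couplings such as R²(S, G), percentile ranks,
and the shares of genomes with no synologs or with at least one
high-identity group.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .records import (
    CohortSummary,
    GenomeSynologSummary,
    MetricSummary,
    ProteinRecord,
    SynologGroup,
)


def median_mad(values: Sequence[float]) -> Tuple[float, float]:
    """Sample median and unscaled median absolute deviation.

    The MAD carries no 1.4826 normal-consistency factor: it is literally the
    median of absolute deviations from the median.
    """
    if len(values) == 0:
        raise ValueError("median_mad requires a non-empty list")
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    return med, float(np.median(np.abs(arr - med)))


def outlier_threshold(median: float, mad: float) -> float:
    """Upper outlier cutoff: median + 2·MAD."""
    if mad < 0:
        raise ValueError("MAD cannot be negative")
    return median + 2.0 * mad


def linear_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """R² of the simple linear regression of y on x (squared Pearson r)."""
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("linear_r2 requires two equal-length lists of >= 3 values")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("regression undefined for a constant variable")
    r = sps.pearsonr(xa, ya).statistic
    return float(r * r)


def subcategory_breakdown(groups: Sequence[SynologGroup]) -> Dict[str, int]:
    """Group counts per subcategory; groups without a label count as 'none'.

    Each group carries a single subcategory (majority label of its members,
    lexicographic tie-break, assigned at group construction), so the counts
    sum to the number of groups.
    """
    counts: Dict[str, int] = defaultdict(int)
    for g in groups:
        counts[g.subcategory or "none"] += 1
    return dict(sorted(counts.items()))


def summarize_genome(
    groups: Sequence[SynologGroup],
    records_in_scope: Sequence[ProteinRecord],
    n_groups_at_cutoff: Optional[int] = None,
    n_proteins_total: Optional[int] = None,
) -> GenomeSynologSummary:
    """Fold one genome's groups into counts and the synolog fraction.

    S counts each gene once even if it appears under several subcategories
    (deduplicated by gene id); the synolog fraction is kept at full
    precision here and rounded to one decimal only at report time.
    """
    gene_ids = {r.gene_id for r in records_in_scope}
    n_genes = len(gene_ids)
    if n_genes == 0:
        raise ValueError("synolog fraction undefined for an empty gene set")
    genome_id = records_in_scope[0].genome_id
    members = set()
    for g in groups:
        members |= g.members
    n_synologs = len(members)
    n_pairs = sum(g.n_pairs for g in groups)
    mean_identity = (
        100.0 * sum(g.mean_identity * g.n_pairs for g in groups) / n_pairs
        if n_pairs
        else math.nan
    )
    return GenomeSynologSummary(
        genome_id=genome_id,
        n_genes=n_genes,
        n_synologs=n_synologs,
        n_groups=len(groups),
        synolog_fraction=100.0 * n_synologs / n_genes,
        mean_pair_identity=mean_identity,
        subcategory_group_counts=subcategory_breakdown(groups),
        n_groups_at_cutoff=n_groups_at_cutoff,
        n_proteins_total=n_proteins_total,
    )


_METRICS = (
    ("n_synologs", lambda s: s.n_synologs),
    ("n_groups", lambda s: s.n_groups),
    ("synolog_fraction", lambda s: s.synolog_fraction),
    ("mean_pair_identity", lambda s: s.mean_pair_identity),
)


def _metric_summary(values: Sequence[float]) -> MetricSummary:
    med, mad = median_mad(values)
    return MetricSummary(
        median=med,
        mad=mad,
        min=float(np.min(values)),
        max=float(np.max(values)),
        outlier_threshold=outlier_threshold(med, mad),
    )


def _percentile_ranks(values: Mapping[str, float]) -> Dict[str, float]:
    arr = np.asarray(list(values.values()), dtype=float)
    return {
        gid: round(float(sps.percentileofscore(arr, v, kind="weak")), 1)
        for gid, v in values.items()
    }


def cohort_summarize(
    summaries: Sequence[GenomeSynologSummary],
    share_decimals: int = 1,
) -> CohortSummary:
    """Aggregate per-genome summaries into cohort statistics.

    Mean pairwise identity is summarised over the genomes that contain
    groups (it is undefined elsewhere).  R² couplings are reported for
    S vs G, G vs N, and G vs total protein count when every summary carries
    one; a coupling whose x happens to be constant is omitted rather than
    reported.  ``share_decimals`` controls the rounding of the share
    percentages (1 decimal by default; 0 gives nearest-integer reporting).
    """
    if not summaries:
        raise ValueError("cohort_summarize requires at least one genome summary")
    metrics: Dict[str, MetricSummary] = {}
    for name, get in _METRICS:
        vals = [get(s) for s in summaries]
        vals = [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
        if vals:
            metrics[name] = _metric_summary(vals)

    S = [s.n_synologs for s in summaries]
    G = [s.n_groups for s in summaries]
    N = [s.n_genes for s in summaries]
    r2_pairs: Dict[str, float] = {}
    candidates: List[Tuple[str, List[float], List[float]]] = [
        ("n_synologs_vs_n_groups", S, G),
        ("n_groups_vs_n_genes", G, N),
    ]
    if all(s.n_proteins_total is not None for s in summaries):
        candidates.append(
            ("n_groups_vs_n_proteins", G, [s.n_proteins_total for s in summaries])
        )
    for name, x, y in candidates:
        try:
            r2_pairs[name] = linear_r2(x, y)
        except ValueError:
            pass

    by_groups = {s.genome_id: float(s.n_groups) for s in summaries}
    by_fraction = {s.genome_id: s.synolog_fraction for s in summaries}
    rank_g = _percentile_ranks(by_groups)
    rank_f = _percentile_ranks(by_fraction)
    genome_ranks = {
        gid: {"by_groups": rank_g[gid], "by_fraction": rank_f[gid]}
        for gid in by_groups
    }

    n = len(summaries)
    zero = sum(1 for s in summaries if s.n_groups == 0)
    zero_share = round(100.0 * zero / n, share_decimals)
    high: Optional[float] = None
    if all(s.n_groups_at_cutoff is not None for s in summaries):
        k = sum(1 for s in summaries if s.n_groups_at_cutoff >= 1)
        high = round(100.0 * k / n, share_decimals)
    if share_decimals == 0:
        zero_share = float(int(zero_share))
        high = float(int(high)) if high is not None else None

    return CohortSummary(
        n_genomes=n,
        metrics=metrics,
        r2_pairs=r2_pairs,
        genome_ranks=genome_ranks,
        zero_synolog_share=zero_share,
        high_identity_share=high,
    )


def histogram_table(
    values: Sequence[float], bin_edges: Sequence[float]
) -> List[Tuple[float, float, int]]:
    """(left, right, count) rows for a distribution report; right-open bins,
    final bin closed."""
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bin_edges)
    return [
        (float(edges[i]), float(edges[i + 1]), int(counts[i]))
        for i in range(len(counts))
    ]
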