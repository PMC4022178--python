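"""Genomic-context classification of synolog groups.

Duplicated genes can sit side by side (a recent tandem duplication) or be
scattered across the chromosome, where their neighbours hint at the
functional context each copy operates in.  Distances are measured in gene
ranks (positions in the start-sorted gene order of a contig), not base
pairs, which makes the classification robust to intergenic-length variation.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Mapping, Sequence, Tuple

from .records import ContextCall, ProteinRecord, SynologGroup

Arrangement = str


def _rank_index(
    annotations: Sequence[ProteinRecord],
) -> Tuple[Dict[str, List[ProteinRecord]], Dict[str, Tuple[str, int]]]:
    """Genes per contig in start order, plus gene_id -> (contig, rank)."""
    per_contig: Dict[str, List[ProteinRecord]] = defaultdict(list)
    for r in annotations:
        per_contig[r.contig].append(r)
    ranks: Dict[str, Tuple[str, int]] = {}
    for contig, genes in per_contig.items():
        genes.sort(key=lambda r: (r.start, r.gene_id))
        for i, g in enumerate(genes):
            ranks[g.gene_id] = (contig, i)
    return per_contig, ranks


def classify_arrangement(
    group: SynologGroup,
    annotations: Sequence[ProteinRecord],
    max_intervening: int = 2,
) -> Arrangement:
    """Tandem, dispersed or mixed placement of one group's members.

    Tandem: all members on one contig with at most ``max_intervening``
    non-member genes between consecutive members.  Dispersed: members on
    more than one contig, or no two members within ``max_intervening`` of
    each other.  Anything else is mixed.
    """
    _, ranks = _rank_index(annotations)
    placed = []
    for gid in group.sorted_members:
        if gid not in ranks:
            raise ValueError(f"group member {gid!r} has no annotation row")
        placed.append(ranks[gid])
    contigs = {c for c, _ in placed}
    if len(contigs) > 1:
        return "dispersed"
    member_ranks = sorted(r for _, r in placed)
    gaps = [
        member_ranks[i + 1] - member_ranks[i] - 1
        for i in range(len(member_ranks) - 1)
    ]
    if all(g <= max_intervening for g in gaps):
        return "tandem"
    if all(g > max_intervening for g in gaps):
        return "dispersed"
    return "mixed"


def neighbor_category_profile(
    group: SynologGroup,
    annotations: Sequence[ProteinRecord],
    window: int = 5,
) -> Dict[str, int]:
    """Tally the functional categories of genes flanking the group members.

    For each member, up to ``window`` genes on each side of it on the same
    contig are examined; other members of the group are skipped, and genes
    without a category label are tallied under ``"unknown"``.  A gene
    flanking two members is counted once per member it flanks.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    per_contig, ranks = _rank_index(annotations)
    members = group.members
    profile: Dict[str, int] = defaultdict(int)
    for gid in group.sorted_members:
        contig, rank = ranks[gid]
        genes = per_contig[contig]
        lo = max(0, rank - window)
        hi = min(len(genes), rank + window + 1)
        for other in genes[lo:hi]:
            if other.gene_id == gid or other.gene_id in members:
                continue
            profile[other.category or "unknown"] += 1
    return dict(sorted(profile.items()))


def call_context(
    group: SynologGroup,
    annotations: Sequence[ProteinRecord],
    max_intervening: int = 2,
    window: int = 5,
) -> ContextCall:
    """Arrangement plus neighbour profile for one group."""
    _, ranks = _rank_index(annotations)
    contigs = {ranks[g][0] for g in group.members if g in ranks}
    return ContextCall(
        group_id=group.group_id,
        arrangement=classify_arrangement(group, annotations, max_intervening),
        contig_count=len(contigs),
        neighbor_profile=neighbor_category_profile(group, annotations, window),
        window=window,
    )


def call_contexts(
    groups: Sequence[SynologGroup],
    annotations: Sequence[ProteinRecord],
    max_intervening: int = 2,
    window: int = 5,
) -> List[ContextCall]:
    return [
        call_context(g, annotations, max_intervening, window)
        for g in sorted(groups, key=lambda g: g.group_id)
    ]
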