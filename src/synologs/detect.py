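"""Genome-wide synolog detection.

The de novo route aligns every unordered intra-genome pair locally and keeps
pairs with >= 90% identity over >= 90% of both full lengths (defaults).  The
family route pairs genes sharing a family label, aligns them globally for
identity bookkeeping, and optionally re-partitions families by an identity
cutoff.  Groups are connected components (single linkage) of passing pairs.

An optional exact 7-mer prescreen can skip de novo pairs that share no
7-residue word.  At the default 0.90/0.90 thresholds it is lossless: a pair
passing the criterion has a local alignment with C >= 27 columns of which at
most floor(C/10) are non-matches, and those split the matched columns into
runs whose longest is always >= 7 (the minimum, 7, occurs at C = 30).  Pairs
where either sequence is shorter than 30 residues bypass the prescreen.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .align import _matrix, align_pair, synolog_criterion
from .records import DetectionConfig, PairwiseHit, ProteinRecord, SynologGroup

PRESCREEN_K = 7
_PRESCREEN_MIN_LEN = 30


def apply_category_filter(
    records: Sequence[ProteinRecord], config: DetectionConfig
) -> List[ProteinRecord]:
    """Restrict to the configured functional category (no-op when unset)."""
    if config.category_filter is None:
        return list(records)
    return [r for r in records if r.category == config.category_filter]


def filter_truncated(
    records: Sequence[ProteinRecord], config: DetectionConfig
) -> Tuple[List[ProteinRecord], List[str]]:
    """Flag severely truncated members within each family (family mode).

    Within every family of >= 2 members, sequences shorter than
    ``truncation_fraction`` times the family's median length are flagged and
    excluded from pairing and counting.  De novo detection needs no such
    filter: its coverage rule already rejects full-vs-fragment pairs.
    """
    if config.mode != "family":
        return list(records), []
    by_family: Dict[str, List[ProteinRecord]] = defaultdict(list)
    for r in records:
        if r.family_id:
            by_family[r.family_id].append(r)
    flagged: Set[str] = set()
    for members in by_family.values():
        if len(members) < 2:
            continue
        cutoff = config.truncation_fraction * statistics.median(
            m.length for m in members
        )
        for m in members:
            if m.length < cutoff:
                flagged.add(m.gene_id)
    kept = [r for r in records if r.gene_id not in flagged]
    return kept, sorted(flagged)


def _kmers(seq: str, k: int) -> Set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _prescreen_pairs(records: Sequence[ProteinRecord]) -> Set[Tuple[int, int]]:
    """Index pairs sharing an exact 7-mer; short sequences always pass."""
    index: Dict[str, List[int]] = defaultdict(list)
    short = [i for i, r in enumerate(records) if r.length < _PRESCREEN_MIN_LEN]
    for i, r in enumerate(records):
        for w in _kmers(r.sequence, PRESCREEN_K):
            index[w].append(i)
    pairs: Set[Tuple[int, int]] = set()
    for hits in index.values():
        if len(hits) > 1:
            pairs.update(combinations(hits, 2))
    for i in short:
        for j in range(len(records)):
            if j != i:
                pairs.add((min(i, j), max(i, j)))
    return pairs


def _validate_records(records: Sequence[ProteinRecord]) -> None:
    genomes = {r.genome_id for r in records}
    if len(genomes) > 1:
        raise ValueError(f"records span several genomes: {sorted(genomes)}")
    seen: Set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene_id {r.gene_id!r}")
        seen.add(r.gene_id)


def all_pair_hits(
    records: Sequence[ProteinRecord], config: DetectionConfig
) -> List[PairwiseHit]:
    """Align every pair the mode calls for and return all hits, pass or fail.

    De novo mode evaluates all unordered pairs (optionally prescreened);
    family mode evaluates only same-family pairs and raises when no record
    carries a family label.  Hits are sorted by (gene_a, gene_b).
    """
    _validate_records(records)
    _matrix(config.matrix_name)  # warm the substitution-matrix cache
    hits: List[PairwiseHit] = []
    order = sorted(range(len(records)), key=lambda i: records[i].gene_id)
    if config.mode == "family":
        if not any(r.family_id for r in records):
            raise ValueError("family mode requires family_id labels on records")
        by_family: Dict[str, List[int]] = defaultdict(list)
        for i in order:
            if records[i].family_id:
                by_family[records[i].family_id].append(i)
        index_pairs = [
            (i, j)
            for members in by_family.values()
            for i, j in combinations(members, 2)
        ]
    elif config.kmer_prescreen:
        allowed = _prescreen_pairs(records)
        index_pairs = [
            (i, j) for i, j in combinations(order, 2)
            if (min(i, j), max(i, j)) in allowed
        ]
    else:
        index_pairs = list(combinations(order, 2))
    for i, j in index_pairs:
        a, b = records[i], records[j]
        hits.append(
            align_pair(a.sequence, b.sequence, config,
                       gene_a=a.gene_id, gene_b=b.gene_id)
        )
    hits.sort(key=lambda h: (h.gene_a, h.gene_b))
    return hits


def candidate_pairs(
    records: Sequence[ProteinRecord],
    config: DetectionConfig,
    hits: Optional[Sequence[PairwiseHit]] = None,
) -> List[PairwiseHit]:
    """Hits passing the synolog criterion, sorted by (gene_a, gene_b).

    Pass precomputed ``hits`` (from :func:`all_pair_hits`) to re-filter at a
    different threshold without re-aligning.
    """
    if hits is None:
        hits = all_pair_hits(records, config)
    fam = {r.gene_id: r.family_id for r in records}
    return [
        h for h in hits
        if synolog_criterion(h, config, fam[h.gene_a], fam[h.gene_b])
    ]


def build_groups(
    pairs: Sequence[PairwiseHit],
    records: Sequence[ProteinRecord],
    all_hits: Optional[Sequence[PairwiseHit]] = None,
) -> List[SynologGroup]:
    """Connected components of passing pairs, as deterministic groups.

    Group ids are ``<genome>:SG<ordinal>`` with ordinals assigned by the
    lexicographically smallest member gene id.  Min and mean identity are
    taken over all evaluated within-group pairs (``all_hits`` when given,
    falling back to the passing pairs), and each group inherits the family
    and subcategory labels of its members via majority with lexicographic
    tie-break.
    """
    if not pairs:
        return []
    by_id = {r.gene_id: r for r in records}
    genome_id = next(iter(by_id.values())).genome_id
    graph = nx.Graph()
    graph.add_edges_from((p.gene_a, p.gene_b) for p in pairs)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    pool = all_hits if all_hits is not None else pairs
    groups: List[SynologGroup] = []
    for ordinal, members in enumerate(components, start=1):
        mset = set(members)
        idents = [
            h.identity for h in pool if h.gene_a in mset and h.gene_b in mset
        ]
        groups.append(
            SynologGroup(
                group_id=f"{genome_id}:SG{ordinal:04d}",
                genome_id=genome_id,
                members=frozenset(members),
                min_identity=min(idents),
                mean_identity=sum(idents) / len(idents),
                n_pairs=len(idents),
                family_id=_majority(by_id, members, "family_id"),
                subcategory=_majority(by_id, members, "subcategory"),
            )
        )
    return groups


def _majority(by_id, members: Iterable[str], attr: str) -> Optional[str]:
    labels = [getattr(by_id[m], attr) for m in members]
    labels = [l for l in labels if l]
    if not labels:
        return None
    counts: Dict[str, int] = defaultdict(int)
    for l in labels:
        counts[l] += 1
    top = max(counts.values())
    return sorted(l for l, c in counts.items() if c == top)[0]


def detect_synologs(
    records: Sequence[ProteinRecord], config: DetectionConfig
) -> Tuple[List[SynologGroup], List[str], List[PairwiseHit]]:
    """Full per-genome detection: filter, align, group.

    Returns (groups, truncated gene ids, all evaluated hits).
    """
    in_scope = apply_category_filter(records, config)
    kept, flagged = filter_truncated(in_scope, config)
    hits = all_pair_hits(kept, config)
    passing = candidate_pairs(kept, config, hits=hits)
    groups = build_groups(passing, kept, all_hits=hits)
    return groups, flagged, hits
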