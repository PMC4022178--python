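"""Synthetic proteomes with planted synolog groups and known ground truth.

A synthetic genome emulates the statistical structure of a real prokaryotic
gene set: a majority of mutually unrelated background genes (i.i.d. uniform
amino-acid composition, so spurious 90%-identity collisions are vanishingly
rare at lengths >= 50) plus a minority of planted duplicate groups.  Each
planted group is a star: one ancestor and ``size`` copies independently
mutated to a per-copy identity ``t``, which bounds every pairwise copy
identity below by 2t - 1 (union bound on mutated positions) — choosing
t = 0.97 guarantees pairwise identity >= 0.94, comfortably above a 0.90
detection cutoff.  Optional severely truncated decoys keep only the leading
fraction of the ancestor.  Gene coordinates are synthesised so that tandem
groups occupy consecutive gene ranks while dispersed groups sit >= 20 ranks
apart, with fixed gene length 3L + 3 and 100-bp spacers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alphabet import CANONICAL
from .records import ProteinRecord

_AA = np.frombuffer(CANONICAL.encode(), dtype=np.uint8)

#: eleven SEED-style carbohydrate-metabolism subcategories used by the
#: standard fixture (cycled over the planted groups).
SUBCATEGORIES = (
    "Central carbohydrate metabolism",
    "Monosaccharides",
    "Di- and oligosaccharides",
    "Amino sugars",
    "Sugar alcohols",
    "Fermentation",
    "Organic acids",
    "Glycoside hydrolases",
    "Polysaccharides",
    "CO2 fixation",
    "One-carbon metabolism",
)


@dataclass(frozen=True)
class PlantedGroup:
    """Specification of one planted synolog group."""

    size: int
    target_identity: float = 0.97
    subcategory: str = SUBCATEGORIES[0]
    arrangement: str = "dispersed"  # tandem | dispersed
    truncated_copies: int = 0
    truncated_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("a planted group needs size >= 2")
        if not 0.0 <= self.target_identity <= 1.0:
            raise ValueError("target_identity must lie in [0, 1]")
        if self.arrangement not in ("tandem", "dispersed"):
            raise ValueError("arrangement must be tandem or dispersed")
        if self.truncated_copies < 0 or not 0.0 < self.truncated_fraction <= 1.0:
            raise ValueError("invalid truncated-copy specification")


@dataclass(frozen=True)
class SyntheticDesign:
    """Complete recipe for one synthetic genome."""

    n_background: int = 300
    length_range: Tuple[int, int] = (60, 180)
    planted_groups: Tuple[PlantedGroup, ...] = ()
    n_contigs: int = 1
    rng_seed: int = 0
    genome_id: str = "synthetic"
    planted_category: str = "Carbohydrates"
    background_category: str = "other"
    min_dispersed_gap: int = 20

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (30 <= lo <= hi):
            raise ValueError("length_range minimum must be >= 30 residues")
        if self.n_background < 0 or self.n_contigs < 1:
            raise ValueError("invalid design sizes")

    @property
    def n_genes(self) -> int:
        return self.n_background + sum(
            g.size + g.truncated_copies for g in self.planted_groups
        )


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one emitted gene."""

    group: Optional[str]  # planted family label, None for background
    is_truncated: bool
    subcategory: Optional[str]
    contig: str
    rank: int  # gene rank within its contig, 0-based


TruthTable = Dict[str, TruthEntry]


def random_protein(length: int, rng: np.random.Generator) -> str:
    """An i.i.d. uniform draw over the 20 canonical residues."""
    if length < 1:
        raise ValueError("protein length must be >= 1")
    return bytes(rng.choice(_AA, size=length)).decode()


def mutate_to_identity(
    seq: str, target_identity: float, rng: np.random.Generator
) -> str:
    """Substitute exactly round((1 - t)·L) distinct positions of ``seq``.

    Each chosen position is replaced by a uniformly drawn *different*
    residue, so the ungapped identity of the copy to its parent is exactly
    (L - m)/L.  No indels are introduced.
    """
    if not 0.0 <= target_identity <= 1.0:
        raise ValueError("target_identity must lie in [0, 1]")
    L = len(seq)
    m = int(np.floor((1.0 - target_identity) * L + 0.5))
    if m == 0:
        return seq
    positions = rng.choice(L, size=m, replace=False)
    out = bytearray(seq.encode())
    for p in positions:
        current = out[p]
        choices = _AA[_AA != current]
        out[p] = int(rng.choice(choices))
    return out.decode()


def standard_design(rng_seed: int = 0) -> SyntheticDesign:
    """The standard fixture: 300 background genes, 12 planted groups of
    sizes 2-4 at copy identity 0.97, and 3 truncated decoys, alternating
    tandem and dispersed placements over the eleven subcategories."""
    sizes = [2, 2, 2, 2, 3, 3, 3, 3, 4, 4, 4, 4]
    groups = []
    for i, size in enumerate(sizes):
        groups.append(
            PlantedGroup(
                size=size,
                target_identity=0.97,
                subcategory=SUBCATEGORIES[i % len(SUBCATEGORIES)],
                arrangement="tandem" if i % 2 == 0 else "dispersed",
                truncated_copies=1 if i < 3 else 0,
                truncated_fraction=0.3,
            )
        )
    return SyntheticDesign(
        n_background=300,
        length_range=(60, 180),
        planted_groups=tuple(groups),
        n_contigs=1,
        rng_seed=rng_seed,
    )


def _contig_of(rank: int, bounds: Sequence[int]) -> int:
    for c, b in enumerate(bounds):
        if rank < b:
            return c
    raise AssertionError("rank outside contig bounds")


def generate_genome(
    design: SyntheticDesign,
) -> Tuple[List[ProteinRecord], TruthTable]:
    """Emit the proteome and its truth table, deterministically per seed."""
    rng = np.random.default_rng(design.rng_seed)
    T = design.n_genes
    if T < 1:
        raise ValueError("design emits no genes")
    sizes = np.full(design.n_contigs, T // design.n_contigs, dtype=int)
    sizes[: T % design.n_contigs] += 1
    bounds = list(np.cumsum(sizes))

    lo, hi = design.length_range
    slots: List[Optional[dict]] = [None] * T

    def free(r: int) -> bool:
        return slots[r] is None

    for gi, grp in enumerate(design.planted_groups):
        label = f"FAM{gi + 1:03d}"
        L = int(rng.integers(lo, hi + 1))
        ancestor = random_protein(L, rng)
        copies = [
            mutate_to_identity(ancestor, grp.target_identity, rng)
            for _ in range(grp.size)
        ]
        frag_len = max(1, int(np.floor(grp.truncated_fraction * L + 0.5)))
        fragments = [ancestor[:frag_len] for _ in range(grp.truncated_copies)]

        member_ranks: List[int] = []
        if grp.arrangement == "tandem":
            starts = [
                s
                for s in range(T - grp.size + 1)
                if all(free(s + k) for k in range(grp.size))
                and _contig_of(s, bounds) == _contig_of(s + grp.size - 1, bounds)
            ]
            if not starts:
                raise ValueError(
                    f"design infeasible: no room for tandem group {label}"
                )
            start = int(rng.choice(starts))
            member_ranks = list(range(start, start + grp.size))
        else:
            for _ in range(grp.size):
                candidates = [
                    r
                    for r in range(T)
                    if free(r)
                    and all(
                        abs(r - q) >= design.min_dispersed_gap
                        or _contig_of(r, bounds) != _contig_of(q, bounds)
                        for q in member_ranks
                    )
                ]
                if not candidates:
                    raise ValueError(
                        f"design infeasible: cannot disperse group {label}"
                    )
                member_ranks.append(int(rng.choice(candidates)))
        for rank, seq in zip(member_ranks, copies):
            slots[rank] = {"seq": seq, "group": label, "trunc": False,
                           "sub": grp.subcategory}
        for seq in fragments:
            candidates = [
                r
                for r in range(T)
                if free(r)
                and all(
                    abs(r - q) >= design.min_dispersed_gap
                    or _contig_of(r, bounds) != _contig_of(q, bounds)
                    for q in member_ranks
                )
            ]
            if not candidates:
                raise ValueError(
                    f"design infeasible: cannot place decoy of group {label}"
                )
            r = int(rng.choice(candidates))
            slots[r] = {"seq": seq, "group": label, "trunc": True,
                        "sub": grp.subcategory}

    for r in range(T):
        if free(r):
            L = int(rng.integers(lo, hi + 1))
            slots[r] = {"seq": random_protein(L, rng), "group": None,
                        "trunc": False, "sub": None}

    strands = rng.choice(np.array(["+", "-"]), size=T)

    records: List[ProteinRecord] = []
    truth: TruthTable = {}
    next_start = {c: 1 for c in range(design.n_contigs)}
    local_rank = {c: 0 for c in range(design.n_contigs)}
    for r in range(T):
        c = _contig_of(r, bounds)
        contig = f"contig{c + 1}"
        info = slots[r]
        L = len(info["seq"])
        start = next_start[c]
        end = start + 3 * L + 2
        next_start[c] = end + 101
        gene_id = f"{design.genome_id}_g{r + 1:05d}"
        planted = info["group"] is not None
        records.append(
            ProteinRecord(
                gene_id=gene_id,
                genome_id=design.genome_id,
                sequence=info["seq"],
                contig=contig,
                start=start,
                end=end,
                strand=str(strands[r]),
                family_id=info["group"],
                category=design.planted_category if planted
                else design.background_category,
                subcategory=info["sub"],
            )
        )
        truth[gene_id] = TruthEntry(
            group=info["group"],
            is_truncated=info["trunc"],
            subcategory=info["sub"],
            contig=contig,
            rank=local_rank[c],
        )
        local_rank[c] += 1
    return records, truth


def planted_partition(truth: TruthTable) -> Dict[str, frozenset]:
    """Ground-truth partition: group label -> full-length member gene ids."""
    part: Dict[str, set] = {}
    for gid, entry in truth.items():
        if entry.group is not None and not entry.is_truncated:
            part.setdefault(entry.group, set()).add(gid)
    return {k: frozenset(v) for k, v in part.items()}


def design_to_json(design: SyntheticDesign) -> str:
    d = dataclasses.asdict(design)
    d["planted_groups"] = [dataclasses.asdict(g) for g in design.planted_groups]
    return json.dumps(d, indent=2)


def design_from_json(text: str) -> SyntheticDesign:
    d = json.loads(text)
    groups = tuple(PlantedGroup(**g) for g in d.pop("planted_groups", []))
    d["length_range"] = tuple(d.get("length_range", (60, 180)))
    return SyntheticDesign(planted_groups=groups, **d)
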