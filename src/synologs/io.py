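"""Reading and writing the pipeline's external representations.

Proteomes travel as protein FASTA plus a tab-separated annotation table with
the fixed header ``gene_id genome_id contig start end strand family_id
category subcategory`` (empty string means absent).  Groups and per-genome
summaries are TSV, the cohort summary is JSON, and every run can echo its
resolved configuration to a plain-text log.  Coordinates may alternatively
come from a GFF3 file (CDS features; the ID attribute is the gene id).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO

from .records import (
    CohortSummary,
    GenomeSynologSummary,
    MetricSummary,
    ProteinRecord,
    SynologGroup,
)
from .simulate import TruthEntry, TruthTable

Source = Union[str, Path, TextIO]

ANNOTATION_COLUMNS = [
    "gene_id", "genome_id", "contig", "start", "end", "strand",
    "family_id", "category", "subcategory",
]

GROUP_COLUMNS = [
    "genome_id", "group_id", "gene_id", "family_id", "subcategory",
    "group_size", "n_pairs", "min_identity", "mean_identity",
]


def _read_table(source: Source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)


def read_annotations(source: Source) -> pd.DataFrame:
    table = _read_table(source)
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    return table


def read_gff3_coordinates(source: Source) -> pd.DataFrame:
    """Coordinates of CDS features from a GFF3 file.

    Only the columns this pipeline needs are extracted (contig, 1-based
    inclusive start/end, strand, and the ID attribute as gene_id); all other
    GFF3 semantics are ignored.
    """
    rows = []
    path = Path(source) if isinstance(source, (str, Path)) else None
    handle = open(path) if path is not None else source
    try:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise ValueError(f"CDS feature without ID attribute: {line!r}")
            rows.append(
                {
                    "gene_id": attrs["ID"],
                    "contig": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                }
            )
    finally:
        if path is not None:
            handle.close()
    return pd.DataFrame(rows)


def _clean_sequence(gene_id: str, seq: str) -> str:
    seq = seq.strip().upper().rstrip("*")
    if "*" in seq:
        raise ValueError(f"gene {gene_id}: internal stop character")
    return seq


def read_proteome(
    fasta_source: Source, annotation_source: Source
) -> List[ProteinRecord]:
    """Join a protein FASTA with its annotation table, FASTA order preserved.

    The first whitespace-delimited token of each FASTA header is the gene
    id.  A FASTA entry without an annotation row, a duplicated gene id, or
    a residue outside the accepted alphabet is a hard error.
    """
    table = read_annotations(annotation_source)
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in annotation table")
    rows = table.set_index("gene_id")
    records: List[ProteinRecord] = []
    seen = set()
    for entry in SeqIO.parse(fasta_source, "fasta"):
        gene_id = entry.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in FASTA")
        seen.add(gene_id)
        if gene_id not in rows.index:
            raise ValueError(f"no annotation row for FASTA entry {gene_id!r}")
        row = rows.loc[gene_id]
        records.append(
            ProteinRecord(
                gene_id=gene_id,
                genome_id=row["genome_id"],
                sequence=_clean_sequence(gene_id, str(entry.seq)),
                contig=row["contig"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                family_id=row["family_id"] or None,
                category=row["category"] or None,
                subcategory=row["subcategory"] or None,
            )
        )
    return records


def write_proteome(
    records: Sequence[ProteinRecord],
    fasta_sink: Source,
    annotation_sink: Source,
    wrap: int = 60,
) -> None:
    """Emit FASTA plus the matching annotation table."""
    own = isinstance(fasta_sink, (str, Path))
    handle = open(fasta_sink, "w") if own else fasta_sink
    try:
        for r in records:
            handle.write(f">{r.gene_id}\n")
            for i in range(0, len(r.sequence), wrap):
                handle.write(r.sequence[i : i + wrap] + "\n")
    finally:
        if own:
            handle.close()
    annotations_frame(records).to_csv(annotation_sink, sep="\t", index=False)


def annotations_frame(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "genome_id": r.genome_id,
                "contig": r.contig,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "family_id": r.family_id or "",
                "category": r.category or "",
                "subcategory": r.subcategory or "",
            }
            for r in records
        ],
        columns=ANNOTATION_COLUMNS,
    )


def groups_frame(groups: Sequence[SynologGroup]) -> pd.DataFrame:
    rows = []
    for g in sorted(groups, key=lambda g: g.group_id):
        for gene_id in g.sorted_members:
            rows.append(
                {
                    "genome_id": g.genome_id,
                    "group_id": g.group_id,
                    "gene_id": gene_id,
                    "family_id": g.family_id or "",
                    "subcategory": g.subcategory or "",
                    "group_size": g.size,
                    "n_pairs": g.n_pairs,
                    "min_identity": g.min_identity,
                    "mean_identity": g.mean_identity,
                }
            )
    return pd.DataFrame(rows, columns=GROUP_COLUMNS)


def write_groups(groups: Sequence[SynologGroup], sink: Source) -> None:
    """One row per (group, member), ordered by group id then gene id."""
    groups_frame(groups).to_csv(sink, sep="\t", index=False)


def read_groups(source: Source) -> List[SynologGroup]:
    table = _read_table(source)
    groups: List[SynologGroup] = []
    for group_id, chunk in table.groupby("group_id", sort=True):
        first = chunk.iloc[0]
        groups.append(
            SynologGroup(
                group_id=str(group_id),
                genome_id=first["genome_id"],
                members=frozenset(chunk["gene_id"]),
                min_identity=float(first["min_identity"]),
                mean_identity=float(first["mean_identity"]),
                n_pairs=int(first["n_pairs"]),
                family_id=first["family_id"] or None,
                subcategory=first["subcategory"] or None,
            )
        )
    return groups


def summaries_frame(
    summaries: Sequence[GenomeSynologSummary],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": s.genome_id,
                "n_genes": s.n_genes,
                "n_synologs": s.n_synologs,
                "n_groups": s.n_groups,
                "synolog_fraction": repr(s.synolog_fraction),
                "mean_pair_identity": repr(s.mean_pair_identity),
                "n_groups_at_cutoff": "" if s.n_groups_at_cutoff is None
                else s.n_groups_at_cutoff,
                "n_proteins_total": "" if s.n_proteins_total is None
                else s.n_proteins_total,
                "subcategory_group_counts": json.dumps(
                    s.subcategory_group_counts, sort_keys=True
                ),
            }
            for s in summaries
        ]
    )


def write_summaries(
    summaries: Sequence[GenomeSynologSummary], sink: Source
) -> None:
    summaries_frame(summaries).to_csv(sink, sep="\t", index=False)


def read_summaries(source: Source) -> List[GenomeSynologSummary]:
    table = _read_table(source)
    out = []
    for _, row in table.iterrows():
        out.append(
            GenomeSynologSummary(
                genome_id=row["genome_id"],
                n_genes=int(row["n_genes"]),
                n_synologs=int(row["n_synologs"]),
                n_groups=int(row["n_groups"]),
                synolog_fraction=float(row["synolog_fraction"]),
                mean_pair_identity=float(row["mean_pair_identity"]),
                subcategory_group_counts=json.loads(
                    row["subcategory_group_counts"]
                ),
                n_groups_at_cutoff=None if row["n_groups_at_cutoff"] == ""
                else int(row["n_groups_at_cutoff"]),
                n_proteins_total=None if row["n_proteins_total"] == ""
                else int(row["n_proteins_total"]),
            )
        )
    return out


def cohort_to_dict(cohort: CohortSummary) -> Dict:
    d = dataclasses.asdict(cohort)
    d["metrics"] = {
        name: dataclasses.asdict(m) if isinstance(m, MetricSummary) else m
        for name, m in cohort.metrics.items()
    }
    return d


def write_cohort(cohort: CohortSummary, sink: Source) -> None:
    own = isinstance(sink, (str, Path))
    handle = open(sink, "w") if own else sink
    try:
        json.dump(cohort_to_dict(cohort), handle, indent=2, sort_keys=True)
        handle.write("\n")
    finally:
        if own:
            handle.close()


def read_cohort(source: Source) -> CohortSummary:
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    try:
        d = json.load(handle)
    finally:
        if own:
            handle.close()
    d["metrics"] = {k: MetricSummary(**v) for k, v in d["metrics"].items()}
    return CohortSummary(**d)


def write_truth(truth: TruthTable, sink: Source) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": gid,
                "group": e.group or "",
                "is_truncated": int(e.is_truncated),
                "subcategory": e.subcategory or "",
                "contig": e.contig,
                "rank": e.rank,
            }
            for gid, e in truth.items()
        ]
    ).to_csv(sink, sep="\t", index=False)


def read_truth(source: Source) -> TruthTable:
    table = _read_table(source)
    return {
        row["gene_id"]: TruthEntry(
            group=row["group"] or None,
            is_truncated=bool(int(row["is_truncated"])),
            subcategory=row["subcategory"] or None,
            contig=row["contig"],
            rank=int(row["rank"]),
        )
        for _, row in table.iterrows()
    }


def write_run_log(
    sink: Source, resolved_config: Dict, header: Optional[str] = None
) -> None:
    """Plain-text echo of every resolved parameter (incl. the RNG seed)."""
    own = isinstance(sink, (str, Path))
    handle = open(sink, "w") if own else sink
    try:
        if header:
            handle.write(f"# {header}\n")
        for key in sorted(resolved_config):
            handle.write(f"{key} = {resolved_config[key]!r}\n")
    finally:
        if own:
            handle.close()
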