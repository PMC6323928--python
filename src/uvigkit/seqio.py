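"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Bio.SeqIO; tables are tab-delimited with a header row and
go through pandas. All coordinates written to output files are 1-based
inclusive; internal coordinates are 0-based half-open.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .records import GroupMembership, MarkerHit, QualityTier, ViralContig

PathLike = Union[str, Path]

REPORT_COLUMNS = [
    "contig_id",
    "length",
    "circular",
    "circular_mechanism",
    "false_positive_circular",
    "votu",
    "taxon",
    "predicted_genome_size",
    "completeness_pct",
    "quality_tier",
    "host_domain",
    "host_prediction",
    "host_method",
]


def read_fasta(path: PathLike, source_class: str = "uvig") -> list[ViralContig]:
    """Read a FASTA file into :class:`ViralContig` records.

    Ids are the first whitespace-delimited token of each header; sequences
    are uppercased and validated to A/C/G/T/N. An empty file or a duplicate
    id is an error.
    """
    contigs: list[ViralContig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        seen.add(record.id)
        contigs.append(
            ViralContig(id=record.id, sequence=str(record.seq), source_class=source_class)
        )
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return contigs


def write_fasta(contigs: Iterable[ViralContig], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.id}\n")
            for i in range(0, contig.length, width):
                fh.write(contig.sequence[i : i + width] + "\n")


def _read_table(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_hit_table(path: PathLike) -> list[MarkerHit]:
    """Read taxonomic marker hits (contig_id, model_id, taxon, taxon_class)."""
    df = _read_table(path, ["contig_id", "model_id", "taxon", "taxon_class"])
    return [
        MarkerHit(row.contig_id, row.model_id, row.taxon, row.taxon_class)
        for row in df.itertuples(index=False)
    ]


def read_group_table(path: PathLike) -> list[GroupMembership]:
    """Read genus-level group memberships (seq_id, group_id, member_class)."""
    df = _read_table(path, ["seq_id", "group_id", "member_class"])
    dup = df["seq_id"][df["seq_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: sequence(s) in more than one group: {sorted(set(dup))}")
    return [
        GroupMembership(row.seq_id, row.group_id, row.member_class)
        for row in df.itertuples(index=False)
    ]


def read_ref_length_table(path: PathLike) -> dict[str, float]:
    """Read mean isolate genome lengths per taxon (taxon, mean_genome_length)."""
    df = _read_table(path, ["taxon", "mean_genome_length"])
    return {row.taxon: float(row.mean_genome_length) for row in df.itertuples(index=False)}


def read_host_table(path: PathLike) -> pd.DataFrame:
    """Read known virus-host links (seq_id, host_lineage, source)."""
    return _read_table(path, ["seq_id", "host_lineage", "source"])


def read_vpf_reference_hits(path: PathLike) -> pd.DataFrame:
    """Read per-model reference hits with host domains (model_id, host_domain).

    One row per hit of a protein family against a known viral genome whose
    host domain is annotated; this table feeds the uniformity score.
    """
    return _read_table(path, ["model_id", "host_domain"])


def read_contig_vpf_hits(path: PathLike) -> pd.DataFrame:
    """Read protein-family hits on contigs (contig_id, model_id)."""
    return _read_table(path, ["contig_id", "model_id"])


def read_spacers(path: PathLike) -> list[tuple[str, str]]:
    """Read CRISPR spacer sequences from FASTA as (id, sequence) pairs."""
    spacers = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not spacers:
        raise ValueError(f"no spacer records found in {path}")
    return spacers


def write_circular_calls(contigs: Iterable[ViralContig], path: PathLike) -> None:
    """Write circularity calls; repeat-copy positions are 1-based starts."""
    rows = []
    for c in contigs:
        call = c.circularity
        if call is None:
            continue
        rows.append(
            {
                "contig_id": c.id,
                "circular": "true" if call.is_circular else "false",
                "mechanism": call.mechanism,
                "repeat_length": call.repeat_length,
                "five_prime_pos": call.five_prime_pos + 1 if call.five_prime_pos is not None else "NA",
                "three_prime_pos": call.three_prime_pos + 1 if call.three_prime_pos is not None else "NA",
            }
        )
    pd.DataFrame(
        rows,
        columns=["contig_id", "circular", "mechanism", "repeat_length",
                 "five_prime_pos", "three_prime_pos"],
    ).to_csv(path, sep="\t", index=False)


def read_circular_calls(path: PathLike):
    """Read circularity calls back into a contig_id -> CircularityCall map."""
    from .circularity import CircularityCall

    df = _read_table(
        path,
        ["contig_id", "circular", "mechanism", "repeat_length",
         "five_prime_pos", "three_prime_pos"],
    )
    calls = {}
    for row in df.itertuples(index=False):
        calls[row.contig_id] = CircularityCall(
            is_circular=row.circular == "true",
            mechanism=row.mechanism,
            repeat_length=int(row.repeat_length),
            five_prime_pos=None if row.five_prime_pos == "NA" else int(row.five_prime_pos) - 1,
            three_prime_pos=None if row.three_prime_pos == "NA" else int(row.three_prime_pos) - 1,
        )
    return calls


def write_votu_table(votus, path: PathLike) -> None:
    """Write clustering results as seq_id, votu_name, n_members rows."""
    rows = [
        {"seq_id": member, "votu_name": v.name, "n_members": len(v.member_ids)}
        for v in votus
        for member in v.member_ids
    ]
    pd.DataFrame(rows, columns=["seq_id", "votu_name", "n_members"]).to_csv(
        path, sep="\t", index=False
    )


def read_votu_table(path: PathLike):
    """Read a clustering table back into VOTU records."""
    from .votu import VOTU

    df = _read_table(path, ["seq_id", "votu_name", "n_members"])
    members: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        members.setdefault(row.votu_name, []).append(row.seq_id)
    return [VOTU(name=name, member_ids=tuple(sorted(ids))) for name, ids in members.items()]


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, QualityTier):
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.1f}"
    return str(value)


def write_report(contigs: Iterable[ViralContig], path: PathLike) -> None:
    """Write the consolidated per-contig report (13 tab-delimited columns).

    Undefined fields are emitted as ``NA``; completeness and predicted
    genome size are rounded to one decimal for reporting.
    """
    rows = []
    for c in contigs:
        call = c.circularity
        is_circ = bool(call is not None and call.is_circular)
        rows.append(
            {
                "contig_id": c.id,
                "length": c.length,
                "circular": _fmt(is_circ),
                "circular_mechanism": call.mechanism if is_circ else "NA",
                "false_positive_circular": _fmt(c.false_positive_circular) if is_circ else "NA",
                "votu": _fmt(c.votu),
                "taxon": _fmt(c.taxon),
                "predicted_genome_size": _fmt(c.predicted_genome_size),
                "completeness_pct": _fmt(c.completeness_pct),
                "quality_tier": _fmt(c.quality_tier),
                "host_domain": _fmt(c.host_domain),
                "host_prediction": _fmt(c.host_prediction),
                "host_method": _fmt(c.host_method),
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
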