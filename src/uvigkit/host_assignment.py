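"""Specific virus-host prediction.

Two complementary routes:

* cluster propagation — unlabeled members of a vOTU containing at least one
  virus with a known host (isolate or curated prophage) inherit the lowest
  common ancestor of the known host lineages in that cluster;
* CRISPR spacer matching — a microbial CRISPR array stores 25-65 bp
  virus-derived spacers; a (near-)exact occurrence of a spacer in a contig
  links the contig to the spacer's host. Matching is full-spacer-length,
  substitutions only (default at most 1 mismatch), both strands, N never
  matches.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .records import ViralContig, reverse_complement
from .votu import VOTU

logger = logging.getLogger(__name__)

LINEAGE_SEP = ";"
SPACER_MIN_LEN = 25
SPACER_MAX_LEN = 65
_N_BYTE = ord("N")


@dataclass(frozen=True)
class HostLabel:
    """A host lineage attached to one viral sequence.

    ``host_lineage`` is a ranked, semicolon-separated taxonomy path
    (domain;phylum;...;genus). ``source`` records the evidence: ``isolate``
    or ``prophage`` for curated links, ``spacer`` for CRISPR evidence,
    ``cluster`` for labels propagated through vOTU co-membership.
    """

    seq_id: str
    host_lineage: str
    source: str

    def __post_init__(self) -> None:
        if not self.host_lineage.strip(LINEAGE_SEP).strip():
            raise ValueError(f"label for {self.seq_id!r}: empty host lineage")

    @property
    def ranks(self) -> tuple[str, ...]:
        return tuple(r.strip() for r in self.host_lineage.split(LINEAGE_SEP) if r.strip())


@dataclass(frozen=True)
class SpacerMatch:
    """A spacer occurrence on a contig: 0-based start on the forward
    strand, strand of the spacer, and number of mismatching positions."""

    spacer_id: str
    contig_id: str
    position: int
    strand: str
    mismatches: int


def lineage_lca(lineages: Sequence[str]) -> str:
    """Lowest common ancestor of ranked lineage strings (longest common
    rank prefix)."""
    if not lineages:
        raise ValueError("lineage_lca requires at least one lineage")
    split = [[r.strip() for r in lin.split(LINEAGE_SEP) if r.strip()] for lin in lineages]
    common: list[str] = []
    for ranks in zip(*split):
        if len(set(ranks)) == 1:
            common.append(ranks[0])
        else:
            break
    return LINEAGE_SEP.join(common)


def propagate_cluster_hosts(
    votus: Iterable[VOTU], labels: Iterable[HostLabel]
) -> list[HostLabel]:
    """Propagate host labels within vOTUs.

    Every unlabeled member of a cluster containing at least one labeled
    member receives the LCA of the cluster's known lineages (with source
    ``cluster``). Existing labels are never overwritten; labels for ids not
    present in any cluster are skipped with a warning. Returns only the
    newly created labels.
    """
    votus = list(votus)
    member_ids = {m for v in votus for m in v.member_ids}
    by_id: dict[str, list[HostLabel]] = {}
    for label in labels:
        if label.seq_id not in member_ids:
            logger.warning("host label for unknown sequence %r skipped", label.seq_id)
            continue
        by_id.setdefault(label.seq_id, []).append(label)

    propagated: list[HostLabel] = []
    for votu in votus:
        known = [l.host_lineage for m in votu.member_ids for l in by_id.get(m, [])]
        if not known:
            continue
        lca = lineage_lca(known)
        if not lca:
            continue  # known lineages disagree even at domain rank
        for member in votu.member_ids:
            if member not in by_id:
                propagated.append(HostLabel(member, lca, source="cluster"))
    return propagated


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_one_strand(contig_arr: np.ndarray, spacer_arr: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    if contig_arr.size < spacer_arr.size:
        return []
    windows = sliding_window_view(contig_arr, spacer_arr.size)
    mismatch = (windows != spacer_arr) | (windows == _N_BYTE) | (spacer_arr == _N_BYTE)
    counts = mismatch.sum(axis=1)
    return [(int(i), int(counts[i])) for i in np.nonzero(counts <= max_mm)[0]]


def match_spacers(
    contigs: Iterable[ViralContig],
    spacers: Iterable[tuple[str, str]],
    max_mismatches: int = 1,
    min_len: int = SPACER_MIN_LEN,
    max_len: int = SPACER_MAX_LEN,
) -> list[SpacerMatch]:
    """Find every occurrence of each spacer in every contig, on both
    strands, allowing at most ``max_mismatches`` substitutions over the
    full spacer length (no indels).

    Spacers outside [``min_len``, ``max_len``] bp are skipped with a
    warning. Positions are 0-based starts on the contig's forward strand.
    """
    usable: list[tuple[str, str]] = []
    for spacer_id, seq in spacers:
        seq = seq.upper()
        if not (min_len <= len(seq) <= max_len):
            logger.warning(
                "spacer %r skipped: length %d outside [%d, %d] bp",
                spacer_id, len(seq), min_len, max_len,
            )
            continue
        usable.append((spacer_id, seq))

    matches: list[SpacerMatch] = []
    for contig in contigs:
        contig_arr = _encode(contig.sequence)
        for spacer_id, seq in usable:
            for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
                if strand == "-" and oriented == seq:
                    continue  # palindromic spacer: both strands identical
                for pos, mm in _scan_one_strand(contig_arr, _encode(oriented), max_mismatches):
                    matches.append(SpacerMatch(spacer_id, contig.id, pos, strand, mm))
    return matches


def summarize_host_phyla(labels: Iterable[HostLabel]) -> pd.DataFrame:
    """Count distinct labeled sequences per host phylum (rank 2 of the
    lineage), descending; ties broken alphabetically."""
    seen: dict[str, set[str]] = {}
    for label in labels:
        ranks = label.ranks
        if len(ranks) < 2:
            continue
        seen.setdefault(ranks[1], set()).add(label.seq_id)
    rows = sorted(
        ((phylum, len(ids)) for phylum, ids in seen.items()),
        key=lambda r: (-r[1], r[0]),
    )
    return pd.DataFrame(rows, columns=["phylum", "n_contigs"])
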