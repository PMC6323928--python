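"""Pairwise ANI / aligned fraction and single-linkage vOTU clustering.

Two sequences belong to the same viral OTU (a species-like unit) when they
share >= 95% average nucleotide identity over >= 85% of the length of the
shorter sequence, and clusters are the connected components of that
relation (single linkage).

ANI is computed from local alignments: the shorter sequence is the query,
both of its strands are aligned against the longer sequence, and alignment
blocks are collected greedily (best local alignment, mask the covered query
region, realign) until the block score drops below ``min_block_score``.
ANI is matched columns over aligned columns, length-weighted across blocks;
the aligned fraction is the union of query bases covered by any block,
divided by the query length.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .records import ViralContig, reverse_complement

DEFAULT_MIN_BLOCK_SCORE = 30.0
DEFAULT_MAX_BLOCKS = 10


@dataclass(frozen=True)
class AniResult:
    """ANI (% identity over aligned columns) and aligned fraction of the
    shorter sequence (%). Symmetric in the two input sequences."""

    ani_pct: float
    af_shorter_pct: float


@dataclass(frozen=True)
class ClusteringParams:
    """Species-rank thresholds: 95% ANI over 85% of the shorter sequence."""

    min_ani_pct: float = 95.0
    min_af_pct: float = 85.0

    def __post_init__(self) -> None:
        for value in (self.min_ani_pct, self.min_af_pct):
            if not (0 < value <= 100):
                raise ValueError("clustering thresholds must lie in (0, 100]")


@dataclass(frozen=True)
class VOTU:
    """A viral OTU: ``vc_<k>`` for clusters of >= 2 members, ``sg_<k>`` for
    singletons."""

    name: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.name.startswith("vc_") and len(self.member_ids) < 2:
            raise ValueError(f"{self.name}: vc_ clusters need >= 2 members")
        if self.name.startswith("sg_") and len(self.member_ids) != 1:
            raise ValueError(f"{self.name}: sg_ singletons have exactly 1 member")


def build_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    """Local aligner over A/C/G/T/N where N matches nothing (scores as a
    mismatch against every symbol, itself included)."""
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            matrix[a, b] = match if (a == b and a != "N") else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _greedy_blocks(
    target: str,
    query: str,
    aligner: Align.PairwiseAligner,
    min_block_score: float,
    max_blocks: int,
) -> tuple[list[tuple[int, int, float]], list[tuple[int, int]], float]:
    """Collect local alignment blocks, masking the covered query span after
    each round so blocks never overlap on the query.

    Returns (per-block (matches, columns, score), query spans, total score).
    """
    blocks: list[tuple[int, int, float]] = []
    spans: list[tuple[int, int]] = []
    total_score = 0.0
    masked = query
    for _ in range(max_blocks):
        result = aligner.align(target, masked)
        if result.score < min_block_score:
            break
        aln = result[0]
        tsegs, qsegs = aln.aligned
        matches = 0
        columns = 0
        prev_t = prev_q = None
        for (ts, te), (qs, qe) in zip(tsegs, qsegs):
            for x, y in zip(target[ts:te], masked[qs:qe]):
                if x == y and x != "N":
                    matches += 1
            columns += te - ts
            if prev_t is not None:  # gap columns between aligned segments
                columns += (ts - prev_t) + (qs - prev_q)
            prev_t, prev_q = te, qe
        q_start, q_end = int(qsegs[0][0]), int(qsegs[-1][1])
        blocks.append((matches, columns, float(result.score)))
        spans.append((q_start, q_end))
        total_score += float(result.score)
        masked = masked[:q_start] + "N" * (q_end - q_start) + masked[q_end:]
    return blocks, spans, total_score


def _union_length(spans: Iterable[tuple[int, int]]) -> int:
    covered = 0
    end_prev = None
    for start, end in sorted(spans):
        if end_prev is None or start >= end_prev:
            covered += end - start
            end_prev = end
        elif end > end_prev:
            covered += end - end_prev
            end_prev = end
    return covered


def pairwise_ani(
    a: str,
    b: str,
    *,
    aligner: Optional[Align.PairwiseAligner] = None,
    min_block_score: float = DEFAULT_MIN_BLOCK_SCORE,
    max_blocks: int = DEFAULT_MAX_BLOCKS,
) -> AniResult:
    """ANI and aligned fraction between two nucleotide sequences.

    The shorter sequence is always designated the query (ties broken
    lexicographically), making the result symmetric by construction. Both
    query strands are tried and the orientation with the higher total
    aligned score wins.
    """
    if not a or not b:
        raise ValueError("pairwise_ani requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    if (len(a), a) <= (len(b), b):
        query, target = a, b
    else:
        query, target = b, a
    aligner = aligner or build_aligner()

    best = None
    for oriented in (query, reverse_complement(query)):
        candidate = _greedy_blocks(target, oriented, aligner, min_block_score, max_blocks)
        if best is None or candidate[2] > best[2]:
            best = candidate
    blocks, spans, _ = best

    total_matches = sum(m for m, _, _ in blocks)
    total_columns = sum(c for _, c, _ in blocks)
    if total_columns == 0:
        return AniResult(0.0, 0.0)
    ani = 100.0 * total_matches / total_columns
    af = 100.0 * _union_length(spans) / len(query)
    return AniResult(ani, af)


def _canonical_kmers(seq: str, k: int) -> set[str]:
    kmers = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        kmers.add(min(kmer, reverse_complement(kmer)))
    return kmers


def build_votus(
    contigs: Sequence[ViralContig],
    params: ClusteringParams | None = None,
    *,
    aligner: Optional[Align.PairwiseAligner] = None,
    prefilter_k: int = 16,
    prefilter_min_shared: int = 5,
) -> list[VOTU]:
    """Single-linkage clustering into vOTUs.

    An edge joins two sequences when ANI >= ``min_ani_pct`` and AF >=
    ``min_af_pct``; vOTUs are the connected components, named ``vc_<k>``
    (>= 2 members) or ``sg_<k>`` (singletons), ordered by descending size
    then lexicographically smallest member id.

    A canonical shared-k-mer prefilter skips the alignment for pairs that
    cannot reach the identity threshold (set ``prefilter_min_shared=0`` to
    disable).
    """
    params = params or ClusteringParams()
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("contig ids must be unique for clustering")
    aligner = aligner or build_aligner()

    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(ids)
    kmer_sets = (
        [_canonical_kmers(c.sequence, prefilter_k) for c in contigs]
        if prefilter_min_shared > 0
        else None
    )
    for i in range(len(contigs)):
        for j in range(i + 1, len(contigs)):
            if kmer_sets is not None:
                if len(kmer_sets[i] & kmer_sets[j]) < prefilter_min_shared:
                    continue
            result = pairwise_ani(contigs[i].sequence, contigs[j].sequence, aligner=aligner)
            if result.ani_pct >= params.min_ani_pct and result.af_shorter_pct >= params.min_af_pct:
                graph.add_edge(ids[i], ids[j])

    components = sorted(
        (sorted(component) for component in nx.connected_components(graph)),
        key=lambda members: (-len(members), members[0]),
    )
    votus: list[VOTU] = []
    n_vc = n_sg = 0
    for members in components:
        if len(members) >= 2:
            n_vc += 1
            name = f"vc_{n_vc}"
        else:
            n_sg += 1
            name = f"sg_{n_sg}"
        votus.append(VOTU(name=name, member_ids=tuple(members)))
    return votus
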