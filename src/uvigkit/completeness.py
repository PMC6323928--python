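"""Genome completeness estimation and quality tiering.

Completeness of a linear contig is its length relative to an expected
genome size, borrowed either from the mean isolate genome length of its
marker-affiliated taxon or from its genus-level group (mean length of the
group's isolates and complete circular members, accepted only when the
standard deviation is <= 15% of the mean). Linear contigs longer than the
expected size are capped at 99% (likely near-complete). Circular contigs
that survive false-positive filtering are treated as complete genomes.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .records import MarkerHit, QualityTier, ViralContig

#: Minimum number of consistent taxonomic markers per virus class.
MARKER_MINIMUMS = {"dsDNA": 2, "NCLDV": 5, "ssDNA": 1, "RNA": 1}


@dataclass(frozen=True)
class CompletenessParams:
    """Filtering and tiering constants.

    ``fp_min_length_fraction``: a circular contig shorter than this fraction
    of its group's minimum isolate length (or, in isolate-free groups, of
    the maximum linear member length) is a false positive.
    ``fp_short_circular_bp``: circular contigs below this length without an
    ssDNA/RNA marker affiliation are false positives (they would be
    implausibly small dsDNA genomes).
    ``max_size_sd_fraction``: a group predicts a genome size only when the
    SD of its complete-member lengths is within this fraction of the mean.
    ``high_quality_min_pct`` / ``oversize_completeness_pct``: tier boundary
    and the cap applied to over-length linear contigs.
    """

    fp_min_length_fraction: float = 0.8
    fp_short_circular_bp: int = 10_000
    max_size_sd_fraction: float = 0.15
    high_quality_min_pct: float = 90.0
    oversize_completeness_pct: float = 99.0


@dataclass
class GenusGroup:
    """A genus-level group with member lengths split by class.

    ``isolate_lengths`` and ``circular_lengths`` contribute to the predicted
    genome size; ``linear_lengths`` are the remaining members (including
    reclassified false-positive circulars).
    """

    group_id: str
    isolate_lengths: list[int] = field(default_factory=list)
    circular_lengths: list[int] = field(default_factory=list)
    linear_lengths: list[int] = field(default_factory=list)
    predicted_genome_size: Optional[float] = None
    size_sd: Optional[float] = None


@dataclass(frozen=True)
class TaxonAffiliation:
    """Marker-based taxon assignment for one contig."""

    contig_id: str
    taxon: str
    taxon_class: str
    n_supporting_markers: int
    mean_taxon_genome_length: Optional[float] = None


def affiliate_by_markers(
    hits: Iterable[MarkerHit],
    contig_id: str,
    ref_lengths: Optional[Mapping[str, float]] = None,
) -> Optional[TaxonAffiliation]:
    """Affiliate a contig to the taxon with the most consistent markers.

    The winning taxon must meet its class minimum (dsDNA: 2, NCLDV: 5,
    ssDNA/RNA: 1); a tie for the top count yields no affiliation. A taxon
    label carrying two different classes across hits is an error.
    """
    mine = [h for h in hits if h.contig_id == contig_id]
    if not mine:
        return None
    classes: dict[str, set[str]] = defaultdict(set)
    counts: Counter[str] = Counter()
    for hit in mine:
        classes[hit.taxon].add(hit.taxon_class)
        counts[hit.taxon] += 1
    for taxon, taxon_classes in classes.items():
        if len(taxon_classes) > 1:
            raise ValueError(
                f"contig {contig_id!r}: taxon {taxon!r} carries conflicting "
                f"classes {sorted(taxon_classes)}"
            )
    top_count = max(counts.values())
    leaders = [t for t, n in counts.items() if n == top_count]
    if len(leaders) > 1:
        return None
    taxon = leaders[0]
    taxon_class = next(iter(classes[taxon]))
    if top_count < MARKER_MINIMUMS[taxon_class]:
        return None
    mean_length = ref_lengths.get(taxon) if ref_lengths else None
    return TaxonAffiliation(contig_id, taxon, taxon_class, top_count, mean_length)


def flag_false_positive_circular(
    contig: ViralContig,
    group: Optional[GenusGroup],
    affiliation: Optional[TaxonAffiliation],
    params: CompletenessParams | None = None,
) -> tuple[bool, str]:
    """Decide whether a circular contig is a spurious complete-genome call.

    Rules, in order: shorter than 80% of the group's minimum isolate length;
    shorter than 80% of the maximum linear member in an isolate-free group;
    shorter than 10 kb without an ssDNA/RNA marker affiliation. Flagged
    contigs are thereafter treated as linear.
    """
    params = params or CompletenessParams()
    if contig.circularity is None or not contig.circularity.is_circular:
        raise ValueError(f"contig {contig.id!r} has no positive circularity call")
    length = contig.length
    frac = params.fp_min_length_fraction
    if group is not None and group.isolate_lengths:
        if length < frac * min(group.isolate_lengths):
            return True, "length_below_80pct_of_min_isolate"
    elif group is not None and group.linear_lengths:
        if length < frac * max(group.linear_lengths):
            return True, "length_below_80pct_of_max_linear"
    if length < params.fp_short_circular_bp and (
        affiliation is None or affiliation.taxon_class not in ("ssDNA", "RNA")
    ):
        return True, "short_circular_without_ssDNA_or_RNA_affiliation"
    return False, ""


def predicted_genome_size(
    group: GenusGroup, params: CompletenessParams | None = None
) -> Optional[float]:
    """Mean length of the group's isolates and complete circular members,
    accepted only when the population SD is <= 15% of the mean.

    A single contributing length has SD 0 and always yields a size. Updates
    ``group.predicted_genome_size`` and ``group.size_sd`` in place.
    """
    params = params or CompletenessParams()
    lengths = list(group.isolate_lengths) + list(group.circular_lengths)
    if not lengths:
        group.predicted_genome_size = None
        group.size_sd = None
        return None
    mean = float(np.mean(lengths))
    sd = float(np.std(lengths))  # population SD: members are the population
    group.size_sd = sd
    group.predicted_genome_size = mean if sd <= params.max_size_sd_fraction * mean else None
    return group.predicted_genome_size


def estimate_completeness(
    contig: ViralContig,
    size_ref: Optional[float],
    params: CompletenessParams | None = None,
) -> Optional[float]:
    """Completeness of a linear contig against an expected genome size.

    Returns 100 * length / size_ref (unrounded; report writers round to one
    decimal), capped at 99% when the contig exceeds the expected size, and
    None when no size is available. Complete circular contigs bypass this
    estimate entirely.
    """
    params = params or CompletenessParams()
    if size_ref is None:
        return None
    if size_ref <= 0:
        raise ValueError("size_ref must be positive")
    if contig.length > size_ref:
        return params.oversize_completeness_pct
    return 100.0 * contig.length / size_ref


def assign_quality_tier(
    contig: ViralContig, params: CompletenessParams | None = None
) -> QualityTier:
    """Tier a contig: isolate references are finished genomes; non-FP
    circulars are likely complete; linear contigs split at 90% estimated
    completeness into high-quality drafts and genome fragments."""
    params = params or CompletenessParams()
    if contig.source_class == "isolate":
        return QualityTier.FINISHED
    if contig.is_complete_circular:
        return QualityTier.COMPLETE_CIRCULAR
    if (
        contig.completeness_pct is not None
        and contig.completeness_pct >= params.high_quality_min_pct
    ):
        return QualityTier.HIGH_QUALITY_DRAFT
    return QualityTier.GENOME_FRAGMENT
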