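"""Core domain records shared across the toolkit.

A :class:`ViralContig` is the unit of work: a nucleotide sequence plus the
annotations accumulated by the pipeline (circularity call, vOTU membership,
taxon affiliation, completeness, quality tier, host predictions).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .circularity import CircularityCall

SOURCE_CLASSES = ("isolate", "prophage", "uvig")
TAXON_CLASSES = ("dsDNA", "NCLDV", "ssDNA", "RNA")
MEMBER_CLASSES = ("isolate_reference", "circular", "linear")
VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class QualityTier(str, Enum):
    """MIUViG-style genome quality categories.

    ``finished``: isolate reference genome.
    ``complete_circular``: circular contig not flagged as a false positive,
    treated as a likely complete genome.
    ``high_quality_draft``: linear contig with estimated completeness >= 90%.
    ``genome_fragment``: everything else (low completeness or no predicted
    genome size).
    """

    FINISHED = "finished"
    COMPLETE_CIRCULAR = "complete_circular"
    HIGH_QUALITY_DRAFT = "high_quality_draft"
    GENOME_FRAGMENT = "genome_fragment"


@dataclass
class ViralContig:
    """A viral genome or genome fragment with pipeline annotations.

    ``sequence`` is stored uppercase and restricted to A/C/G/T/N.
    ``completeness_pct`` lives in (0, 100] when defined; ``None`` means the
    completeness could not be estimated (no predicted genome size).
    """

    id: str
    sequence: str
    source_class: str = "uvig"
    circularity: Optional["CircularityCall"] = None
    false_positive_circular: bool = False
    fp_reason: Optional[str] = None
    votu: Optional[str] = None
    taxon: Optional[str] = None
    predicted_genome_size: Optional[float] = None
    completeness_pct: Optional[float] = None
    quality_tier: Optional[QualityTier] = None
    host_domain: Optional[str] = None
    host_prediction: Optional[str] = None
    host_method: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid characters {sorted(bad)!r}; "
                "only A/C/G/T/N are accepted"
            )
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(
                f"contig {self.id!r}: source_class {self.source_class!r} "
                f"not one of {SOURCE_CLASSES}"
            )
        if self.completeness_pct is not None and not (0 < self.completeness_pct <= 100):
            raise ValueError(
                f"contig {self.id!r}: completeness_pct must be in (0, 100]"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_complete_circular(self) -> bool:
        """True for a circular call that survived false-positive filtering."""
        return (
            self.circularity is not None
            and self.circularity.is_circular
            and not self.false_positive_circular
        )


@dataclass(frozen=True)
class MarkerHit:
    """A taxonomic marker (VOG) hit on a contig.

    ``taxon`` is a genus for dsDNA viruses and a family for ssDNA/RNA
    viruses; ``taxon_class`` selects the per-class marker minimum used for
    affiliation.
    """

    contig_id: str
    model_id: str
    taxon: str
    taxon_class: str

    def __post_init__(self) -> None:
        if self.taxon_class not in TAXON_CLASSES:
            raise ValueError(
                f"marker hit on {self.contig_id!r}: taxon_class "
                f"{self.taxon_class!r} not one of {TAXON_CLASSES}"
            )


@dataclass(frozen=True)
class GroupMembership:
    """Membership of one sequence in a genus-level group.

    Group construction (gene-sharing networks) is upstream of this toolkit;
    the table is consumed as input. ``member_class`` records how the member
    contributes to the group's predicted genome size.
    """

    seq_id: str
    group_id: str
    member_class: str

    def __post_init__(self) -> None:
        if self.member_class not in MEMBER_CLASSES:
            raise ValueError(
                f"group member {self.seq_id!r}: member_class "
                f"{self.member_class!r} not one of {MEMBER_CLASSES}"
            )
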