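"""Host-domain uniformity scoring of viral protein families (VPFs).

Each protein family is scored by how uniformly its hits against viruses of
known hosts fall into a single host domain (prokaryotic vs eukaryotic):

    score = (#uniform hits / #total hits)

and, for families with fewer hits than the database-wide average per model
(6.8 by default), the score is shrunk by (#total hits / average #hits).
Families scoring exactly 1.0 are domain signatures; a contig is classified
to the domain with the strict majority of its signature-family hits.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

DOMAINS = ("prokaryotic", "eukaryotic")
_SCORE_EPS = 1e-9  # float tolerance when testing score == 1.0


@dataclass(frozen=True)
class ScoringContext:
    """``average_hits``: database-wide mean hits per model (default 6.8,
    derived from ~11 400 scored families). ``signature_threshold``: score
    required for a family to act as a domain signature."""

    average_hits: float = 6.8
    signature_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.average_hits <= 0:
            raise ValueError("average_hits must be positive")


@dataclass(frozen=True)
class VPFProfile:
    """Per-family hit profile and its uniformity score."""

    model_id: str
    hits_per_domain: Mapping[str, int]
    total_hits: int
    uniform_hits: int
    score: float

    @property
    def dominant_domain(self) -> str:
        return max(self.hits_per_domain, key=lambda d: (self.hits_per_domain[d], d))


def vpf_uniformity_score(
    hits_per_domain: Mapping[str, int],
    ctx: ScoringContext | None = None,
    mode: str = "majority",
) -> float:
    """Uniformity score of one family, clamped to [0, 1].

    ``mode="majority"`` counts the dominant domain's hits as the uniform
    hits (so a fully uniform profile scores 1 before the low-count
    correction, and a split profile scores its dominant fraction).
    ``mode="strict"`` counts uniform hits only when every hit falls in a
    single domain, and 0 otherwise.
    """
    ctx = ctx or ScoringContext()
    unknown = set(hits_per_domain) - set(DOMAINS)
    if unknown:
        raise ValueError(f"unknown host domain(s) {sorted(unknown)!r}")
    if any(n < 0 for n in hits_per_domain.values()):
        raise ValueError("hit counts must be non-negative")
    total = sum(hits_per_domain.values())
    if total < 1:
        raise ValueError("scoring requires at least one hit")
    nonzero = [n for n in hits_per_domain.values() if n > 0]
    if mode == "majority":
        uniform = max(nonzero)
    elif mode == "strict":
        uniform = total if len(nonzero) == 1 else 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    score = uniform / total
    if total < ctx.average_hits:
        score *= total / ctx.average_hits
    return min(max(score, 0.0), 1.0)


def profiles_from_table(
    hits: pd.DataFrame,
    ctx: ScoringContext | None = None,
    mode: str = "majority",
) -> list[VPFProfile]:
    """Score every model in a reference hit table (model_id, host_domain;
    one row per hit against a virus of known host domain)."""
    ctx = ctx or ScoringContext()
    profiles = []
    for model_id, group in hits.groupby("model_id", sort=True):
        counts = Counter(group["host_domain"])
        total = sum(counts.values())
        score = vpf_uniformity_score(counts, ctx, mode=mode)
        nonzero = [n for n in counts.values() if n > 0]
        uniform = max(nonzero) if mode == "majority" else (total if len(nonzero) == 1 else 0)
        profiles.append(
            VPFProfile(
                model_id=str(model_id),
                hits_per_domain=dict(counts),
                total_hits=total,
                uniform_hits=uniform,
                score=score,
            )
        )
    return profiles


def recompute_average_hits(hits: pd.DataFrame) -> float:
    """Mean number of hits per model in a reference hit table, for use as
    ``ScoringContext.average_hits`` instead of the published default."""
    if hits.empty:
        raise ValueError("cannot average an empty hit table")
    return float(hits.groupby("model_id").size().mean())


def select_signature_vpfs(
    profiles: Iterable[VPFProfile], ctx: ScoringContext | None = None
) -> dict[str, str]:
    """Families scoring exactly the signature threshold (1.0, within float
    tolerance), mapped to their single host domain."""
    ctx = ctx or ScoringContext()
    return {
        p.model_id: p.dominant_domain
        for p in profiles
        if p.score >= ctx.signature_threshold - _SCORE_EPS
    }


def classify_host_domain(
    contig_vpf_hits: Sequence[str], signatures: Mapping[str, str]
) -> str:
    """Classify a contig from its hits to signature families.

    The domain with the strict majority of signature hits wins; no
    signature hits or a tie yields ``unclassified``. Order of hits is
    irrelevant.
    """
    counts = Counter(signatures[m] for m in contig_vpf_hits if m in signatures)
    if not counts:
        return "unclassified"
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "unclassified"
    return ranked[0][0]
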