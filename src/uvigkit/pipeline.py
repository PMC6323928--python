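"""End-to-end orchestration: circularity -> clustering -> completeness ->
domain scoring -> host prediction, producing the consolidated report.

The stages follow the curation order used for large uncultivated-virus
catalogs: detect putative complete genomes first, cluster everything into
vOTUs, borrow expected genome sizes from marker taxa or genus-level groups
to tier the linear contigs, then attach host information at domain level
(protein-family signatures) and at specific level (cluster propagation and
CRISPR spacers).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import pandas as pd

from . import seqio
from .circularity import CircularityParams, detect_circularity
from .completeness import (
    CompletenessParams,
    GenusGroup,
    affiliate_by_markers,
    assign_quality_tier,
    estimate_completeness,
    flag_false_positive_circular,
    predicted_genome_size,
)
from .domain_scoring import (
    ScoringContext,
    classify_host_domain,
    profiles_from_table,
    select_signature_vpfs,
)
from .host_assignment import (
    HostLabel,
    lineage_lca,
    match_spacers,
    propagate_cluster_hosts,
)
from .records import ViralContig
from .votu import ClusteringParams, build_votus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline constants, with the published defaults.

    Circularity: 10 bp DTR floor, 20 bp windowed-repeat floor, 50 bp
    terminal window. Clustering: 95% ANI over 85% of the shorter sequence.
    Completeness: 80% false-positive length fraction, 10 kb unaffiliated-
    circular floor, 15% group SD cap, 90% high-quality boundary, 99%
    oversize cap. Scoring: 6.8 average hits per model. Spacers: 25-65 bp,
    at most 1 mismatch.
    """

    min_dtr_len: int = 10
    min_terminal_repeat_len: int = 20
    terminal_window: int = 50
    min_ani_pct: float = 95.0
    min_af_pct: float = 85.0
    fp_min_length_fraction: float = 0.8
    fp_short_circular_bp: int = 10_000
    max_size_sd_fraction: float = 0.15
    high_quality_min_pct: float = 90.0
    oversize_completeness_pct: float = 99.0
    average_hits: float = 6.8
    spacer_min_len: int = 25
    spacer_max_len: int = 65
    spacer_max_mismatches: int = 1

    @property
    def circularity(self) -> CircularityParams:
        return CircularityParams(
            self.min_dtr_len, self.min_terminal_repeat_len, self.terminal_window
        )

    @property
    def clustering(self) -> ClusteringParams:
        return ClusteringParams(self.min_ani_pct, self.min_af_pct)

    @property
    def completeness(self) -> CompletenessParams:
        return CompletenessParams(
            self.fp_min_length_fraction,
            self.fp_short_circular_bp,
            self.max_size_sd_fraction,
            self.high_quality_min_pct,
            self.oversize_completeness_pct,
        )

    @property
    def scoring(self) -> ScoringContext:
        return ScoringContext(average_hits=self.average_hits)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a flat ``key=value`` file (# comments)."""
        types = {f.name: f.type for f in fields(cls)}
        casts = {f.name: (int if f.type == "int" else float) for f in fields(cls)}
        overrides = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            overrides[key] = casts[key](value)
        return cls(**overrides)


@dataclass
class PipelineInputs:
    """Paths to the pipeline's input files. ``fasta`` is mandatory; stages
    whose inputs are None are skipped."""

    fasta: Path
    hits: Optional[Path] = None
    groups: Optional[Path] = None
    ref_lengths: Optional[Path] = None
    vpf_hits: Optional[Path] = None
    contig_vpf_hits: Optional[Path] = None
    hosts: Optional[Path] = None
    spacers: Optional[Path] = None
    spacer_hosts: Optional[Path] = None

    def validate(self) -> None:
        for f in fields(self):
            path = getattr(self, f.name)
            if path is not None and not Path(path).is_file():
                raise FileNotFoundError(f"input {f.name!r}: no such file {path}")


def annotate_completeness(
    contigs: list[ViralContig],
    hits,
    memberships,
    ref_lengths,
    params: CompletenessParams,
) -> dict[str, GenusGroup]:
    """Affiliate contigs, filter false-positive circulars, predict genome
    sizes, estimate completeness and assign quality tiers.

    Expects circularity calls already set on the contigs. Mutates the
    contigs in place; returns the genus-level groups with their predicted
    sizes populated.
    """
    by_id = {c.id: c for c in contigs}
    affiliations = {}
    for contig in contigs:
        aff = affiliate_by_markers(hits, contig.id, ref_lengths) if hits else None
        affiliations[contig.id] = aff
        if aff is not None:
            contig.taxon = aff.taxon

    group_of: dict[str, str] = {}
    groups: dict[str, GenusGroup] = {}
    for m in memberships:
        contig = by_id.get(m.seq_id)
        if contig is None:
            logger.warning("group member %r not in FASTA; skipped", m.seq_id)
            continue
        group = groups.setdefault(m.group_id, GenusGroup(group_id=m.group_id))
        group_of[m.seq_id] = m.group_id
        if m.member_class == "isolate_reference":
            contig.source_class = "isolate"
            group.isolate_lengths.append(contig.length)
        elif contig.circularity is not None and contig.circularity.is_circular:
            group.circular_lengths.append(contig.length)
        else:
            group.linear_lengths.append(contig.length)

    # flag FP circulars against the original group composition, then
    # reclassify them as linear before predicting genome sizes
    for contig in contigs:
        if contig.circularity is None or not contig.circularity.is_circular:
            continue
        if contig.source_class == "isolate":
            continue
        group = groups.get(group_of.get(contig.id, ""))
        fp, reason = flag_false_positive_circular(
            contig, group, affiliations[contig.id], params
        )
        contig.false_positive_circular = fp
        contig.fp_reason = reason or None
        if fp and group is not None:
            group.circular_lengths.remove(contig.length)
            group.linear_lengths.append(contig.length)
    n_fp = sum(1 for c in contigs if c.false_positive_circular)
    logger.info("false-positive filter: %d circular contig(s) reclassified", n_fp)

    for group in groups.values():
        predicted_genome_size(group, params)

    for contig in contigs:
        if contig.source_class == "isolate" or contig.is_complete_circular:
            contig.quality_tier = assign_quality_tier(contig, params)
            continue
        aff = affiliations[contig.id]
        size_ref = aff.mean_taxon_genome_length if aff is not None else None
        if size_ref is None:
            group = groups.get(group_of.get(contig.id, ""))
            size_ref = group.predicted_genome_size if group is not None else None
        contig.predicted_genome_size = size_ref
        contig.completeness_pct = estimate_completeness(contig, size_ref, params)
        contig.quality_tier = assign_quality_tier(contig, params)
    return groups


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs) -> list[ViralContig]:
    """Run every stage whose inputs are available; returns annotated contigs."""
    inputs.validate()
    contigs = seqio.read_fasta(inputs.fasta)
    by_id = {c.id: c for c in contigs}
    logger.info("read %d contigs from %s", len(contigs), inputs.fasta)

    memberships = seqio.read_group_table(inputs.groups) if inputs.groups else []
    host_table = seqio.read_host_table(inputs.hosts) if inputs.hosts else None
    for m in memberships:
        if m.member_class == "isolate_reference" and m.seq_id in by_id:
            by_id[m.seq_id].source_class = "isolate"
    if host_table is not None:
        for row in host_table.itertuples(index=False):
            if row.source in ("isolate", "prophage") and row.seq_id in by_id:
                if by_id[row.seq_id].source_class == "uvig":
                    by_id[row.seq_id].source_class = row.source if row.source == "isolate" else "prophage"

    # stage 1: circularity
    for contig in contigs:
        contig.circularity = detect_circularity(contig, config.circularity)
    n_circular = sum(1 for c in contigs if c.circularity.is_circular)
    logger.info("circularity: %d/%d contigs circular", n_circular, len(contigs))

    # stage 2: vOTU clustering
    votus = build_votus(contigs, config.clustering)
    for votu in votus:
        for member in votu.member_ids:
            by_id[member].votu = votu.name
    logger.info("clustering: %d vOTUs from %d contigs", len(votus), len(contigs))

    # stage 3: taxon affiliation, FP filtering, completeness, tiers
    hits = seqio.read_hit_table(inputs.hits) if inputs.hits else []
    ref_lengths = seqio.read_ref_length_table(inputs.ref_lengths) if inputs.ref_lengths else {}
    annotate_completeness(contigs, hits, memberships, ref_lengths, config.completeness)
    tier_counts = pd.Series([c.quality_tier.value for c in contigs]).value_counts()
    logger.info("quality tiers: %s", tier_counts.to_dict())

    # stage 4: host-domain classification from signature protein families
    if inputs.vpf_hits and inputs.contig_vpf_hits:
        vpf_table = seqio.read_vpf_reference_hits(inputs.vpf_hits)
        profiles = profiles_from_table(vpf_table, config.scoring)
        signatures = select_signature_vpfs(profiles, config.scoring)
        contig_hits = seqio.read_contig_vpf_hits(inputs.contig_vpf_hits)
        hits_per_contig = contig_hits.groupby("contig_id")["model_id"].apply(list)
        for contig in contigs:
            contig.host_domain = classify_host_domain(
                hits_per_contig.get(contig.id, []), signatures
            )
        n_classified = sum(1 for c in contigs if c.host_domain not in (None, "unclassified"))
        logger.info(
            "domain scoring: %d signature families, %d/%d contigs classified",
            len(signatures), n_classified, len(contigs),
        )

    # stage 5: specific host prediction
    if host_table is not None:
        known = [
            HostLabel(row.seq_id, row.host_lineage, row.source)
            for row in host_table.itertuples(index=False)
            if row.source in ("isolate", "prophage")
        ]
        for label in known:
            contig = by_id.get(label.seq_id)
            if contig is not None:
                contig.host_prediction = label.host_lineage
                contig.host_method = label.source
        propagated = propagate_cluster_hosts(votus, known)
        for label in propagated:
            contig = by_id[label.seq_id]
            contig.host_prediction = label.host_lineage
            contig.host_method = "cluster"
        logger.info("host propagation: %d label(s) propagated", len(propagated))

    if inputs.spacers:
        spacers = seqio.read_spacers(inputs.spacers)
        spacer_lineages: dict[str, str] = {}
        for table in (host_table, seqio.read_host_table(inputs.spacer_hosts) if inputs.spacer_hosts else None):
            if table is None:
                continue
            for row in table.itertuples(index=False):
                if row.source == "spacer":
                    spacer_lineages[row.seq_id] = row.host_lineage
        matches = match_spacers(
            contigs,
            spacers,
            max_mismatches=config.spacer_max_mismatches,
            min_len=config.spacer_min_len,
            max_len=config.spacer_max_len,
        )
        per_contig: dict[str, list[str]] = {}
        for match in matches:
            lineage = spacer_lineages.get(match.spacer_id)
            if lineage is not None:
                per_contig.setdefault(match.contig_id, []).append(lineage)
        for contig_id, lineages in per_contig.items():
            contig = by_id[contig_id]
            if contig.host_prediction is None:
                contig.host_prediction = lineage_lca(lineages)
                contig.host_method = "crispr_spacer"
            elif contig.host_method not in (None, "crispr_spacer"):
                # both evidence types: keep the propagated/curated lineage,
                # record that spacer evidence exists too
                contig.host_method = f"{contig.host_method}+crispr_spacer"
        logger.info("spacer matching: %d match(es) on %d contig(s)", len(matches), len(per_contig))

    return contigs


def run_all(config: PipelineConfig, inputs: PipelineInputs, report_path: str | Path) -> list[ViralContig]:
    """Run the pipeline and write the consolidated 13-column report."""
    contigs = run_pipeline(config, inputs)
    seqio.write_report(contigs, report_path)
    logger.info("report: %d row(s) written to %s", len(contigs), report_path)
    return contigs
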