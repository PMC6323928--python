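"""Deterministic synthetic-data generators.

Everything the pipeline consumes — contigs with planted terminal repeats,
identity ladders, marker and protein-family hit tables, genus-group and
host tables, CRISPR spacers — can be fabricated here, so every module is
testable without external downloads. Base composition is uniform over
A/C/G/T with no Ns (N handling is exercised by dedicated edge-case tests).
A single top-level seed derives independent substreams per generator
family, and identical inputs always yield byte-identical outputs.
"""
from __future__ import annotations

import zlib
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import circularity as _circ
from .records import ViralContig, reverse_complement
from .seqio import write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_ATTEMPTS = 200


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Derive an independent, reproducible random stream from a top-level
    seed and a stream name."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode()), index])


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random A/C/G/T sequence."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _plant(backbone: str, repeat_len: int, mode: str, rng: np.random.Generator) -> str:
    n = len(backbone)
    if mode == "direct_terminal":
        if repeat_len == 0:
            return backbone
        return backbone[: n - repeat_len] + backbone[:repeat_len]
    offset5 = int(rng.integers(0, 31))  # 5' copy starts well inside the window
    gap3 = 5  # 3' copy ends 5 bp before the contig end
    copy = backbone[offset5 : offset5 + repeat_len]
    if mode == "inverted":
        copy = reverse_complement(copy)
    end_start = n - gap3 - repeat_len
    if end_start <= offset5 + repeat_len:
        raise ValueError("sequence too short for the requested planted repeat")
    return backbone[:end_start] + copy + backbone[end_start + repeat_len :]


def _is_as_planted(seq: str, repeat_len: int, mode: str, params: _circ.CircularityParams) -> bool:
    call = _circ.detect_circularity(ViralContig(id="tmp", sequence=seq), params)
    dtr = _circ.longest_terminal_dtr(seq)
    if mode == "direct_terminal":
        if repeat_len >= params.min_dtr_len:
            return call.is_circular and call.mechanism == "DTR" and call.repeat_length == repeat_len
        # sub-threshold plant: terminal match must be exactly as planted and
        # nothing else in the sequence may trigger a circular call
        return not call.is_circular and dtr == repeat_len
    expected = {"direct_windowed": "direct_internal", "inverted": "inverted"}[mode]
    return (
        call.is_circular
        and call.mechanism == expected
        and call.repeat_length == repeat_len
        and dtr < params.min_dtr_len
    )


def make_circular_genome(
    seed: int,
    length: int,
    repeat_len: int,
    mode: str = "direct_terminal",
    params: Optional[_circ.CircularityParams] = None,
) -> ViralContig:
    """Random backbone with a planted terminal repeat.

    ``mode`` is one of ``direct_terminal`` (DTR; ``repeat_len`` 0 gives a
    verified non-circular backbone), ``direct_windowed`` or ``inverted``.
    A rejection loop regenerates the backbone until the planted repeat is
    the only qualifying signal at exactly its requested length, so boundary
    scans over ``repeat_len`` are free of incidental repeats.
    """
    if mode not in ("direct_terminal", "direct_windowed", "inverted"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or _circ.CircularityParams()
    if repeat_len >= length / 2:
        raise ValueError("repeat_len must be shorter than half the sequence")
    if mode != "direct_terminal" and repeat_len < params.min_terminal_repeat_len:
        raise ValueError(
            f"{mode} plants need repeat_len >= {params.min_terminal_repeat_len} bp"
        )
    for attempt in range(_MAX_ATTEMPTS):
        rng = substream(seed, f"circular:{mode}:{length}:{repeat_len}", attempt)
        seq = _plant(random_sequence(length, rng), repeat_len, mode, rng)
        if _is_as_planted(seq, repeat_len, mode, params):
            return ViralContig(id=f"{mode}_{seed}_{repeat_len}", sequence=seq)
    raise RuntimeError(
        f"could not generate a clean {mode} fixture (seed={seed}, length={length}, "
        f"repeat_len={repeat_len}) in {_MAX_ATTEMPTS} attempts"
    )


def mutate_to_identity(seq: str, target_identity_pct: float, seed: int) -> str:
    """Substitute exactly round((1 - target/100) * len) positions, each to a
    different base, at seeded positions drawn without replacement."""
    if not (0 < target_identity_pct <= 100):
        raise ValueError("target identity must lie in (0, 100]")
    n_sub = round((1 - target_identity_pct / 100.0) * len(seq))
    if n_sub == 0:
        return seq
    rng = substream(seed, "mutate")
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(out)


def make_vpf_hit_table(spec: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Reference hit table with exact per-domain counts per model.

    ``spec`` maps model id -> {domain: count}; the result has one row per
    hit (columns model_id, host_domain) in deterministic order.
    """
    rows = []
    for model_id in sorted(spec):
        for domain in sorted(spec[model_id]):
            rows.extend(
                {"model_id": model_id, "host_domain": domain}
                for _ in range(spec[model_id][domain])
            )
    return pd.DataFrame(rows, columns=["model_id", "host_domain"])


def make_spacer_set(
    contigs: Sequence[ViralContig],
    n: int,
    len_range: tuple[int, int] = (25, 65),
    mismatches: int = 0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Draw ``n`` spacer-like substrings from the contigs, optionally
    mutated with exactly ``mismatches`` substitutions each."""
    rng = substream(seed, "spacers")
    spacers: list[tuple[str, str]] = []
    for i in range(n):
        contig = contigs[int(rng.integers(0, len(contigs)))]
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        if contig.length < length:
            raise ValueError(f"contig {contig.id!r} shorter than spacer length {length}")
        start = int(rng.integers(0, contig.length - length + 1))
        seq = contig.sequence[start : start + length]
        if mismatches:
            positions = rng.choice(length, size=mismatches, replace=False)
            chars = list(seq)
            for pos in positions:
                alternatives = [b for b in "ACGT" if b != chars[pos]]
                chars[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
            seq = "".join(chars)
        spacers.append((f"sp{i}_{contig.id}", seq))
    return spacers


def make_fixture_bundle(outdir: str | Path, seed: int = 1) -> dict[str, Path]:
    """Write a complete, internally consistent input set for the full
    pipeline and return a name -> path mapping.

    Contents: a FASTA mixing an isolate reference, circular contigs on both
    sides of the false-positive rules, linear fragments, and a three-member
    ~97%-identity family; matching marker hits, genus-group memberships,
    taxon reference lengths, protein-family hit tables, host labels and
    spacers drawn from one contig.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = substream(seed, "bundle")

    iso1 = ViralContig("iso1", random_sequence(12000, rng), source_class="isolate")
    c_big = make_circular_genome(seed, 12000, 15, "direct_terminal")
    c_big = ViralContig("circ_big", c_big.sequence)  # >=10 kb: survives FP filter
    c_ssdna = make_circular_genome(seed + 1, 5000, 12, "direct_terminal")
    c_ssdna = ViralContig("circ_ssdna", c_ssdna.sequence)  # <10 kb but ssDNA-affiliated
    c_fp = make_circular_genome(seed + 2, 6000, 11, "direct_terminal")
    c_fp = ViralContig("circ_fp", c_fp.sequence)  # <10 kb, unaffiliated: FP
    lin_hq = ViralContig("lin_hq", random_sequence(11000, rng))  # 11/12 kb -> 91.7%
    lin_frag = ViralContig("lin_frag", random_sequence(6000, rng))  # 6/12 kb -> 50%
    fam_root = random_sequence(3000, rng)
    fam1 = ViralContig("fam1", fam_root)
    fam2 = ViralContig("fam2", mutate_to_identity(fam_root, 97, seed + 10))
    fam3 = ViralContig("fam3", mutate_to_identity(fam_root, 97, seed + 11))
    contigs = [iso1, c_big, c_ssdna, c_fp, lin_hq, lin_frag, fam1, fam2, fam3]

    paths = {name: outdir / fname for name, fname in [
        ("fasta", "contigs.fa"),
        ("hits", "marker_hits.tsv"),
        ("groups", "groups.tsv"),
        ("ref_lengths", "ref_lengths.tsv"),
        ("vpf_hits", "vpf_reference_hits.tsv"),
        ("contig_vpf_hits", "contig_vpf_hits.tsv"),
        ("hosts", "hosts.tsv"),
        ("spacers", "spacers.fa"),
    ]}
    write_fasta(contigs, paths["fasta"])

    pd.DataFrame(
        [
            ("lin_hq", "vog_a1", "Teeviridae", "dsDNA"),
            ("lin_hq", "vog_a2", "Teeviridae", "dsDNA"),
            ("circ_ssdna", "vog_m1", "Microviridae", "ssDNA"),
        ],
        columns=["contig_id", "model_id", "taxon", "taxon_class"],
    ).to_csv(paths["hits"], sep="\t", index=False)

    pd.DataFrame(
        [
            ("iso1", "g1", "isolate_reference"),
            ("circ_big", "g1", "circular"),
            ("lin_hq", "g1", "linear"),
            ("lin_frag", "g1", "linear"),
        ],
        columns=["seq_id", "group_id", "member_class"],
    ).to_csv(paths["groups"], sep="\t", index=False)

    pd.DataFrame(
        [("Teeviridae", 12000.0), ("Microviridae", 5000.0)],
        columns=["taxon", "mean_genome_length"],
    ).to_csv(paths["ref_lengths"], sep="\t", index=False)

    make_vpf_hit_table(
        {
            "vpf_prok": {"prokaryotic": 7},
            "vpf_euk": {"eukaryotic": 10},
            "vpf_mixed": {"prokaryotic": 3, "eukaryotic": 3},
        }
    ).to_csv(paths["vpf_hits"], sep="\t", index=False)

    pd.DataFrame(
        [
            ("circ_big", "vpf_prok"),
            ("circ_big", "vpf_prok"),
            ("fam1", "vpf_euk"),
            ("lin_hq", "vpf_mixed"),
        ],
        columns=["contig_id", "model_id"],
    ).to_csv(paths["contig_vpf_hits"], sep="\t", index=False)

    pd.DataFrame(
        [
            ("iso1", "Bacteria;Firmicutes;Bacilli", "isolate"),
            ("fam1", "Bacteria;Proteobacteria;Gammaproteobacteria", "prophage"),
        ],
        columns=["seq_id", "host_lineage", "source"],
    ).to_csv(paths["hosts"], sep="\t", index=False)

    spacer_contigs = [c_big]
    spacers = make_spacer_set(spacer_contigs, n=3, mismatches=0, seed=seed)
    with open(paths["spacers"], "w") as fh:
        for spacer_id, seq in spacers:
            fh.write(f">{spacer_id}\n{seq}\n")
    # host lineages for the spacers' source arrays
    spacer_hosts = pd.DataFrame(
        [(sid, "Archaea;Euryarchaeota;Methanomicrobia", "spacer") for sid, _ in spacers],
        columns=["seq_id", "host_lineage", "source"],
    )
    spacer_hosts.to_csv(outdir / "spacer_hosts.tsv", sep="\t", index=False)
    paths["spacer_hosts"] = outdir / "spacer_hosts.tsv"
    return paths
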