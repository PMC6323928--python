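# uvigkit

A curation toolkit for **uncultivated viral genomes (UViGs)** assembled from
metagenomes. Large viral catalogs mix everything from short genome fragments
to complete circular genomes; `uvigkit` implements the standard desk
curation steps used to organize such catalogs, for bioinformaticians who
need them as a reusable, tested library and CLI rather than one-off scripts:

* **Circularity detection** — a putative complete genome is called from a
  direct terminal repeat (DTR) of ≥ 10 bp anchored at the contig termini,
  or from a direct/inverted repeat of ≥ 20 bp whose copies lie within 50 bp
  of the two ends.
* **vOTU clustering** — species-rank viral OTUs are the connected
  components (single linkage) of the relation *ANI ≥ 95% over ≥ 85% of the
  shorter sequence*; multi-member clusters are named `vc_<k>`, singletons
  `sg_<k>`.
* **Completeness & quality tiers** — contigs are affiliated to taxa by
  marker genes (≥ 2 consistent markers; ≥ 5 for NCLDV; 1 for ssDNA/RNA
  viruses) or to genus-level groups; a group predicts a genome size when
  the SD of its complete members' lengths is ≤ 15% of the mean. Spurious
  circular calls are filtered (shorter than 80% of the group's minimum
  isolate; or < 10 kb without ssDNA/RNA affiliation). Completeness =
  100·L/size (capped at 99% when L exceeds the expected size), and contigs
  are tiered *finished* / *complete circular* / *high-quality draft*
  (≥ 90%) / *genome fragment*.
* **Host-domain scoring** — each viral protein family (VPF) is scored
  `score = (#uniform hits / #total hits)`, shrunk by
  `(#total hits / average #hits)` when below the database-wide average
  (6.8); families scoring exactly 1.0 are prokaryotic/eukaryotic
  signatures used to classify contigs by majority vote.
* **Specific host assignment** — host lineages propagate from labeled
  isolates/prophages to their vOTU co-members (lowest common ancestor on
  conflict), and 25–65 bp CRISPR spacers are matched against contigs
  (full length, ≤ 1 substitution, both strands).

All inputs are plain text (FASTA and tab-delimited tables); deterministic
synthetic-data generators (`uvigkit.fixtures`) emulate every input so the
whole pipeline is testable offline.

## Worked example

```bash
uvigkit make-fixtures --outdir fixtures --seed 1
uvigkit run-all \
    --fasta fixtures/contigs.fa \
    --hits fixtures/marker_hits.tsv \
    --groups fixtures/groups.tsv \
    --ref-lengths fixtures/ref_lengths.tsv \
    --vpf-hits fixtures/vpf_reference_hits.tsv \
    --contig-vpf-hits fixtures/contig_vpf_hits.tsv \
    --hosts fixtures/hosts.tsv \
    --spacers fixtures/spacers.fa \
    --spacer-hosts fixtures/spacer_hosts.tsv \
    --out-report report.tsv
```

Selected rows of `report.tsv` (13 tab-delimited columns):

```
contig_id   length  circular  ...  completeness_pct  quality_tier        host_domain  host_prediction                               host_method
circ_big    12000   true      ...  NA                complete_circular   prokaryotic  Archaea;Euryarchaeota;Methanomicrobia         crispr_spacer
circ_fp     6000    true      ...  NA                genome_fragment     unclassified NA                                            NA
lin_hq      11000   false     ...  91.7              high_quality_draft  unclassified NA                                            NA
lin_frag    6000    false     ...  50.0              genome_fragment     unclassified NA                                            NA
fam2        3000    false     ...  NA                genome_fragment     unclassified Bacteria;Proteobacteria;Gammaproteobacteria   cluster
```

Reading these rows: `circ_big` carries a planted DTR and is ≥ 10 kb, so it
is tiered a likely complete genome and linked to an archaeal host through
an exact CRISPR spacer match; `circ_fp` is also circular but, at 6 kb with
no ssDNA/RNA marker, is flagged a false positive and demoted to a genome
fragment; `lin_hq` is 11 kb against a 12 kb predicted group size (91.7% ≥
90% → high-quality draft) while `lin_frag` reaches only 50%; `fam2` has no
host evidence of its own but inherits its lineage from a labeled prophage
in the same `vc_1` cluster.

The same stages are available as `detect-circular`, `cluster`,
`completeness`, `domain-score` and `host-predict` subcommands, and as
library functions (`uvigkit.detect_circularity`, `uvigkit.pairwise_ani`,
`uvigkit.build_votus`, ...).

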