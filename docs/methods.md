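# Methods

This note documents the models and procedures implemented in `uvigkit`,
their assumptions, the parameters that matter, and the design choices made
where the underlying conventions are genuinely open.

## Circularity from terminal repeats

An assembler that closes a circular genome reproduces the sequence start at
the contig end, leaving a direct terminal repeat (DTR). Some complete
linear genomes instead carry long terminal repeats, direct or inverted.
Three rules are applied in order, and the first satisfied rule fixes the
reported mechanism:

1. **DTR** — longest exact match between a prefix anchored at base 0 and a
   suffix ending at the last base; circular if ≥ `min_dtr_len` (10 bp).
2. **Windowed direct repeat** — exact repeat of ≥ `min_terminal_repeat_len`
   (20 bp) with the 5′ copy *starting* within `terminal_window` (50 bp) of
   the 5′ end and the 3′ copy *ending* within 50 bp of the 3′ end.
3. **Windowed inverted repeat** — as rule 2 with the 3′ copy reverse
   complemented.

Choices that the thresholds alone do not determine, made here and tested
against a quadratic brute-force scanner:

* matches are **exact**; no mismatch allowance. Exactness makes the oracle
  unambiguous and errs on the conservative side.
* `N` never matches anything, including another `N`.
* window anchoring is start-anchored at the 5′ end and end-anchored at the
  3′ end (the convention "within 50 bp of the ends" does not specify which
  coordinate of the copy must fall in the window).
* rule 1 requires the repeat to be strictly terminal (position 0 to last
  base); near-terminal direct repeats are rule 2's job.
* a DTR longer than half the contig is not considered (cap at L/2).
* DTR takes precedence on ties: it is the conventional signal of a
  complete circular genome.
* contigs ≤ 2 × window (100 bp) are refused with a warning: the two
  windows would overlap.

The detector anchors seed words from the 5′ window and extends maximal
exact runs, which is exactly equivalent to the quadratic scan (property
tested over hundreds of random sequences with planted repeats of every
mechanism).

## ANI, aligned fraction, and vOTU clustering

Species-rank viral OTUs use the community thresholds: **ANI ≥ 95% over
≥ 85% of the shorter sequence**, single linkage. The ANI engine is a local
aligner (Biopython's `PairwiseAligner`; match +1, mismatch −1, gap open −2,
gap extend −1, N scored as mismatch against everything) wrapped in a greedy
block collector: the best local alignment is taken, its query span masked,
and the query realigned until the block score drops below 30. ANI is
matched columns over aligned columns (gap columns included), length-
weighted across blocks; AF is the union of query bases covered by any
block over the query length. Both query strands are tried; the higher
total score wins. The shorter sequence is always the query (ties broken
lexicographically), so the result is symmetric by construction.

Numerical behavior worth knowing: local alignment trims mismatch-dense
termini, so on substitution ladders the measured ANI sits a few tenths of
a point above the planted identity (e.g. ≈ 80.3 at a planted 80%); the
identity-recovery tests hold to ±1 point across 80–100%, and the cluster
merge threshold verifiably falls between the 94% and 96% rungs.

Clustering builds the threshold graph and takes connected components
(networkx); the test suite checks this against a hand-rolled union-find
over independently computed edges. A canonical 16-mer prefilter (≥ 5 shared
k-mers) skips alignments for pairs that cannot be related at ≥ 95%
identity; a test asserts the prefilter never changes the clustering.
Cluster naming (`vc_`/`sg_`, ordered by descending size then smallest
member id) is a determinism convention; only the prefixes carry meaning.

## Completeness and quality tiers

Expected genome sizes come from two sources, tried in this order:

1. **marker affiliation** — a contig affiliates to the taxon with the most
   consistent marker genes, subject to per-class minimums (dsDNA genera: 2,
   NCLDV: 5, ssDNA/RNA families: 1). "Consistent" means agreeing on the
   same taxon label; the majority label wins and ties yield no affiliation.
   The taxon's mean isolate genome length is read from a reference table.
2. **genus-level group** — mean length of the group's isolates and
   non-false-positive circular members, accepted only when the population
   SD (divide by n — the members *are* the population under consideration)
   is ≤ 15% of the mean. A single member yields SD 0 and a defined size.

False-positive circular filtering precedes size prediction: a circular
contig is spurious when shorter than 80% of the group's minimum isolate
length, shorter than 80% of the maximum linear member in an isolate-free
group, or < 10 kb without an ssDNA/RNA affiliation (too small for a dsDNA
genome). Flagged contigs are reclassified as linear, against the *original*
group composition so the outcome does not depend on flagging order.

Completeness is 100·L/size, capped at 99% for over-length linear contigs
(near-complete, never complete); the cap is applied uniformly whether the
size came from a marker taxon or a group. Comparisons (the 90% tier
boundary) use unrounded values; reports round to one decimal. Tiers:
isolates → `finished`; surviving circulars → `complete_circular` (kept
distinct from `finished` because isolate genomes and predicted-complete
contigs are different evidence classes); linear ≥ 90% →
`high_quality_draft`; otherwise `genome_fragment`.

## VPF host-domain scoring

`score = (#uniform hits / #total hits)`, multiplied by
`(#total hits / average #hits)` when the family has fewer hits than the
database-wide average per model (default 6.8, a property of the reference
database and therefore a supplied parameter; `recompute_average_hits`
derives it from a hit table instead). "#uniform hits" is ambiguous for
split profiles; the default reads it as the dominant domain's count (a
fully uniform profile scores 1 before correction, an even split scores
0.5), with the stricter reading (uniform = total only when a single domain
is hit, else 0) behind `mode="strict"`. Consequences that the tests pin
down: any uniform profile with ≥ ⌈6.8⌉ = 7 hits scores exactly 1.0, and
the score is monotone in the dominant count at fixed total. Signature
selection uses score ≥ 1 − 1e−9 to absorb float error. Contig
classification is a strict majority vote over signature-family hits; ties
and empty votes are `unclassified`.

## Host assignment

Cluster propagation gives every unlabeled member of a vOTU containing
labeled members (isolates and curated prophages are treated identically)
the **lowest common ancestor** of the known lineages — the LCA is the
conflict-resolution rule chosen here; existing labels are never
overwritten, and labels for unknown ids are skipped with a warning.

Spacer matching is full-spacer-length, substitutions only (no indels),
≤ 1 mismatch by default, both strands, with `N` counting as a mismatch;
spacers outside 25–65 bp (the biological length range of CRISPR spacers)
are skipped. When a contig has both propagation and spacer evidence the
propagated lineage is reported and the method tag records both
(`cluster+crispr_spacer`); the two evidence types are not merged into a
consensus because they have different error modes.

## Synthetic data

The generators fabricate uniform-composition A/C/G/T backbones (no Ns by
default; N behavior has dedicated edge-case tests) with planted features:
terminal repeats of each mechanism, identity ladders with an exact
substitution count, hit tables with exact per-domain counts, and spacers
excised from contigs with an exact mismatch count. A rejection loop
guarantees a planted repeat is the only qualifying signal at exactly its
requested length, so boundary scans (e.g. 5–15 bp DTR plants) are clean.
One top-level seed derives named substreams, and identical inputs produce
byte-identical files.

What the fixtures do **not** emulate: real gene content, codon bias,
repeat-rich or low-complexity regions, indel divergence between related
genomes, and chimeric assemblies. Passing tests therefore demonstrate the
correctness of the decision rules and their boundaries, not the field
error rates of circularity or host prediction on real metagenomes.

## Problem sizes and tolerances

Test and verification runs use desk-scale inputs chosen to exercise every
rule: 0.3–5 kb sequences for oracle-equivalence suites (hundreds of cases),
1 kb ladders at 1-point identity steps over 80–100% with three seeds, and
a 9-contig end-to-end bundle covering all tiers and both host-assignment
routes. Identity recovery is asserted to ±1 percentage point; all boundary
values (10 bp, 90%, 99%, 10 kb, score 1.0) are asserted exactly.

## Known limitations

* ANI block collection is greedy; heavily rearranged pairs may have their
  aligned fraction slightly underestimated compared with an optimal
  chaining of all local alignments.
* All-vs-all clustering is quadratic in the number of sequences; the
  k-mer prefilter removes most unrelated alignments but catalog-scale
  inputs (10⁵+) would need a sketching front end.
* Spacer matching is exhaustive per contig × spacer; fine at desk scale,
  but an index (e.g. Aho–Corasick) would be needed for millions of spacers.
* Marker-based affiliation trusts the input hit table; no HMM searching is
  performed here.
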