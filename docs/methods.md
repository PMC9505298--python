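# Methods

This note documents the models, conventions and parameter choices behind
`pasite`: what the pipeline computes, what the synthetic-data generator
emulates (and does not), and where the design was genuinely open.

## Coordinate convention: the cleavage base

All positions are 0-based internally (BED output half-open, GFF3 read as
1-based closed). Position 0 of every profile — "the cleavage site" — is
the **poly(A) attachment base**: the genomic base one step 3' (in
transcription direction) of the last aligned base of the tail-trimmed
sense read. Operationally: `reference_end` of a forward alignment,
`reference_start − 1` of a reverse one.

Why this and not the last aligned base itself: cleavage in animals
occurs preferentially at a CA dinucleotide, so the genomic base at the
cleavage position is usually an A. A maximal-run tail trimmer
necessarily absorbs that templated A into the apparent tail, so the last
*aligned* base can never be an A — yet the empirical hallmark of CS
profiles is precisely a sharp A peak (> 60%) at position 0 with C/G
enrichment at −1. Anchoring position 0 one base past the alignment makes
the A peak measurable, keeps the generator's truth coordinates exactly
recoverable, and leaves every downstream definition consistent.

The internal-priming window is anchored accordingly at relative
positions 0..9 (the 10 genomic sense bases *starting at* the cleavage
base). This is the identical absolute genomic window as "the 10 bp
downstream of the last aligned base", so the two published filter rules
behave exactly as stated: an 8-A priming run beginning at the attachment
base is caught by the run rule, and ≥ 9 A in the window by the count
rule. Both rules apply by default (`--ip-mode either`); each can be
toggled because the two thresholds are independent statements, not one
rule.

## Stage conventions

* **Tail calling** (`tails`): the tail is the maximal *exact* terminal
  homopolymer (A at 3', T at 5'); N terminates a run; called only at
  ≥ `min_tail` (default 10 nt). If both ends qualify the longer run
  wins, ties go to the 3' A end (the orientation prior of oligo(dT)
  libraries). 5'-T reads are reverse complemented so all downstream work
  is in sense orientation. No mismatches are tolerated inside the run —
  the strictest reading; a looser tail model would be a parameter, not a
  different algorithm.
* **Alignment**: real data should be mapped by a dedicated aligner and
  supplied as SAM/BAM; only primary, non-supplementary records at
  mapping quality ≥ 1 (uniquely mapped) with an unclipped 3' end are
  used. The bundled `align` module is an exact-match, ungapped,
  unique-placement k-mer aligner sufficient for the generator's
  error-free contiguous reads; it is not a general mapper.
* **Clustering** (`sites`): single linkage with `merge_distance` 20 —
  adjacent distinct positions ≤ 20 bp apart chain transitively (the
  alternative, fixed-span windows, is not what "separated by ≤ 20 bp
  were merged" describes). Representative = member with maximal read
  support; ties resolve 5'-most (smallest coordinate on +, largest
  on −). Evidence sources (EST vs long-read) are clustered separately
  and their cluster counts added, mirroring how per-source site counts
  are reported; `--merge-sources` pools them instead.
* **PAS assignment** (`profiling`): hexamers are searched wholly within
  the 40 nt upstream (5' base in −40..−6). Priority is the fixed
  canonical-first order (AAUAAA, AUUAAA, …, AAAAAG); among several
  occurrences of the winning hexamer the one closest to the modal PAS
  region is reported (largest offset ≤ −11, else nearest −11).
  Positional scan tables use −50..−1 by default; scanning and assignment
  windows are configured independently because they answer different
  questions (distribution shape vs per-site call).
* **Signal/noise classification**: a hexamer's positional distribution
  is "signal" when its maximal count inside −40..−10, divided by the
  median count over the scan range + 1, reaches `--peak-ratio`
  (default 5.0) and the global argmax lies inside −40..−10. This is an
  operationalization of the qualitative peak-vs-scattered criterion; the
  ratio is exposed because 5.0 is a judgement call. Flat distributions
  (UUUUUU) score ≈ 1.
* **χ² tests**: per position and nucleotide, 1-df goodness of fit on the
  two-cell split (is-nucleotide vs not) against the GC-content
  background, P(G)=P(C)=gc/2, P(A)=P(U)=(1−gc)/2 (gc default 0.364). No
  multiple-testing correction is applied in the headline output — the
  804 per-position tests are descriptive — but a Bonferroni column is
  emitted for transparency.
* **Feature assignment** (`annotate`): strand-matched, by cluster
  representative (`span` assignment would straddle junctions). "Exon"
  means CDS-bearing exon sequence so that {3'UTR, 5'UTR, exon, intron,
  intergenic} partitions. Precedence at multiply-annotated positions:
  3'UTR > 5'UTR > exon > intron. Overlapping same-strand genes: the gene
  whose 3'UTR contains the site wins, else the nearest 3' end, ties by
  gene id. APA types: single; tandem 3'UTR (all sites in the 3'UTR);
  5'UTR/CDS/intronic APA when the distal site is in the 3'UTR and an
  upstream site sits in that feature (5'-most deviation names the type
  when several co-occur); otherwise mixed.

## The synthetic-data generator

`simulate.SimConfig` defaults *are* the study conditions; they are set
once, from the biology, not per test:

| parameter | default | why |
|---|---|---|
| `gc_content` | 0.364 | host genome composition |
| `hexamer_usage` | AAUAAA 51.64% … none 10.13% (normalized) | the empirical usage vector of the organism |
| `pas_offset_range` | −30..−11 | the modal PAS placement window |
| `dse_window`, `dse_u_fraction` | +3..+27, 0.45 | downstream U enrichment rises to ~45% against a 31.8% background |
| `sites_per_gene_dist` | {1: 0.2959, 2: 0.30, 3: 0.17, 4: 0.10, 5: 0.06, >5: 0.0741} | 70.41% of genes multi-site, declining tail |
| `extra_site_feature_mix` | 3'UTR 0.66, intron 0.24, exon 0.072, 5'UTR 0.028 | with the forced 3'UTR distal site this yields ~79% 3'UTR / ~15% intron genic placement |
| `cs_jitter_sd` | 2 nt | per-read cleavage heterogeneity |
| `reads_per_site` | 20 | scaled down from the data's ~200× per-site depth; enough for the modal position to dominate |
| `tail_len_dist` | uniform 15–45 nt | full-length-read tail scale; ≥ 10 so every read passes the tail rule |
| `decoy_fraction` | 0.05 | internal-priming contamination share |
| `error_rate` | 0 | tails are written clean so the ≥ 10-nt rule is exercised at its boundary by the length distribution, not by noise |

Construction details that matter for interpretation:

* The cleavage base is written as A with a non-A (C-biased) base at −1,
  emulating the CA cleavage dinucleotide. `tail_len_dist` parameterizes
  the **observed** terminal run: the appended untemplated As plus the
  absorbed templated A(s), so a constant-10 configuration produces reads
  with exactly 10 terminal As.
* Accidental occurrences of any of the 14 PAS hexamers near the upstream
  search window (5' base in cs−45..cs−4) are scrubbed — not only for
  "none"-class sites. At this AT-rich composition an accidental
  canonical hexamer appears in a few percent of windows; without
  scrubbing those would upgrade calls and planted-vs-recovered usage
  comparisons would be biased, not just noisy. Replacement bases are
  verified not to create another PAS hexamer.
* The 10-base window at each *true* site is kept below the
  internal-priming thresholds (excess As flipped to C): a real study's
  retained site set survives that filter by construction, and this makes
  filter false-positive behaviour a measured quantity (via decoys)
  rather than a confound on recall.
* Decoy reads are sampled at genomic A-runs ≥ 8 nt (T-runs for the −
  strand) and labelled in the read-level truth table, so filter
  sensitivity/specificity is measurable; the published procedure states
  the filter but not its error rates.
* Reads are genomically contiguous (the evidence reads' 3' ends
  overwhelmingly lie within the terminal exon), half are emitted reverse
  complemented, and FASTQ qualities are constant.

What the generator does **not** emulate — so what passing tests do not
show: sequencing indels/chimeras, quality-score structure, spliced
reads, expression-level variation between genes beyond `reads_per_site`,
overlapping genes, alternative transcript structures, and mismatch-
containing tails. Recovery rates on this benchmark are therefore upper
bounds for real data; the per-stage contracts (filter rules, clustering,
assignment priority) transfer exactly.

## Numerical and testing choices

* Determinism: every stage is a pure function of configuration + inputs;
  the generator derives independent substreams from one seed; identical
  configurations give byte-identical FASTA/GFF3/FASTQ/TSV outputs.
* Degenerate inputs: empty event sets cluster to an empty list; a
  truncated downstream window at a contig edge is evaluated as-is; χ²
  at n = 0 returns an undefined-result marker rather than raising;
  per-chromosome ratios with zero genes are flagged undefined.
* Edge-masked flank positions are excluded from every denominator.
* Problem sizes: the acceptance-scale benchmark plants ~20,000 sites in
  7,600 genes on a 19.2-Mb genome (≈ 420k reads); unit suites use
  50–1,900 genes. These sizes make binomial standard errors small
  relative to the recovery tolerances while completing in about a
  minute each.
* Tolerances: planted-vs-recovered class frequencies are compared at 3
  binomial standard errors per class. Where many classes are compared
  simultaneously in a *generator sampling* check (15 usage classes), a
  multinomial χ² goodness-of-fit at α = 1e-3 is used instead, since 15
  simultaneous 3-SE bands mis-state the family-wise error.

## Known limitations

* The exact-match aligner cannot place reads once `error_rate` > 0; for
  noisy synthetic reads, map externally and enter at `callsites`.
* A read whose random 5' genomic context starts with a T-run longer than
  its whole poly(A) tail would be mis-oriented; with the default tail
  lengths this is a < 1e-7 per-read event.
* `load_annotation` flattens multiple transcripts per gene into merged
  per-gene intervals; transcript-level APA (isoform quantification) is
  out of scope.
* The 200-bp-suffix alignment variant (aligning only the sequence
  immediately upstream of the tail rather than the full trimmed read) is
  noted as a configuration alternative but not implemented; the full
  trimmed read is aligned.
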