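# pasite

Poly(A)-site discovery and polyadenylation-signal (PAS) usage analysis
from poly(A)-tailed 3'-end sequence evidence — EST and full-length
transcriptome reads — with a complete synthetic benchmark for the fall
armyworm *Spodoptera frugiperda* setting (AT-rich genome, GC 36.4%).

## The problem

When a pre-mRNA is cleaved and polyadenylated, reads that retain part of
the untemplated poly(A) tail pinpoint the cleavage site (CS): trim the
terminal A (or leading T) homopolymer of at least 10 nt, map the trimmed
read uniquely to the genome, and the tail-attachment base is the CS.
Three complications make this a pipeline rather than a one-liner:

* **Internal priming.** Oligo(dT) also primes on genomic A-runs,
  producing fake "tails". An apparent CS is discarded when the 10
  genomic bases starting at it contain ≥ 9 A on the sense strand, or a
  run of ≥ 8 consecutive A.
* **Cleavage heterogeneity.** The cleavage reaction wobbles by a few
  bases, so per-read cleavage events ≤ 20 bp apart are merged
  (single-linkage) into one pA cluster; the best-supported position
  represents the cluster.
* **Signal identification.** The PAS is a hexamer — canonically AAUAAA,
  with 13 recognized single-nucleotide variants — located roughly 10–35
  nt upstream of the CS; a U/GU-rich downstream sequence element (DSE)
  sits at about +3..+27. The pipeline profiles positional nucleotide and
  hexamer frequencies around each CS, assigns the PAS per site
  (canonical-first priority within the 40 nt upstream), tabulates usage
  percentages, and tests per-position composition against the genome
  background with 1-df χ² goodness-of-fit tests
  (GC 36.4% ⇒ expected G/C 18.2%, A/U 31.8% each):

  χ² = (x − ne)²/(ne) + ((n−x) − n(1−e))²/(n(1−e)).

Genes with ≥ 2 pA clusters are candidates for alternative
polyadenylation (APA); the cluster placement within gene models (3'UTR /
5'UTR / CDS exon / intron) classifies each gene's APA type (tandem
3'UTR, intronic, CDS, 5'UTR, mixed).

Real data enters as genome FASTA + GFF3 + SAM/BAM of tail-trimmed reads.
Because the original read sets are enormous, the package ships a
first-class generator (`pasite.simulate`) that plants sites, hexamers,
DSEs and internal-priming decoys with known truth tables, so every stage
is tested end-to-end against ground truth.

## Worked example

The numbered scripts under `analysis/` walk the full study on synthetic
data (~4,900 planted sites, 100k reads; about 30 s total):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_prep_reads.py
python analysis/03_call_sites.py
python analysis/04_profile_signals.py
python analysis/05_annotate_apa.py
python analysis/06_validate_recovery.py
```

Output of steps 3–6 (seed 1):

```
pA clusters: 4,882 (single-position 0.0%, two 0.8%, >=3 99.2%)
PAS usage (%):
  AAUAAA    52.64
  AUUAAA    11.49
  ...
  Other     10.63
AAUAAA: signal (peak -28, score 14.6)
UUUUUU: noise (peak -37, score 2.8)
A frequency at position 0: 94.6%
mean U in +3..+27: 44.9% (background 31.8%, far window 31.6%)
feature placement of genic pA sites:
  three_prime_utr  78.19%
  intron           15.34%
genes with >=2 sites (APA): 69.53%
recall_within_20: 1.0000
pas_accuracy: 1.0000
decoy_removal_rate: 1.0000
```

Reading this: the 4,882 planted sites are all recovered within the 20-bp
merge distance; the recovered PAS usage (52.6% AAUAAA, 10.6% with no
canonical hexamer) matches the planted usage vector; AAUAAA shows a
sharp positional peak inside the −30..−11 window while UUUUUU is flat
(noise); the cleavage base is overwhelmingly A; downstream U is elevated
exactly in the DSE window; and every internal-priming decoy read was
removed by the filter.

The same pipeline runs as one command, or stage by stage, via the CLI:

```sh
pasite run-all --config run.cfg --seed 1 --out myrun
pasite callsites --alignments reads.bam --genome genome.fa   # real data entry
pasite validate --run-dir myrun
```

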