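"""Placing pA clusters onto gene models: feature-category assignment,
per-gene site counts and APA typing, and per-chromosome summaries.

Category semantics: "exon" means CDS-bearing exon sequence; the UTRs are
reported as their own categories so that {3'UTR, 5'UTR, exon, intron,
intergenic} partitions every cluster.  Assignment is strand-matched (a +
cluster is never assigned to a - gene) and decided by the cluster's
representative position.  When a position carries several annotations
across transcripts the precedence is 3'UTR > 5'UTR > exon > intron.

A gene with two or more assigned clusters is potentially regulated by
alternative polyadenylation (APA).  APA types follow the classic
patterns: tandem 3'UTR (all sites in the 3'UTR, protein unchanged),
5'UTR / CDS / intronic APA (an upstream site in that feature with the
distal site in the 3'UTR, truncating or abolishing the protein), and
mixed for anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .sites import PolyACluster

__all__ = ["GeneModel", "FeatureAssignment", "APASummary", "FeatureIndex",
           "load_annotation", "assign_feature", "assign_features",
           "summarize_gene_apa", "classify_apa_type", "chromosome_summary"]

_CATEGORY_PRECEDENCE = ("three_prime_utr", "five_prime_utr", "exon", "intron")
_COUNT_CLASSES = ("1", "2", "3", "4", "5", ">5")


@dataclass
class GeneModel:
    """Gene with per-transcript structure; intervals 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def three_prime_end(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex, ex[1:])]

    def category_at(self, pos: int) -> str | None:
        """Feature category at a genomic position inside the gene span."""
        if not self.start <= pos < self.end:
            return None
        for cat, ivs in (("three_prime_utr", self.utr3),
                         ("five_prime_utr", self.utr5),
                         ("exon", self.cds)):
            if any(a <= pos < b for a, b in ivs):
                return cat
        if any(a <= pos < b for a, b in self.exons):
            # exonic but neither UTR nor CDS (e.g. CDS-less transcript)
            return "exon"
        return "intron"


@dataclass
class FeatureAssignment:
    cluster_id: str
    gene_id: str | None
    category: str              # three_prime_utr|five_prime_utr|exon|intron|intergenic
    position: int = -1
    strand: str = "."


@dataclass
class APASummary:
    gene_id: str
    n_sites: int
    count_class: str
    is_apa: bool
    apa_type: str


def load_annotation(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 into gene models (gffutils, in-memory database).

    UTRs missing from the file are inferred as exon-minus-CDS on the
    appropriate sides when CDS features are present."""
    import gffutils

    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    try:
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                keep_order=False, merge_strategy="create_unique",
                                disable_infer_genes=True,
                                disable_infer_transcripts=True)
    except Exception as exc:  # gffutils raises assorted parse errors
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        model = GeneModel(g.id, g.seqid, g.strand, g.start - 1, g.end)
        has_utr = False
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            for f in db.children(t):
                iv = (f.start - 1, f.end)
                if f.featuretype == "exon":
                    model.exons.append(iv)
                elif f.featuretype == "CDS":
                    model.cds.append(iv)
                elif f.featuretype == "five_prime_UTR":
                    has_utr = True
                    model.utr5.append(iv)
                elif f.featuretype == "three_prime_UTR":
                    has_utr = True
                    model.utr3.append(iv)
        model.exons = _merge(model.exons)
        model.cds = _merge(model.cds)
        model.utr5 = _merge(model.utr5)
        model.utr3 = _merge(model.utr3)
        if not has_utr and model.cds:
            _infer_utrs(model)
        genes.append(model)
    genes.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return genes


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def _infer_utrs(model: GeneModel) -> None:
    """UTR = exon minus CDS, split by side of the CDS span."""
    cds_lo = min(a for a, _ in model.cds)
    cds_hi = max(b for _, b in model.cds)
    left, right = [], []
    for a, b in model.exons:
        if a < cds_lo:
            left.append((a, min(b, cds_lo)))
        if b > cds_hi:
            right.append((max(a, cds_hi), b))
    if model.strand == "+":
        model.utr5, model.utr3 = left, right
    else:
        model.utr5, model.utr3 = right, left


class FeatureIndex:
    """Strand-aware interval index of gene spans for position lookup."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            key = (g.chrom, g.strand)
            self._trees.setdefault(key, IntervalTree())
            if g.end > g.start:
                self._trees[key][g.start:g.end] = g

    def overlapping(self, chrom: str, strand: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]), key=lambda g: g.gene_id)


def assign_feature(cluster: PolyACluster, index: FeatureIndex) -> FeatureAssignment:
    """Assign one cluster to a gene and feature category by its
    representative position.  Overlapping same-strand genes: prefer the
    gene whose 3'UTR contains the site, else the gene with the closest 3'
    end (ties by gene_id)."""
    pos = cluster.representative_position
    hits = index.overlapping(cluster.chrom, cluster.strand, pos)
    if not hits:
        return FeatureAssignment(cluster.cluster_id, None, "intergenic",
                                 pos, cluster.strand)
    if len(hits) > 1:
        in_utr3 = [g for g in hits if g.category_at(pos) == "three_prime_utr"]
        if in_utr3:
            hits = in_utr3
        hits.sort(key=lambda g: (abs(pos - g.three_prime_end), g.gene_id))
    gene = hits[0]
    return FeatureAssignment(cluster.cluster_id, gene.gene_id,
                             gene.category_at(pos) or "intron",
                             pos, cluster.strand)


def assign_features(clusters: Iterable[PolyACluster], index: FeatureIndex
                    ) -> list[FeatureAssignment]:
    return [assign_feature(c, index) for c in clusters]


def classify_apa_type(site_records: Sequence[tuple[int, str]], strand: str) -> str:
    """APA type from a gene's (position, category) site list; invariant to
    listing order.

    single: one site.  tandem_3utr: all sites in the 3'UTR.  five_utr_apa /
    cds_apa / intronic_apa: the distal site is in the 3'UTR and at least
    one upstream site sits in that feature (when several co-occur, the
    5'-most class of deviation names the type).  mixed: anything else."""
    if len(site_records) == 1:
        return "single"
    cats = [c for _, c in site_records]
    if all(c == "three_prime_utr" for c in cats):
        return "tandem_3utr"
    distal = max(site_records, key=lambda r: r[0] if strand == "+" else -r[0])
    if distal[1] == "three_prime_utr":
        for cat, name in (("five_prime_utr", "five_utr_apa"),
                          ("exon", "cds_apa"),
                          ("intron", "intronic_apa")):
            if cat in cats:
                return name
    return "mixed"


def summarize_gene_apa(assignments: Sequence[FeatureAssignment]
                       ) -> tuple[list[APASummary], dict]:
    """Per-gene site counts, count class and APA type, plus aggregate
    fractions over genes carrying at least one site."""
    per_gene: dict[str, list[FeatureAssignment]] = {}
    for a in assignments:
        if a.gene_id is not None:
            per_gene.setdefault(a.gene_id, []).append(a)

    summaries: list[APASummary] = []
    for gene_id in sorted(per_gene):
        recs = per_gene[gene_id]
        n = len({a.cluster_id for a in recs})
        cls = str(n) if n <= 5 else ">5"
        apa_type = classify_apa_type([(a.position, a.category) for a in recs],
                                     recs[0].strand)
        summaries.append(APASummary(gene_id, n, cls, n >= 2, apa_type))

    n_genes = len(summaries)
    aggregate = {
        "n_genes_with_sites": n_genes,
        "class_fractions": {
            c: (sum(s.count_class == c for s in summaries) / n_genes
                if n_genes else 0.0)
            for c in _COUNT_CLASSES},
        "fraction_apa": (sum(s.is_apa for s in summaries) / n_genes
                         if n_genes else 0.0),
        "type_counts": {},
    }
    for s in summaries:
        aggregate["type_counts"][s.apa_type] = \
            aggregate["type_counts"].get(s.apa_type, 0) + 1
    return summaries, aggregate


def category_fractions(assignments: Sequence[FeatureAssignment],
                       genic_only: bool = True) -> dict[str, float]:
    """Fraction of clusters per feature category (over genic clusters by
    default, mirroring how placement is usually reported)."""
    pool = [a for a in assignments if a.gene_id is not None] if genic_only \
        else list(assignments)
    n = len(pool)
    cats = _CATEGORY_PRECEDENCE if genic_only else _CATEGORY_PRECEDENCE + ("intergenic",)
    return {c: (sum(a.category == c for a in pool) / n if n else 0.0) for c in cats}


def chromosome_summary(clusters: Sequence[PolyACluster],
                       genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-chromosome gene and pA-site counts and their ratio (NaN where a
    chromosome has clusters but no annotated genes), with a genome-wide
    total row appended."""
    gene_counts: dict[str, int] = {}
    for g in genes:
        gene_counts[g.chrom] = gene_counts.get(g.chrom, 0) + 1
    site_counts: dict[str, int] = {}
    for c in clusters:
        site_counts[c.chrom] = site_counts.get(c.chrom, 0) + 1
    chroms = sorted(set(gene_counts) | set(site_counts))
    rows = []
    for ch in chroms:
        ng = gene_counts.get(ch, 0)
        ns = site_counts.get(ch, 0)
        rows.append((ch, ng, ns, ns / ng if ng else np.nan))
    rows.append(("TOTAL", sum(gene_counts.values()), sum(site_counts.values()),
                 (sum(site_counts.values()) / sum(gene_counts.values())
                  if gene_counts else np.nan)))
    return pd.DataFrame(rows, columns=["chrom", "n_genes", "n_sites", "ratio"])
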