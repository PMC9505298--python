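"""Synthetic genome / annotation / poly(A)-evidence read generator.

The generator emulates the statistical structure that the downstream
pipeline assumes about real 3'-end evidence:

* an i.i.d. background genome at a configurable GC content (default 36.4%,
  the *Spodoptera frugiperda* genome composition),
* strand-assigned, non-overlapping gene models with exon/intron/UTR
  structure, written as GFF3,
* per-gene poly(A) sites (the distal one always in the 3'UTR, earlier ones
  spread over 3'UTR/intron/CDS-exon/5'UTR per a configurable mix), each
  carrying a PAS hexamer drawn from a configurable usage distribution and
  written into the sense strand 11-30 nt upstream of the cleavage base,
* a U(T-on-sense)-rich downstream sequence element,
* reads that end in a genuine poly(A) tail (half emitted reverse
  complemented, i.e. starting with poly(T)), with per-read cleavage
  jitter, and
* internal-priming decoy reads whose apparent tails arise at genomic
  A-runs (>= 8 nt), the artifact the internal-priming filter removes.

Every planted site and read is recorded in tab-separated truth tables so
recovery can be measured exactly.  All outputs are byte-deterministic
given the same :class:`SimConfig`.

Coordinate convention: the cleavage position is the poly(A) attachment
base (position 0 of all profiles), i.e. the genomic base one step 3' of
the last tail-trimmed aligned base.  It is planted as an A, which the
tail trimmer necessarily absorbs into the observed tail; ``tail_len_dist``
therefore parameterizes the *observed* terminal run length.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .dna import PAS_HEXAMERS_DNA, PAS_HEXAMERS_RNA, revcomp, to_dna

__all__ = [
    "SimConfig",
    "SimGene",
    "TruthSite",
    "TruthRead",
    "SimResult",
    "SimSizingError",
    "default_hexamer_usage",
    "simulate_genome",
    "plant_pa_sites",
    "simulate_reads",
    "simulate_all",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 65, 67, 71, 84


class SimSizingError(ValueError):
    """Raised when the requested gene models do not fit the genome budget."""


def default_hexamer_usage() -> dict[str, float]:
    """PAS hexamer usage vector: the empirical frequencies reported for
    *S. frugiperda* (AAUAAA 51.64% ... none 10.13%), normalized to sum to 1."""
    pct = {
        "AAUAAA": 51.64, "AUUAAA": 12.15, "UAUAAA": 4.38, "AGUAAA": 4.17,
        "AAGAAA": 2.63, "AAUAUA": 2.42, "AAUACA": 2.32, "CAUAAA": 2.00,
        "GAUAAA": 2.01, "AAUGAA": 1.64, "UUUAAA": 1.25, "ACUAAA": 1.19,
        "AAUAGA": 1.05, "AAAAAG": 1.03, "none": 10.13,
    }
    total = sum(pct.values())
    return {k: v / total for k, v in pct.items()}


def default_sites_per_gene_dist() -> dict[str, float]:
    """Sites-per-gene class probabilities {1,2,3,4,5,>5}.  Chosen so that
    70.41% of genes carry two or more sites, with a declining tail."""
    return {"1": 0.2959, "2": 0.30, "3": 0.17, "4": 0.10, "5": 0.06, ">5": 0.0741}


def default_feature_mix() -> dict[str, float]:
    """Feature-category mix for the non-distal sites of multi-site genes.
    Together with the forced 3'UTR distal site this reproduces the genic
    placement fractions of the study (~79% 3'UTR, ~15% intron)."""
    return {"three_prime_utr": 0.66, "intron": 0.24, "exon": 0.072,
            "five_prime_utr": 0.028}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions the
    downstream analysis assumes (see docs/methods.md)."""

    seed: int = 0
    gc_content: float = 0.364
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (90, 250)
    utr5_len: tuple[int, int] = (120, 250)
    utr3_len: tuple[int, int] = (300, 600)
    sites_per_gene_dist: Mapping[str, float] = field(default_factory=default_sites_per_gene_dist)
    hexamer_usage: Mapping[str, float] = field(default_factory=default_hexamer_usage)
    pas_offset_range: tuple[int, int] = (-30, -11)
    dse_window: tuple[int, int] = (3, 27)
    dse_u_fraction: float = 0.45
    cs_jitter_sd: float = 2.0
    tail_len_dist: tuple[int, int] = (15, 45)
    reads_per_site: int = 20
    decoy_fraction: float = 0.05
    error_rate: float = 0.0
    read_len: tuple[int, int] = (120, 200)
    extra_site_feature_mix: Mapping[str, float] = field(default_factory=default_feature_mix)
    min_site_separation: int = 80

    def validate(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0,1)")
        for name, vec in (("sites_per_gene_dist", self.sites_per_gene_dist),
                          ("hexamer_usage", self.hexamer_usage),
                          ("extra_site_feature_mix", self.extra_site_feature_mix)):
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 +- 1e-9")
        lo, hi = self.pas_offset_range
        if not (lo <= hi <= -6):
            raise ValueError("pas_offset_range must lie strictly upstream of the "
                             "cleavage site with room for a full hexamer (5' base <= -6)")
        if self.tail_len_dist[0] < 10:
            raise ValueError("tail_len_dist support must be >= 10 nt")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise ValueError("decoy_fraction must lie in [0,1)")
        unknown = set(self.hexamer_usage) - set(PAS_HEXAMERS_RNA) - {"none"}
        if unknown:
            raise ValueError(f"unknown hexamer classes in usage vector: {sorted(unknown)}")


@dataclass
class SimGene:
    """A simulated gene model; all intervals are 0-based half-open genomic."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex, ex[1:])]


@dataclass
class TruthSite:
    site_id: str
    gene_id: str
    chrom: str
    strand: str
    cleavage_position: int
    planted_hexamer: str      # RNA alphabet, or "none"
    hexamer_offset: int | None
    feature_category: str


@dataclass
class TruthRead:
    read_id: str
    site_id: str              # "" for decoys
    is_decoy: bool
    chrom: str
    strand: str
    true_end: int             # genomic coordinate of the last templated base
    expected_event: int       # cleavage base the pipeline should recover
    tail_length: int          # observed terminal homopolymer run


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, np.ndarray]
    genes: list[SimGene]
    sites: list[TruthSite]
    reads_truth: list[TruthRead]
    genome_fasta: Path | None = None
    annotation_gff3: Path | None = None
    reads_fastq: Path | None = None
    sites_tsv: Path | None = None
    reads_tsv: Path | None = None
    config_txt: Path | None = None
    genome_md5: str | None = None

    def genome_str(self) -> dict[str, str]:
        return {c: a.tobytes().decode("ascii") for c, a in self.genome.items()}


# ---------------------------------------------------------------------------
# strand-aware sequence access ("sense" = transcript orientation; +1 = one
# base downstream, i.e. 3', of the anchor in transcription direction)

def _sense_slice(arr: np.ndarray, strand: str, anchor: int, rel_lo: int, rel_hi: int) -> str:
    """Sense-strand sequence at relative positions [rel_lo, rel_hi] inclusive."""
    if strand == "+":
        g0, g1 = anchor + rel_lo, anchor + rel_hi
        g0c, g1c = max(g0, 0), min(g1, len(arr) - 1)
        if g0c > g1c:
            return ""
        return arr[g0c:g1c + 1].tobytes().decode("ascii")
    g0, g1 = anchor - rel_hi, anchor - rel_lo
    g0c, g1c = max(g0, 0), min(g1, len(arr) - 1)
    if g0c > g1c:
        return ""
    return revcomp(arr[g0c:g1c + 1].tobytes().decode("ascii"))


def _write_sense(arr: np.ndarray, strand: str, anchor: int, rel: int, seq: str) -> None:
    """Write ``seq`` onto the sense strand with its first base at relative
    position ``rel``."""
    if strand == "+":
        g0 = anchor + rel
        arr[g0:g0 + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)
    else:
        g1 = anchor - rel           # genomic coord of seq[0]
        g0 = g1 - len(seq) + 1
        arr[g0:g1 + 1] = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)


# ---------------------------------------------------------------------------
# genome + gene models

def simulate_genome(config: SimConfig) -> tuple[dict[str, np.ndarray], list[SimGene]]:
    """Random background genome plus non-overlapping gene models.

    Base composition is i.i.d. with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2;
    gene models only define structure at this stage (no sequence elements
    are written until :func:`plant_pa_sites`)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    gc = config.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = {
        f"chr{i + 1}": rng.choice(_BASES, size=config.chrom_length, p=p)
        for i in range(config.n_chromosomes)
    }

    genes: list[SimGene] = []
    chrom_names = list(genome)
    ci = 0
    cursor = 500
    for gi in range(config.n_genes):
        layout = _draw_gene_layout(config, rng)
        span = layout["span"]
        gap = int(rng.integers(400, 1200))
        while ci < len(chrom_names) and cursor + span + 500 > config.chrom_length:
            ci += 1
            cursor = 500
        if ci >= len(chrom_names):
            raise SimSizingError(
                f"gene models do not fit: gene {gi + 1}/{config.n_genes} needs "
                f"{span} bp but the {config.n_chromosomes} x {config.chrom_length} bp "
                f"genome budget is exhausted")
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_materialize_gene(f"gene{gi + 1:05d}", chrom_names[ci],
                                       strand, cursor, layout))
        cursor += span + gap
    return genome, genes


def _draw_gene_layout(config: SimConfig, rng: np.random.Generator) -> dict:
    """Draw a transcript layout (local + orientation), including the
    feature categories of the sites the gene will later receive."""
    k_class = _draw_class(config.sites_per_gene_dist, rng)
    k = int(rng.integers(6, 9)) if k_class == ">5" else int(k_class)
    cats = ["three_prime_utr"]
    mix = config.extra_site_feature_mix
    keys, probs = list(mix), np.fromiter(mix.values(), float)
    for _ in range(k - 1):
        cats.append(keys[rng.choice(len(keys), p=probs)])

    n3 = cats.count("three_prime_utr")
    n_int = cats.count("intron")
    n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    n_ex = max(n_ex, n_int + 1, 1)
    utr5 = int(rng.integers(*_incl(config.utr5_len)))
    utr3 = max(int(rng.integers(*_incl(config.utr3_len))),
               70 + 95 * n3)
    cds_chunks = [int(rng.integers(*_incl(config.exon_len))) for _ in range(n_ex)]
    cds_chunks[-1] += (3 - sum(cds_chunks) % 3) % 3
    introns = [int(rng.integers(*_incl(config.intron_len))) for _ in range(n_ex - 1)]

    # local coordinates, + orientation: [5'UTR][cds1] i1 [cds2] ... [cdsN][3'UTR]
    exons, cds, pos = [], [], 0
    for i, chunk in enumerate(cds_chunks):
        ex_start = pos
        if i == 0:
            pos += utr5
        cds.append((pos, pos + chunk))
        pos += chunk
        if i == n_ex - 1:
            pos += utr3
        exons.append((ex_start, pos))
        if i < n_ex - 1:
            pos += introns[i]
    return {
        "span": pos,
        "exons": exons,
        "cds": cds,
        "utr5": [(0, utr5)],
        "utr3": [(pos - utr3, pos)],
        "site_categories": cats,
    }


def _materialize_gene(gene_id: str, chrom: str, strand: str, start: int,
                      layout: dict) -> SimGene:
    span = layout["span"]

    def place(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        if strand == "+":
            return [(start + a, start + b) for a, b in ivs]
        return sorted((start + span - b, start + span - a) for a, b in ivs)

    gene = SimGene(gene_id, chrom, strand, start, start + span,
                   exons=place(layout["exons"]), cds=place(layout["cds"]),
                   utr5=place(layout["utr5"]), utr3=place(layout["utr3"]))
    gene.site_categories = list(layout["site_categories"])  # type: ignore[attr-defined]
    return gene


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def _draw_class(dist: Mapping[str, float], rng: np.random.Generator) -> str:
    keys = list(dist)
    probs = np.fromiter(dist.values(), float)
    return keys[rng.choice(len(keys), p=probs)]


# ---------------------------------------------------------------------------
# site planting

_SCRUB_START_LO, _SCRUB_START_HI = -45, -4   # hexamer 5'-base range scrubbed


def plant_pa_sites(genes: list[SimGene], genome: dict[str, np.ndarray],
                   config: SimConfig) -> list[TruthSite]:
    """Plant per-gene cleavage sites and their sequence elements into the
    genome (edited in place); returns the site truth table.

    For every site: the cleavage base (relative position 0) is written as
    A with a non-A base at -1; the drawn PAS hexamer (unless "none") is
    written at a uniform offset in ``pas_offset_range``; the downstream
    window is rewritten U(T)-rich; accidental occurrences of any of the 14
    PAS hexamers near the upstream search window are scrubbed so that the
    planted class is recoverable; and the 10-base window the
    internal-priming filter inspects is kept below its thresholds (real
    retained sites survive that filter by construction)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    hex_keys = list(config.hexamer_usage)
    hex_probs = np.fromiter(config.hexamer_usage.values(), float)
    sites: list[TruthSite] = []
    sid = 0
    for gene in genes:
        cats: list[str] = getattr(gene, "site_categories", ["three_prime_utr"])
        placed: list[int] = []
        arr = genome[gene.chrom]
        for cat in cats:
            placement = _place_site(gene, cat, placed, config, rng)
            if placement is None:
                warnings.warn(f"could not place a {cat} site in {gene.gene_id}; skipped")
                continue
            pos, cat = placement
            placed.append(pos)
            sid += 1
            hexamer = hex_keys[rng.choice(len(hex_keys), p=hex_probs)]
            offset = None
            if hexamer != "none":
                offset = int(rng.integers(config.pas_offset_range[0],
                                          config.pas_offset_range[1] + 1))
            _plant_elements(arr, gene.strand, pos, hexamer, offset, config, rng)
            sites.append(TruthSite(f"site{sid:06d}", gene.gene_id, gene.chrom,
                                   gene.strand, pos, hexamer, offset, cat))
    return sites


def _category_intervals(gene: SimGene, cat: str) -> list[tuple[int, int]]:
    if cat == "three_prime_utr":
        return gene.utr3
    if cat == "five_prime_utr":
        return gene.utr5
    if cat == "exon":
        return gene.cds
    return gene.introns


def _place_site(gene: SimGene, cat: str, placed: list[int],
                config: SimConfig, rng: np.random.Generator,
                margin: int = 30) -> tuple[int, str] | None:
    """Pick a cleavage position inside a feature of the requested category,
    keeping ``min_site_separation`` from already-placed sites.  Falls back
    to the 3'UTR when the category cannot host the site; the *actual*
    category is returned alongside the position."""
    sep = config.min_site_separation
    for attempt_cat in (cat, "three_prime_utr"):
        ivs = [(a + margin, b - margin) for a, b in _category_intervals(gene, attempt_cat)
               if b - a > 2 * margin + 1]
        if not ivs:
            continue
        lens = np.array([b - a for a, b in ivs], float)
        for _ in range(40):
            a, b = ivs[rng.choice(len(ivs), p=lens / lens.sum())]
            pos = int(rng.integers(a, b))
            if all(abs(pos - q) >= sep for q in placed):
                return pos, attempt_cat
    return None


def _plant_elements(arr: np.ndarray, strand: str, cs: int, hexamer: str,
                    offset: int | None, config: SimConfig,
                    rng: np.random.Generator) -> None:
    # cleavage base and its 5' neighbour (CA-like dinucleotide bias)
    _write_sense(arr, strand, cs, 0, "A")
    _write_sense(arr, strand, cs, -1, str(rng.choice(["C", "G", "T"], p=[0.4, 0.35, 0.25])))

    protected = {-1, 0}
    if hexamer != "none":
        dna = to_dna(hexamer)
        _write_sense(arr, strand, cs, offset, dna)
        protected.update(range(offset, offset + 6))

    # downstream U/GU-rich element (T on the sense strand)
    lo, hi = config.dse_window
    gc = config.gc_content
    rest = np.array([(1 - gc) / 2, gc / 2, gc / 2])
    rest /= rest.sum()
    dse = "".join(
        "T" if rng.random() < config.dse_u_fraction
        else str(rng.choice(["A", "C", "G"], p=rest))
        for _ in range(hi - lo + 1))
    _write_sense(arr, strand, cs, lo, dse)

    _scrub_accidental_hexamers(arr, strand, cs, protected, rng)
    _enforce_filter_safe_window(arr, strand, cs, config)


def _scrub_accidental_hexamers(arr: np.ndarray, strand: str, cs: int,
                               protected: set[int], rng: np.random.Generator,
                               max_iter: int = 60) -> None:
    """Mutate away any PAS-hexamer occurrence with 5' base in the scrub
    range other than the planted one, so the recovered call equals the
    planted class even when the recovered representative wobbles by a
    couple of bases."""
    planted_span = frozenset(p for p in protected if p not in (-1, 0))
    for _ in range(max_iter):
        window = _sense_slice(arr, strand, cs, _SCRUB_START_LO, _SCRUB_START_HI + 5)
        hit = None
        for dna in PAS_HEXAMERS_DNA:
            idx = window.find(dna)
            while idx != -1:
                rel = _SCRUB_START_LO + idx
                if set(range(rel, rel + 6)) != planted_span:
                    hit = rel
                    break
                idx = window.find(dna, idx + 1)
            if hit is not None:
                break
        if hit is None:
            return
        mutable = [p for p in range(hit, hit + 6) if p not in protected]
        if not mutable:  # fully shadowed by the planted span; geometrically rare
            return
        if not _mutate_clean(arr, strand, cs, mutable):
            break
    warnings.warn("hexamer scrub did not converge; residual accidental motif left")


def _mutate_clean(arr: np.ndarray, strand: str, cs: int,
                  candidates: list[int]) -> bool:
    """Substitute one of ``candidates`` (relative positions) with a base
    that leaves no PAS-hexamer occurrence spanning it; e.g. turning AATAGA
    into AATACA would merely swap one signal for another, so replacements
    are verified on the local neighbourhood before being written."""
    for pos in sorted(candidates, key=lambda p: (abs(p - candidates[len(candidates) // 2]), p)):
        hood = _sense_slice(arr, strand, cs, pos - 5, pos + 5)
        old = _sense_slice(arr, strand, cs, pos, pos)
        for base in "CGTA":
            if base == old:
                continue
            trial = hood[:5] + base + hood[6:]
            spanning = {trial[s:s + 6] for s in range(6) if len(trial[s:s + 6]) == 6}
            if not spanning & set(PAS_HEXAMERS_DNA):
                _write_sense(arr, strand, cs, pos, base)
                return True
    return False


def _enforce_filter_safe_window(arr: np.ndarray, strand: str, cs: int,
                                config: SimConfig) -> None:
    """Keep the 10-base window starting at the cleavage base below the
    internal-priming thresholds (< 9 A total, no 8-A run)."""
    from .dna import max_run
    for _ in range(10):
        w = _sense_slice(arr, strand, cs, 0, 9)
        if w.count("A") < 9 and max_run(w, "A") < 8:
            return
        # flip the middle A of the longest run, never the cleavage base itself
        best_len = best_start = cur = 0
        start = 1
        for i, c in enumerate(w):
            if i == 0:
                continue
            if c == "A":
                if cur == 0:
                    start = i
                cur += 1
                if cur > best_len:
                    best_len, best_start = cur, start
            else:
                cur = 0
        if best_len == 0:
            return
        _write_sense(arr, strand, cs, best_start + best_len // 2, "C")


# ---------------------------------------------------------------------------
# reads

def find_a_runs(genome: dict[str, np.ndarray], min_run: int = 8
                ) -> list[tuple[str, str, int, int]]:
    """Genomic homopolymer runs that can internally prime: A-runs on the +
    sense and T-runs (A on the - sense).  Returns (chrom, sense_strand,
    run_start_genomic, run_len)."""
    runs = []
    for chrom, arr in genome.items():
        for strand, base in (("+", _A), ("-", _T)):
            mask = (arr == base).astype(np.int8)
            diff = np.diff(np.concatenate(([0], mask, [0])))
            starts = np.flatnonzero(diff == 1)
            lens = np.flatnonzero(diff == -1) - starts
            keep = lens >= min_run
            runs.extend((chrom, strand, int(s), int(l))
                        for s, l in zip(starts[keep], lens[keep]))
    return runs


def simulate_reads(sites: list[TruthSite], genome: dict[str, np.ndarray],
                   config: SimConfig) -> tuple[list[tuple[str, str]], list[TruthRead]]:
    """Generate poly(A)-tailed reads (plus internal-priming decoys) for the
    planted sites.  Returns ``[(read_id, read_sequence), ...]`` (sequences
    as sequenced: half of them reverse complemented, i.e. 5' poly(T)) and
    the read-level truth table."""
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    reads: list[tuple[str, str]] = []
    truth: list[TruthRead] = []
    rid = 0

    def emit(chrom: str, strand: str, e_gen: int, site_id: str, is_decoy: bool) -> None:
        nonlocal rid
        arr = genome[chrom]
        length = int(rng.integers(*_incl(config.read_len)))
        tail = int(rng.integers(*_incl(config.tail_len_dist)))
        templ = _sense_slice(arr, strand, e_gen, -(length - 1), 0)
        if not templ:
            return
        r = _trailing_a(templ)
        if r >= len(templ):
            return
        appended = max(tail - r, 0)
        observed_tail = r + appended
        seq = templ + "A" * appended
        if config.error_rate > 0:
            seq = _apply_errors(seq, len(seq) - observed_tail, config.error_rate, rng)
        flipped = rng.random() < 0.5
        if flipped:
            seq = revcomp(seq)
        rid += 1
        read_id = f"read{rid:07d}"
        reads.append((read_id, seq))
        step = 1 if strand == "+" else -1
        expected_event = e_gen - step * r + step  # first base of the observed tail
        truth.append(TruthRead(read_id, site_id, is_decoy, chrom, strand,
                               e_gen, expected_event, observed_tail))

    for site in sites:
        step = 1 if site.strand == "+" else -1
        for _ in range(config.reads_per_site):
            jitter = (int(np.rint(rng.normal(0.0, config.cs_jitter_sd)))
                      if config.cs_jitter_sd > 0 else 0)
            emit(site.chrom, site.strand,
                 site.cleavage_position + step * jitter, site.site_id, False)

    if config.decoy_fraction > 0:
        runs = [x for x in find_a_runs(genome, min_run=8)
                if _decoy_has_room(x, genome, config)]
        if not runs:
            warnings.warn("no genomic A-run >= 8 nt available; decoy reads skipped")
        else:
            n_normal = len(reads)
            total = int(round(n_normal / (1.0 - config.decoy_fraction)))
            n_decoys = int(rng.binomial(total, config.decoy_fraction))
            for _ in range(n_decoys):
                chrom, strand, s, rlen = runs[rng.integers(len(runs))]
                e_gen = s + rlen - 1 if strand == "+" else s
                emit(chrom, strand, e_gen, "", True)
    return reads, truth


def _decoy_has_room(run: tuple[str, str, int, int], genome: dict[str, np.ndarray],
                    config: SimConfig) -> bool:
    chrom, strand, s, rlen = run
    n = len(genome[chrom])
    need = config.read_len[1] + 5
    if strand == "+":
        return s + rlen - 1 - need >= 0
    return s + need < n


def _trailing_a(seq: str) -> int:
    n = 0
    for c in reversed(seq):
        if c != "A":
            break
        n += 1
    return n


def _apply_errors(seq: str, templ_len: int, rate: float,
                  rng: np.random.Generator) -> str:
    """Substitution errors outside the observed tail.  The base adjacent to
    the tail is never mutated to A (that would silently lengthen the tail)."""
    hits = np.flatnonzero(rng.random(templ_len) < rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        if i == templ_len - 1:
            choices = [b for b in choices if b != "A"]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: dict[str, np.ndarray], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, arr in genome.items():
            fh.write(f">{chrom}\n")
            s = arr.tobytes().decode("ascii")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_gff3(genes: list[SimGene], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            tid = f"{g.gene_id}.t1"
            fh.write(_gff_line(g.chrom, "gene", g.start, g.end, g.strand,
                               ".", f"ID={g.gene_id}"))
            fh.write(_gff_line(g.chrom, "mRNA", g.start, g.end, g.strand,
                               ".", f"ID={tid};Parent={g.gene_id}"))
            for a, b in sorted(g.exons):
                fh.write(_gff_line(g.chrom, "exon", a, b, g.strand, ".", f"Parent={tid}"))
            cds = sorted(g.cds, reverse=(g.strand == "-"))
            cum = 0
            for a, b in cds:
                phase = (3 - cum % 3) % 3
                fh.write(_gff_line(g.chrom, "CDS", a, b, g.strand, str(phase),
                                   f"Parent={tid}"))
                cum += b - a
            for a, b in sorted(g.utr5):
                fh.write(_gff_line(g.chrom, "five_prime_UTR", a, b, g.strand, ".",
                                   f"Parent={tid}"))
            for a, b in sorted(g.utr3):
                fh.write(_gff_line(g.chrom, "three_prime_UTR", a, b, g.strand, ".",
                                   f"Parent={tid}"))


def _gff_line(chrom: str, ftype: str, start0: int, end0: int, strand: str,
              phase: str, attrs: str) -> str:
    return f"{chrom}\tpasite_sim\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t{phase}\t{attrs}\n"


def write_fastq(reads: Iterable[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_sites(sites: list[TruthSite], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tgene_id\tchrom\tstrand\tcleavage_position\t"
                 "planted_hexamer\thexamer_offset\tfeature_category\n")
        for s in sites:
            off = "" if s.hexamer_offset is None else str(s.hexamer_offset)
            fh.write(f"{s.site_id}\t{s.gene_id}\t{s.chrom}\t{s.strand}\t"
                     f"{s.cleavage_position}\t{s.planted_hexamer}\t{off}\t"
                     f"{s.feature_category}\n")


def write_truth_reads(truth: list[TruthRead], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsite_id\tis_decoy\tchrom\tstrand\ttrue_end\t"
                 "expected_event\ttail_length\n")
        for r in truth:
            fh.write(f"{r.read_id}\t{r.site_id or '.'}\t{int(r.is_decoy)}\t"
                     f"{r.chrom}\t{r.strand}\t{r.true_end}\t{r.expected_event}\t"
                     f"{r.tail_length}\n")


def read_truth_sites(path: str | Path) -> list[TruthSite]:
    sites = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            (site_id, gene_id, chrom, strand, pos, hexamer, off, cat) = \
                line.rstrip("\n").split("\t")
            sites.append(TruthSite(site_id, gene_id, chrom, strand, int(pos),
                                   hexamer, int(off) if off else None, cat))
    return sites


def read_truth_reads(path: str | Path) -> list[TruthRead]:
    reads = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            (read_id, site_id, is_decoy, chrom, strand, true_end,
             expected_event, tail_length) = line.rstrip("\n").split("\t")
            reads.append(TruthRead(read_id, "" if site_id == "." else site_id,
                                   bool(int(is_decoy)), chrom, strand,
                                   int(true_end), int(expected_event),
                                   int(tail_length)))
    return reads


def write_config(config: SimConfig, path: Path, extra: Mapping[str, str] = ()) -> None:
    with open(path, "w") as fh:
        for key, value in asdict(config).items():
            if isinstance(value, Mapping):
                value = ",".join(f"{k}:{v}" for k, v in value.items())
            elif isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key} = {value}\n")
        for key, value in dict(extra).items():
            fh.write(f"{key} = {value}\n")


def simulate_all(config: SimConfig, outdir: str | Path) -> SimResult:
    """Run the full generator and write FASTA/GFF3/FASTQ/truth outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_genome(config)
    sites = plant_pa_sites(genes, genome, config)
    reads, truth = simulate_reads(sites, genome, config)

    res = SimResult(config, genome, genes, sites, truth)
    res.genome_fasta = outdir / "genome.fa"
    res.annotation_gff3 = outdir / "annotation.gff3"
    res.reads_fastq = outdir / "reads.fastq"
    res.sites_tsv = outdir / "sites_truth.tsv"
    res.reads_tsv = outdir / "reads_truth.tsv"
    res.config_txt = outdir / "sim_config.txt"

    write_fasta(genome, res.genome_fasta)
    write_gff3(genes, res.annotation_gff3)
    write_fastq(reads, res.reads_fastq)
    write_truth_sites(sites, res.sites_tsv)
    write_truth_reads(truth, res.reads_tsv)
    res.genome_md5 = hashlib.md5(res.genome_fasta.read_bytes()).hexdigest()
    write_config(config, res.config_txt, extra={"genome_md5": res.genome_md5})
    return res
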