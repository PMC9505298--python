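"""End-to-end orchestration: simulate -> tail prep -> align -> call/filter/
cluster -> signal profiling -> APA annotation, plus validation of a
synthetic run against its truth tables.

Every stage is a pure function of its inputs and the run configuration;
re-running with the same configuration and seed reproduces every output
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotate as ann
from . import profiling as prof
from . import report as rep
from . import sites as st
from . import tails
from .align import align_to_sam
from .dna import PAS_HEXAMERS_RNA
from .simulate import SimConfig, SimResult, simulate_all

logger = logging.getLogger("pasite")

__all__ = ["RunConfig", "RunResult", "run_all", "validate_against_truth",
            "load_run_config"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    In synthetic mode the generator produces genome/annotation/reads; in
    real mode ``genome``/``annotation``/``alignments`` (SAM/BAM of
    tail-trimmed sense reads) or ``reads`` must be provided."""

    out_dir: str = "pasite_run"
    mode: str = "synthetic"            # "synthetic" | "real"
    sim: SimConfig = field(default_factory=SimConfig)
    genome: str | None = None
    annotation: str | None = None
    reads: str | None = None
    alignments: str | None = None
    source_tag: str = "long-read"
    min_tail: int = 10
    min_mapq: int = 1
    merge_distance: int = 20
    merge_sources: bool = False
    ip_window: int = 10
    ip_min_at: int = 9
    ip_min_run: int = 8
    ip_mode: str = "either"
    halfwidth: int = 100
    scan_range: tuple[int, int] = (-50, -1)
    pas_window: int = 40
    gc: float | None = None            # None -> synthetic config value / 0.364
    peak_ratio: float = 5.0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            missing = [n for n in ("genome", "annotation") if getattr(self, n) is None]
            if not (self.reads or self.alignments):
                missing.append("reads or alignments")
            if missing:
                raise ValueError(f"real mode requires: {', '.join(missing)}")
            for name in ("genome", "annotation", "reads", "alignments"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name} path does not exist: {p}")
        self.filter_config()  # raises on bad filter parameters
        self.sim.validate()

    def filter_config(self) -> st.FilterConfig:
        return st.FilterConfig(self.ip_window, self.ip_min_at,
                               self.ip_min_run, self.ip_mode)

    @property
    def background_gc(self) -> float:
        if self.gc is not None:
            return self.gc
        return self.sim.gc_content if self.mode == "synthetic" else 0.364


@dataclass
class RunResult:
    config: RunConfig
    out_dir: Path
    sim: SimResult | None
    counters: dict
    site_stats: st.SiteStats
    clusters: list[st.PolyACluster]
    usage: pd.DataFrame
    mono_profile: prof.ProfileMatrix
    di_profile: prof.ProfileMatrix
    hexamer_table: prof.HexamerPositionTable
    signal_calls: dict[str, prof.HexamerSignal]
    pas_calls: list[prof.PASCall]
    dse: dict
    assignments: list[ann.FeatureAssignment]
    apa_summaries: list[ann.APASummary]
    apa_aggregate: dict
    category_fractions: dict[str, float]
    chrom_summary: pd.DataFrame
    genome_md5: str


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage in order, writing all intermediates under
    ``config.out_dir``; any stage failure aborts with the stage name."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ------------------------------------------------------ simulate
        sim: SimResult | None = None
        if config.mode == "synthetic":
            stage = "simulate"
            t0 = time.perf_counter()
            sim = simulate_all(config.sim, out / "sim")
            genome = sim.genome_str()
            genome_fa = sim.genome_fasta
            annotation = sim.annotation_gff3
            reads_path = sim.reads_fastq
            logger.info("simulate: %d genes, %d sites, %.1fs", len(sim.genes),
                        len(sim.sites), time.perf_counter() - t0)
        else:
            genome = st.load_genome(config.genome)
            genome_fa = Path(config.genome)
            annotation = Path(config.annotation)
            reads_path = Path(config.reads) if config.reads else None
        genome_md5 = hashlib.md5(Path(genome_fa).read_bytes()).hexdigest()

        # ---------------------------------------------------------- prep
        counters: dict[str, dict[str, int]] = {}
        sam_path = Path(config.alignments) if config.alignments else None
        if reads_path is not None:
            stage = "prep"
            t0 = time.perf_counter()
            calls, stats = tails.prepare_batch(
                tails.read_sequences(reads_path, config.source_tag),
                config.min_tail)
            tails.write_tail_report(calls, out / "tail_report.tsv")
            tails.write_trimmed_fastq(calls, out / "trimmed.fastq")
            for src, s in stats.items():
                counters.setdefault("raw_reads", {})[src] = s.raw_count
                counters.setdefault("tailed_reads", {})[src] = s.tailed_count
            logger.info("prep: %s, %.1fs", {k: (v.raw_count, v.tailed_count)
                                            for k, v in stats.items()},
                        time.perf_counter() - t0)

            # ----------------------------------------------------- align
            if sam_path is None:
                stage = "align"
                t0 = time.perf_counter()
                sam_path = out / "aligned.sam"
                sense_reads = ((c.read_id, c.sense_sequence) for c in calls
                               if c.tail_end != "none" and c.sense_sequence)
                aln_counts = align_to_sam(genome, sense_reads, sam_path)
                counters.setdefault("mapped_reads", {})[config.source_tag] = \
                    aln_counts["mapped"]
                logger.info("align: %s, %.1fs", aln_counts, time.perf_counter() - t0)

        # ------------------------------------------------------ callsites
        stage = "callsites"
        t0 = time.perf_counter()
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        events, ev_counts = st.events_from_sam(sam_path, chrom_lengths,
                                               config.source_tag, config.min_mapq)
        counters.setdefault("mapped_reads", {}).setdefault(
            config.source_tag, ev_counts["records"] - ev_counts["skipped"])
        kept, discarded = st.apply_filter(events, genome, config.filter_config())
        counters.setdefault("pa_events", {})[config.source_tag] = len(kept)
        clusters = st.cluster_events(kept, config.merge_distance,
                                     config.merge_sources)
        site_stats = st.summarize_sites(clusters)
        st.write_clusters_bed(clusters, out / "clusters.bed")
        st.write_cluster_members(clusters, out / "cluster_members.tsv")
        with open(out / "discarded_events.tsv", "w") as fh:
            fh.write("read_id\tchrom\tstrand\tposition\treason\n")
            for ev, reason in discarded:
                fh.write(f"{ev.read_id}\t{ev.chrom}\t{ev.strand}\t"
                         f"{ev.position}\t{reason}\n")
        for src, n in site_stats.per_source.items():
            counters.setdefault("pa_clusters", {})[src] = n
        logger.info("callsites: %d events kept, %d discarded, %d clusters, %.1fs",
                    len(kept), len(discarded), len(clusters),
                    time.perf_counter() - t0)

        # -------------------------------------------------------- profile
        stage = "profile"
        t0 = time.perf_counter()
        flanks = prof.extract_flanks(clusters, genome, config.halfwidth)
        mono = prof.nucleotide_profile(flanks, order=1)
        di = prof.nucleotide_profile(flanks, order=2)
        hex_table = prof.hexamer_position_scan(flanks, config.scan_range)
        signal_calls = {
            hx: prof.classify_hexamer_signal(hex_table, hx,
                                             threshold=config.peak_ratio)
            for hx in PAS_HEXAMERS_RNA + ("UUUUUU",)}
        pas_calls = prof.assign_pas_all(flanks, window=config.pas_window)
        usage = prof.usage_frequency_table(pas_calls)
        gc = config.background_gc
        dse = prof.dse_enrichment(mono, di, gc)
        mono.to_frame().to_csv(out / "profile_mono.tsv", sep="\t", index=False)
        di.to_frame().to_csv(out / "profile_di.tsv", sep="\t", index=False)
        usage.to_csv(out / "pas_usage.tsv", sep="\t", index=False,
                     float_format="%.2f")
        prof.chisq_profile_table(mono, gc).to_csv(out / "chisq_mono.tsv",
                                                  sep="\t", index=False)
        _write_hexamer_table(hex_table, out / "hexamer_positions.tsv")
        with open(out / "pas_calls.tsv", "w") as fh:
            fh.write("cluster_id\thexamer\toffset\n")
            for c in pas_calls:
                fh.write(f"{c.cluster_id}\t{c.hexamer}\t"
                         f"{'' if c.offset is None else c.offset}\n")
        logger.info("profile: %d flanks, %.1fs", len(flanks),
                    time.perf_counter() - t0)

        # ------------------------------------------------------- annotate
        stage = "annotate"
        t0 = time.perf_counter()
        genes = ann.load_annotation(annotation)
        index = ann.FeatureIndex(genes)
        assignments = ann.assign_features(clusters, index)
        apa_summaries, apa_aggregate = ann.summarize_gene_apa(assignments)
        cat_fracs = ann.category_fractions(assignments)
        chrom_sum = ann.chromosome_summary(clusters, genes)
        _write_assignments(assignments, out / "feature_assignments.tsv")
        _write_apa(apa_summaries, out / "gene_apa.tsv")
        chrom_sum.to_csv(out / "chromosome_summary.tsv", sep="\t", index=False,
                         float_format="%.2f")
        with open(out / "category_fractions.tsv", "w") as fh:
            fh.write("category\tfraction\n")
            for cat, fr in cat_fracs.items():
                fh.write(f"{cat}\t{fr:.4f}\n")
        logger.info("annotate: %d genes, %.1fs", len(genes),
                    time.perf_counter() - t0)

        # --------------------------------------------------------- report
        stage = "report"
        result = RunResult(config, out, sim, counters, site_stats, clusters,
                           usage, mono, di, hex_table, signal_calls, pas_calls,
                           dse, assignments, apa_summaries, apa_aggregate,
                           cat_fracs, chrom_sum, genome_md5)
        _write_run_report(result)
        return result
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_hexamer_table(table: prof.HexamerPositionTable, path: Path,
                         top: int = 50) -> None:
    order = sorted(table.occurrences, key=lambda h: -table.occurrences[h])[:top]
    with open(path, "w") as fh:
        fh.write("hexamer\ttotal_occurrences\tsites_with_occurrence\t" +
                 "\t".join(str(p) for p in table.start_positions) + "\n")
        for hx in order:
            fh.write(f"{hx}\t{table.occurrences[hx]}\t{table.sites_with[hx]}\t" +
                     "\t".join(str(int(c)) for c in table.counts[hx]) + "\n")


def _write_assignments(assignments, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tgene_id\tcategory\tposition\tstrand\n")
        for a in assignments:
            fh.write(f"{a.cluster_id}\t{a.gene_id or '.'}\t{a.category}\t"
                     f"{a.position}\t{a.strand}\n")


def _write_apa(summaries, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_sites\tcount_class\tis_apa\tapa_type\n")
        for s in summaries:
            fh.write(f"{s.gene_id}\t{s.n_sites}\t{s.count_class}\t"
                     f"{int(s.is_apa)}\t{s.apa_type}\n")


def _write_run_report(res: RunResult) -> None:
    """Counter table (TSV) plus a human-readable summary text file."""
    rep.counter_table(res.counters).to_csv(res.out_dir / "run_counters.tsv",
                                           sep="\t", index=False)
    ss = res.site_stats
    lines = ["# pasite run report", ""]
    for label, row in res.counters.items():
        total = rep.per_source_total(row)
        per_src = ", ".join(f"{k}={v}" for k, v in sorted(row.items()))
        lines.append(f"{label}: {per_src}, total={total}")
    lines.append("")
    lines.append(f"clusters with one member: {ss.fraction_one:.4f}")
    lines.append(f"clusters with two members: {ss.fraction_two:.4f}")
    lines.append(f"clusters with >=3 members: {ss.fraction_several:.4f}")
    lines.append("")
    lines.append("PAS usage (%):")
    for _, r in res.usage.iterrows():
        lines.append(f"  {r['hexamer']}\t{r['percent']:.2f}")
    lines.append("")
    lines.append("feature category fractions (genic clusters):")
    for cat, fr in res.category_fractions.items():
        lines.append(f"  {cat}\t{fr:.4f}")
    lines.append("")
    lines.append("sites-per-gene class fractions:")
    for cls, fr in res.apa_aggregate["class_fractions"].items():
        lines.append(f"  {cls}\t{fr:.4f}")
    lines.append(f"fraction of genes with APA (>=2 sites): "
                 f"{res.apa_aggregate['fraction_apa']:.4f}")
    dse = res.dse
    lines.append("")
    lines.append(f"DSE: mean U {dse['mean_u']:.4f} in +{dse['window'][0]}.."
                 f"+{dse['window'][1]} vs background {dse['expected_u']:.4f}; "
                 f"max-U window {dse['max_u_window']}")
    (res.out_dir / "run_summary.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# validation against synthetic truth

def validate_against_truth(result: RunResult, sim: SimResult | None = None,
                           match_distance: int = 20) -> dict:
    """Recovery metrics of a synthetic run against its truth tables:
    cluster recall/precision (exact and +-match_distance), PAS-class
    confusion, feature-category accuracy, and the decoy removal rate.
    Refuses to compare when the genome checksums differ."""
    sim = sim or result.sim
    if sim is None:
        raise ValueError("validation requires a synthetic run (truth tables)")
    if sim.genome_md5 and result.genome_md5 != sim.genome_md5:
        raise ValueError("genome checksum mismatch between run and truth; "
                         "refusing to validate")

    truth_pos = {(s.chrom, s.strand, s.cleavage_position): s for s in sim.sites}
    found = {(c.chrom, c.strand, c.representative_position): c
             for c in result.clusters}

    exact_hits = set(truth_pos) & set(found)
    recall_exact = len(exact_hits) / len(truth_pos) if truth_pos else 0.0
    precision_exact = len(exact_hits) / len(found) if found else 0.0

    # tolerant matching: nearest truth site on the same chrom/strand
    by_key: dict[tuple[str, str], np.ndarray] = {}
    site_lists: dict[tuple[str, str], list] = {}
    for s in sim.sites:
        site_lists.setdefault((s.chrom, s.strand), []).append(s)
    for key, sl in site_lists.items():
        sl.sort(key=lambda s: s.cleavage_position)
        by_key[key] = np.array([s.cleavage_position for s in sl])

    matched_truth: set[str] = set()
    matched_pairs = []
    n_loose = 0
    for c in result.clusters:
        arr = by_key.get((c.chrom, c.strand))
        if arr is None or arr.size == 0:
            continue
        i = int(np.searchsorted(arr, c.representative_position))
        best = None
        for j in (i - 1, i):
            if 0 <= j < arr.size:
                d = abs(int(arr[j]) - c.representative_position)
                if best is None or d < best[0]:
                    best = (d, j)
        if best is not None and best[0] <= match_distance:
            n_loose += 1
            site = site_lists[(c.chrom, c.strand)][best[1]]
            matched_truth.add(site.site_id)
            matched_pairs.append((c, site))
    recall_loose = len(matched_truth) / len(truth_pos) if truth_pos else 0.0
    precision_loose = n_loose / len(found) if found else 0.0

    # PAS confusion and feature accuracy over matched clusters
    pas_by_cluster = {p.cluster_id: p.hexamer for p in result.pas_calls}
    cat_by_cluster = {a.cluster_id: a.category for a in result.assignments}
    confusion: dict[tuple[str, str], int] = {}
    n_pas_correct = n_feat_correct = 0
    for cluster, site in matched_pairs:
        called = pas_by_cluster.get(cluster.cluster_id, "none")
        key = (site.planted_hexamer, called)
        confusion[key] = confusion.get(key, 0) + 1
        if called == site.planted_hexamer:
            n_pas_correct += 1
        if cat_by_cluster.get(cluster.cluster_id) == site.feature_category:
            n_feat_correct += 1
    n_matched = len(matched_pairs)

    # decoy removal: decoy-origin reads absent from surviving cluster support
    decoy_reads = {r.read_id for r in sim.reads_truth if r.is_decoy}
    surviving = _surviving_read_ids(result)
    decoy_survivors = decoy_reads & surviving if surviving is not None else set()
    removal_rate = (1.0 - len(decoy_survivors) / len(decoy_reads)
                    if decoy_reads else 1.0)

    return {
        "n_truth_sites": len(truth_pos),
        "n_clusters": len(found),
        "recall_exact": recall_exact,
        "precision_exact": precision_exact,
        "recall_within_20": recall_loose,
        "precision_within_20": precision_loose,
        "pas_accuracy": n_pas_correct / n_matched if n_matched else 0.0,
        "feature_accuracy": n_feat_correct / n_matched if n_matched else 0.0,
        "pas_confusion": confusion,
        "n_decoy_reads": len(decoy_reads),
        "decoy_removal_rate": removal_rate,
    }


def _surviving_read_ids(result: RunResult) -> set[str] | None:
    """Read ids contributing to kept cleavage events (re-read from the
    run's SAM minus the discarded-event list)."""
    sam = result.out_dir / "aligned.sam"
    if not sam.exists():
        return None
    discarded = set()
    disc_path = result.out_dir / "discarded_events.tsv"
    if disc_path.exists():
        with open(disc_path) as fh:
            next(fh, None)
            for line in fh:
                discarded.add(line.split("\t", 1)[0])
    import pysam
    ids = set()
    with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
        for rec in fh:
            if not (rec.is_unmapped or rec.is_secondary or rec.is_supplementary):
                ids.add(rec.query_name)
    return ids - discarded


def validate_run_dir(out_dir: str | Path, match_distance: int = 20) -> dict:
    """File-based validation of a finished synthetic run directory (as
    written by :func:`run_all`) against the truth tables it contains."""
    from .simulate import read_truth_reads, read_truth_sites

    out = Path(out_dir)
    sim_dir = out / "sim"
    if not sim_dir.exists():
        raise ValueError(f"{out}: no sim/ truth directory; was this a synthetic run?")
    truth_md5 = None
    for line in (sim_dir / "sim_config.txt").read_text().splitlines():
        if line.startswith("genome_md5"):
            truth_md5 = line.split("=", 1)[1].strip()
    sim = SimResult(config=None, genome={}, genes=[],
                    sites=read_truth_sites(sim_dir / "sites_truth.tsv"),
                    reads_truth=read_truth_reads(sim_dir / "reads_truth.tsv"),
                    genome_md5=truth_md5)
    clusters = st.read_cluster_members(out / "cluster_members.tsv")
    pas_calls = []
    with open(out / "pas_calls.tsv") as fh:
        next(fh)
        for line in fh:
            cid, hx, off = line.rstrip("\n").split("\t")
            pas_calls.append(prof.PASCall(cid, hx, int(off) if off else None))
    assignments = []
    with open(out / "feature_assignments.tsv") as fh:
        next(fh)
        for line in fh:
            cid, gid, cat, pos, strand = line.rstrip("\n").split("\t")
            assignments.append(ann.FeatureAssignment(
                cid, None if gid == "." else gid, cat, int(pos), strand))
    genome_md5 = hashlib.md5((sim_dir / "genome.fa").read_bytes()).hexdigest()
    result = RunResult(config=None, out_dir=out, sim=sim, counters={},
                       site_stats=None, clusters=clusters, usage=None,
                       mono_profile=None, di_profile=None, hexamer_table=None,
                       signal_calls={}, pas_calls=pas_calls, dse={},
                       assignments=assignments, apa_summaries=[],
                       apa_aggregate={}, category_fractions={},
                       chrom_summary=None, genome_md5=genome_md5)
    return validate_against_truth(result, sim, match_distance)


def write_validation(metrics: Mapping, path: str | Path) -> None:
    serializable = {k: ({f"{a}->{b}": v for (a, b), v in val.items()}
                        if k == "pas_confusion" else val)
                    for k, val in metrics.items()}
    with open(path, "w") as fh:
        json.dump(serializable, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# flat key=value run configuration files

def load_run_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` configuration file.  Keys matching
    SimConfig fields configure the generator; the rest configure stages."""
    from dataclasses import fields as dc_fields

    raw: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()

    sim_fields = {f.name: f for f in dc_fields(SimConfig)}
    run_fields = {f.name: f for f in dc_fields(RunConfig)}
    sim_kwargs, run_kwargs = {}, {}
    for key, value in raw.items():
        if key in sim_fields:
            sim_kwargs[key] = _coerce(value, sim_fields[key].type)
        elif key in run_fields and key != "sim":
            run_kwargs[key] = _coerce(value, run_fields[key].type)
        elif key == "genome_md5":
            continue
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    cfg = RunConfig(**run_kwargs)
    cfg.sim = SimConfig(**sim_kwargs)
    return cfg


def _coerce(value: str, type_hint: str | type):
    hint = str(type_hint)
    if value.lower() in ("none", ""):
        return None
    if "Mapping" in hint or ":" in value:
        out = {}
        for item in value.split(","):
            k, _, v = item.partition(":")
            out[k.strip()] = float(v)
        return out
    if "tuple" in hint:
        parts = [p.strip() for p in value.split(",")]
        return tuple(float(p) if "." in p else int(p) for p in parts)
    if "bool" in hint:
        return value.lower() in ("1", "true", "yes", "on")
    if "int" in hint:
        return int(value)
    if "float" in hint:
        return float(value)
    return value
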