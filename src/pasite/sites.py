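"""Cleavage-event calling, internal-priming filtering and pA-site
clustering.

Coordinate convention (documented in docs/methods.md): the cleavage base
is the poly(A) *attachment* base - the genomic base one step 3' of the
last aligned base of the tail-trimmed sense read.  On the + strand this
is ``reference_end`` (half-open end) of the alignment; on the - strand it
is ``reference_start - 1``.  In real data this base is usually a genomic
A that the tail trimmer absorbed into the apparent tail, which is exactly
why internally primed artifacts are detectable: a genuine tail is
untemplated beyond position 0, while an internal-priming artifact sits on
a genomic A-run.

The internal-priming filter inspects the 10 sense-strand bases starting
at the cleavage base and discards the event when the window holds >= 9 A
(the window rule) or contains a run of >= 8 consecutive A (the run rule);
by default both rules apply ("either" mode).

Events on one chromosome and strand whose adjacent positions lie <= 20 bp
apart are chained into one poly(A) cluster (single linkage); the cluster
representative is the member with maximal read support, ties resolved to
the 5'-most member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .dna import max_run, revcomp

__all__ = ["CleavageEvent", "FilterConfig", "PolyACluster", "SiteStats",
           "call_cleavage", "events_from_sam", "downstream_window",
           "internal_priming_filter", "apply_filter", "cluster_events",
           "summarize_sites", "load_genome", "write_clusters_bed",
           "write_cluster_members"]

DEFAULT_MERGE_DISTANCE = 20


@dataclass
class CleavageEvent:
    chrom: str
    strand: str
    position: int             # 0-based coordinate of the cleavage (attachment) base
    read_id: str
    source_tag: str = "long-read"


@dataclass
class FilterConfig:
    window_len: int = 10
    min_at: int = 9
    min_run: int = 8
    mode: str = "either"      # "window" | "run" | "either"

    def __post_init__(self) -> None:
        if self.min_at > self.window_len:
            raise ValueError("min_at cannot exceed window_len")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.mode not in ("window", "run", "either"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


@dataclass
class PolyACluster:
    cluster_id: str
    chrom: str
    strand: str
    member_positions: list[int]
    support_per_member: list[int]
    representative_position: int
    total_support: int
    source_tag: str = "long-read"

    @property
    def n_members(self) -> int:
        return len(self.member_positions)


@dataclass
class SiteStats:
    per_source: dict[str, int] = field(default_factory=dict)
    total: int = 0
    fraction_one: float = 0.0
    fraction_two: float = 0.0
    fraction_several: float = 0.0


def call_cleavage(rec: pysam.AlignedSegment, chrom_lengths: Mapping[str, int]
                  ) -> tuple[CleavageEvent | None, str | None]:
    """Cleavage event from one unique alignment of a sense read, or a
    rejection reason.  The read's 3' end must be anchored: a soft or hard
    clip at the tail-adjacent end rejects the record."""
    cig = rec.cigartuples or []
    if rec.is_reverse:
        clipped = bool(cig) and cig[0][0] in (4, 5)
        pos = rec.reference_start - 1
        strand = "-"
    else:
        clipped = bool(cig) and cig[-1][0] in (4, 5)
        pos = rec.reference_end
        strand = "+"
    if clipped:
        return None, "clipped-end"
    chrom = rec.reference_name
    if pos < 0 or pos >= chrom_lengths[chrom]:
        return None, "contig-edge"
    return CleavageEvent(chrom, strand, pos, rec.query_name), None


def events_from_sam(path: str | Path, chrom_lengths: Mapping[str, int] | None = None,
                    source_tag: str = "long-read", min_mapq: int = 1
                    ) -> tuple[list[CleavageEvent], dict[str, int]]:
    """Extract cleavage events from a SAM/BAM of tail-trimmed sense reads.

    Unmapped, secondary and supplementary records are skipped, as are
    records below the mapping-quality floor (multi-mappers)."""
    events: list[CleavageEvent] = []
    counts = {"records": 0, "skipped": 0, "low_mapq": 0,
              "clipped-end": 0, "contig-edge": 0, "events": 0}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        lengths = chrom_lengths or dict(zip(sam.references, sam.lengths))
        for rec in sam:
            counts["records"] += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                counts["skipped"] += 1
                continue
            if rec.mapping_quality < min_mapq:
                counts["low_mapq"] += 1
                continue
            event, reason = call_cleavage(rec, lengths)
            if event is None:
                counts[reason] += 1
                continue
            event.source_tag = source_tag
            events.append(event)
            counts["events"] += 1
    return events, counts


def downstream_window(genome: Mapping[str, str], event: CleavageEvent,
                      window_len: int = 10) -> str:
    """Sense-strand genomic bases at relative positions 0..window_len-1
    (starting at the cleavage base), truncated at contig edges."""
    seq = genome[event.chrom]
    if event.strand == "+":
        return seq[event.position:event.position + window_len]
    lo = max(event.position - window_len + 1, 0)
    return revcomp(seq[lo:event.position + 1])


def internal_priming_filter(event: CleavageEvent, genome: Mapping[str, str],
                            config: FilterConfig = FilterConfig()
                            ) -> tuple[bool, str | None]:
    """Keep/discard decision for one event; reasons are "window-rule" or
    "run-rule" on discard."""
    if event.chrom not in genome:
        raise KeyError(f"contig {event.chrom!r} absent from genome")
    w = downstream_window(genome, event, config.window_len)
    if config.mode in ("window", "either") and w.count("A") >= config.min_at:
        return False, "window-rule"
    if config.mode in ("run", "either") and max_run(w, "A") >= config.min_run:
        return False, "run-rule"
    return True, None


def apply_filter(events: Iterable[CleavageEvent], genome: Mapping[str, str],
                 config: FilterConfig = FilterConfig()
                 ) -> tuple[list[CleavageEvent], list[tuple[CleavageEvent, str]]]:
    kept, discarded = [], []
    for ev in events:
        ok, reason = internal_priming_filter(ev, genome, config)
        if ok:
            kept.append(ev)
        else:
            discarded.append((ev, reason))
    return kept, discarded


def cluster_events(events: Sequence[CleavageEvent],
                   merge_distance: int = DEFAULT_MERGE_DISTANCE,
                   merge_sources: bool = False) -> list[PolyACluster]:
    """Single-linkage merge of per-read events into pA clusters.

    Adjacent distinct positions with gap <= merge_distance chain
    transitively.  Sources are clustered separately unless
    ``merge_sources``; output is deterministically ordered by
    (source, chrom, strand, representative)."""
    groups: dict[tuple, list[int]] = {}
    for ev in events:
        key = (("all",) if merge_sources else (ev.source_tag,)) + (ev.chrom, ev.strand)
        groups.setdefault(key, []).append(ev.position)

    clusters: list[PolyACluster] = []
    for key in sorted(groups):
        source, chrom, strand = key
        positions, support = np.unique(np.array(groups[key], dtype=np.int64),
                                       return_counts=True)
        breaks = np.flatnonzero(np.diff(positions) > merge_distance) + 1
        for mem, sup in zip(np.split(positions, breaks), np.split(support, breaks)):
            best = int(sup.max())
            idx = np.flatnonzero(sup == best)
            i = int(idx[0]) if strand == "+" else int(idx[-1])  # tie -> 5'-most
            clusters.append(PolyACluster(
                cluster_id="",
                chrom=chrom, strand=strand,
                member_positions=[int(p) for p in mem],
                support_per_member=[int(s) for s in sup],
                representative_position=int(mem[i]),
                total_support=int(sup.sum()),
                source_tag=source))
    clusters.sort(key=lambda c: (c.source_tag, c.chrom, c.strand,
                                 c.representative_position))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"pa{i:06d}"
    return clusters


def summarize_sites(clusters: Sequence[PolyACluster]) -> SiteStats:
    """Per-source cluster counts plus the fractions of clusters with one,
    two, or three-plus member positions (cleavage heterogeneity)."""
    stats = SiteStats()
    for c in clusters:
        stats.per_source[c.source_tag] = stats.per_source.get(c.source_tag, 0) + 1
    stats.total = sum(stats.per_source.values())
    if stats.total:
        n = np.array([c.n_members for c in clusters])
        stats.fraction_one = float(np.mean(n == 1))
        stats.fraction_two = float(np.mean(n == 2))
        stats.fraction_several = float(np.mean(n >= 3))
    return stats


def load_genome(path: str | Path) -> dict[str, str]:
    """Genome FASTA into an in-memory {chrom: sequence} map (pyfaidx)."""
    import pyfaidx
    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_clusters_bed(clusters: Iterable[PolyACluster], path: str | Path) -> None:
    """6-column BED of representatives (0-based half-open single-base
    intervals; score = total read support)."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.representative_position}\t"
                     f"{c.representative_position + 1}\t{c.cluster_id}\t"
                     f"{c.total_support}\t{c.strand}\n")


def read_cluster_members(path: str | Path) -> list[PolyACluster]:
    """Inverse of :func:`write_cluster_members`."""
    clusters = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            cid, chrom, strand, source, rep, members, support = \
                line.rstrip("\n").split("\t")
            mem = [int(x) for x in members.split(",")]
            sup = [int(x) for x in support.split(",")]
            clusters.append(PolyACluster(cid, chrom, strand, mem, sup,
                                         int(rep), sum(sup), source))
    return clusters


def write_cluster_members(clusters: Iterable[PolyACluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchrom\tstrand\tsource\trepresentative\t"
                 "member_positions\tsupport_per_member\n")
        for c in clusters:
            fh.write(f"{c.cluster_id}\t{c.chrom}\t{c.strand}\t{c.source_tag}\t"
                     f"{c.representative_position}\t"
                     f"{','.join(map(str, c.member_positions))}\t"
                     f"{','.join(map(str, c.support_per_member))}\n")
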