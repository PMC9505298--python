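"""Naive exact-match aligner for synthetic reads.

Real data enters the pipeline as SAM/BAM produced by a dedicated mapper;
this module only exists so the synthetic fixtures can be taken through the
same SAM interface without an external aligner.  It performs ungapped,
end-to-end, exact matching (the generator emits error-free, genomically
contiguous reads) using a sorted k-mer table of the genome: a read is
seeded by its first k bases in both orientations, every seed hit is
verified by full-string comparison, and only reads with exactly one
verified placement are reported (multi-mapping reads are dropped, as the
analysis keeps uniquely mapped reads only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam

from .dna import revcomp

__all__ = ["Alignment", "ExactAligner", "write_sam", "align_to_sam"]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i

_MAX_SEED_HITS = 100


@dataclass
class Alignment:
    read_id: str
    chrom: str
    pos: int          # 0-based leftmost reference coordinate
    strand: str       # "+" if the sense read matches the forward genome
    length: int
    seq_fwd: str      # genome-forward sequence (revcomp of the read if "-")


class ExactAligner:
    """Sorted k-mer index over the forward genome."""

    def __init__(self, genome: Mapping[str, str], k: int = 24):
        self.k = k
        self.chrom_lengths = {c: len(s) for c, s in genome.items()}
        self._names = list(genome)
        sep = "N" * k
        self._concat = sep.join(genome[c] for c in self._names)
        self._offsets = []
        off = 0
        for c in self._names:
            self._offsets.append(off)
            off += len(genome[c]) + k
        self._offsets_arr = np.array(self._offsets, dtype=np.int64)
        self._build()

    def _build(self) -> None:
        k = self.k
        code = _CODE[np.frombuffer(self._concat.encode(), dtype=np.uint8)]
        n = len(code) - k + 1
        if n <= 0:
            self._sorted_hashes = np.empty(0, np.uint64)
            self._sorted_pos = np.empty(0, np.int64)
            return
        h = np.zeros(n, dtype=np.uint64)
        bad = np.zeros(n, dtype=bool)
        for j in range(k):
            window = code[j:j + n]
            h = (h << np.uint64(2)) | window.astype(np.uint64)
            bad |= window > 3
        valid = np.flatnonzero(~bad)
        hashes = h[valid]
        order = np.argsort(hashes, kind="stable")
        self._sorted_hashes = hashes[order]
        self._sorted_pos = valid[order].astype(np.int64)

    def _hash(self, seq: str) -> int | None:
        h = 0
        for c in seq[:self.k]:
            v = _CODE[ord(c)]
            if v > 3:
                return None
            h = (h << 2) | int(v)
        return h

    def _seed_hits(self, seq: str) -> np.ndarray:
        h = self._hash(seq)
        if h is None:
            return np.empty(0, np.int64)
        h = np.uint64(h)
        lo = np.searchsorted(self._sorted_hashes, h, side="left")
        hi = np.searchsorted(self._sorted_hashes, h, side="right")
        return self._sorted_pos[lo:hi]

    def _locate(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self._offsets_arr, gpos, side="right")) - 1
        return self._names[ci], gpos - self._offsets[ci]

    def map_one(self, seq: str) -> Alignment | None:
        """Unique end-to-end exact placement of a sense-oriented read, or
        None (too short / unmapped / ambiguous)."""
        if len(seq) < self.k:
            return None
        placements: list[tuple[int, str, str]] = []
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            hits = self._seed_hits(query)
            if hits.size > _MAX_SEED_HITS:
                return None
            for gpos in hits:
                gpos = int(gpos)
                if self._concat[gpos:gpos + len(query)] == query:
                    placements.append((gpos, strand, query))
                    if len(placements) > 1:
                        return None
        if len(placements) != 1:
            return None
        gpos, strand, query = placements[0]
        chrom, pos = self._locate(gpos)
        if pos + len(query) > self.chrom_lengths[chrom]:
            return None  # placement straddles the N separator
        return Alignment("", chrom, pos, strand, len(query), query)

    def map_reads(self, reads: Iterable[tuple[str, str]]
                  ) -> tuple[list[Alignment], dict[str, int]]:
        out: list[Alignment] = []
        counts = {"input": 0, "mapped": 0, "unmapped_or_ambiguous": 0}
        for read_id, seq in reads:
            counts["input"] += 1
            aln = self.map_one(seq)
            if aln is None:
                counts["unmapped_or_ambiguous"] += 1
                continue
            aln.read_id = read_id
            counts["mapped"] += 1
            out.append(aln)
        return out, counts


def write_sam(alignments: Iterable[Alignment], chrom_lengths: Mapping[str, int],
              path: str | Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    names = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for aln in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = aln.read_id
            rec.flag = 0 if aln.strand == "+" else 16
            rec.reference_id = names[aln.chrom]
            rec.reference_start = aln.pos
            rec.mapping_quality = 60
            rec.cigartuples = [(0, aln.length)]
            rec.query_sequence = aln.seq_fwd
            sam.write(rec)


def align_to_sam(genome: Mapping[str, str], reads: Iterable[tuple[str, str]],
                 path: str | Path, k: int = 24) -> dict[str, int]:
    """Index, map, and write a SAM file; returns mapping counters."""
    aligner = ExactAligner(genome, k=k)
    alignments, counts = aligner.map_reads(reads)
    write_sam(alignments, aligner.chrom_lengths, path)
    return counts
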