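"""Terminal poly(A)/poly(T) tail detection, trimming and sense
normalization.

A read carries poly(A) evidence if it ends in an A homopolymer (3' tail)
or begins with a T homopolymer (the reverse-complemented mirror).  The
tail is the *maximal* exact terminal run - no mismatches are tolerated
and N terminates a run - and is called only when it reaches ``min_tail``
(default 10 nt).  When both ends qualify the longer run wins; a tie goes
to the 3' A tail.  Reads called on the 5' T end are reverse complemented
so that every emitted sequence is in transcript (sense) orientation with
its 3'-most base adjacent to the removed tail.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .dna import homopolymer_run, revcomp

__all__ = ["RawRead", "TailCall", "PrepStats", "detect_and_trim_tail",
           "prepare_batch", "read_sequences", "write_tail_report",
           "write_trimmed_fastq"]

_VALID = set("ACGTN")

DEFAULT_MIN_TAIL = 10


@dataclass
class RawRead:
    read_id: str
    sequence: str
    source_tag: str = "long-read"


@dataclass
class TailCall:
    read_id: str
    tail_end: str             # "three_prime_A" | "five_prime_T" | "none"
    tail_length: int
    trimmed_sequence: str     # original orientation, tail removed
    sense_sequence: str       # reverse complemented iff five_prime_T
    min_tail: int = DEFAULT_MIN_TAIL
    source_tag: str = "long-read"


@dataclass
class PrepStats:
    raw_count: int = 0
    tailed_count: int = 0

    def __add__(self, other: "PrepStats") -> "PrepStats":
        return PrepStats(self.raw_count + other.raw_count,
                         self.tailed_count + other.tailed_count)


def detect_and_trim_tail(read: RawRead, min_tail: int = DEFAULT_MIN_TAIL) -> TailCall:
    """Call, measure and trim the terminal homopolymer tail of one read."""
    if min_tail < 1:
        raise ValueError("min_tail must be >= 1")
    seq = read.sequence
    if not seq:
        raise ValueError(f"empty sequence for read {read.read_id!r}")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"read {read.read_id!r} contains non-ACGTN characters: {sorted(bad)}")

    a3 = homopolymer_run(seq, "A", from_end=True)
    t5 = homopolymer_run(seq, "T", from_end=False)
    if a3 >= min_tail and a3 >= t5:
        trimmed = seq[:-a3]
        return TailCall(read.read_id, "three_prime_A", a3, trimmed, trimmed,
                        min_tail, read.source_tag)
    if t5 >= min_tail:
        trimmed = seq[t5:]
        return TailCall(read.read_id, "five_prime_T", t5, trimmed,
                        revcomp(trimmed), min_tail, read.source_tag)
    return TailCall(read.read_id, "none", 0, seq, seq, min_tail, read.source_tag)


def prepare_batch(reads: Iterable[RawRead], min_tail: int = DEFAULT_MIN_TAIL
                  ) -> tuple[list[TailCall], dict[str, PrepStats]]:
    """Tail-call a stream of reads.  Every input read is counted once in
    the per-source stats; only reads with a detected tail are emitted."""
    calls: list[TailCall] = []
    stats: dict[str, PrepStats] = {}
    for read in reads:
        st = stats.setdefault(read.source_tag, PrepStats())
        st.raw_count += 1
        call = detect_and_trim_tail(read, min_tail)
        if call.tail_end != "none":
            st.tailed_count += 1
            calls.append(call)
    return calls, stats


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path: str | Path, source_tag: str = "long-read"
                   ) -> Iterator[RawRead]:
    """Stream reads from FASTA or FASTQ (gzip-transparent), sniffing the
    format from the first record character."""
    from Bio.SeqIO.FastaIO import SimpleFastaParser
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            for title, seq in SimpleFastaParser(fh):
                yield RawRead(title.split()[0], seq.upper(), source_tag)
        elif first == "@":
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield RawRead(title.split()[0], seq.upper(), source_tag)
        elif first == "":
            return
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ input")


def write_tail_report(calls: Iterable[TailCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttail_end\ttail_length\n")
        for c in calls:
            fh.write(f"{c.read_id}\t{c.tail_end}\t{c.tail_length}\n")


def write_trimmed_fastq(calls: Iterable[TailCall], path: str | Path) -> None:
    """Trimmed reads in sense orientation, constant quality."""
    with open(path, "w") as fh:
        for c in calls:
            if c.tail_end == "none" or not c.sense_sequence:
                continue
            fh.write(f"@{c.read_id}\n{c.sense_sequence}\n+\n{'I' * len(c.sense_sequence)}\n")
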