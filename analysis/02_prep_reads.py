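#!/usr/bin/env python
"""Detect and trim terminal poly(A)/poly(T) tails (>= 10 nt) and
normalize reads to sense orientation.

Reads results/synthetic_run/sim/reads.fastq; writes the trimmed sense
reads and a per-read tail report next to them.
"""

import argparse
from pathlib import Path

from pasite import tails


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results/synthetic_run"))
    ap.add_argument("--min-tail", type=int, default=10)
    args = ap.parse_args()

    calls, stats = tails.prepare_batch(
        tails.read_sequences(args.dir / "sim" / "reads.fastq"), args.min_tail)
    tails.write_trimmed_fastq(calls, args.dir / "trimmed.fastq")
    tails.write_tail_report(calls, args.dir / "tail_report.tsv")

    for src, s in stats.items():
        print(f"{src}: raw reads {s.raw_count:,}, "
              f"poly(A)/(T)-tailed {s.tailed_count:,} "
              f"({s.tailed_count / s.raw_count:.1%})")
    lengths = [c.tail_length for c in calls]
    print(f"tail length: min {min(lengths)}, max {max(lengths)} nt; "
          f"trimmed sense reads -> {args.dir / 'trimmed.fastq'}")


if __name__ == "__main__":
    main()
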