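#!/usr/bin/env python
"""Sequence structure around the recovered cleavage sites: positional
nucleotide profiles, hexamer positional scan with signal/noise
classification, PAS hexamer assignment (40 nt upstream, canonical
first), usage table, chi-square tests against the genome background and
the downstream U/GU (DSE) report.
"""

import argparse
from pathlib import Path

from pasite import profiling as prof
from pasite import sites as st


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results/synthetic_run"))
    ap.add_argument("--gc", type=float, default=0.364)
    args = ap.parse_args()

    genome = st.load_genome(args.dir / "sim" / "genome.fa")
    clusters = st.read_cluster_members(args.dir / "cluster_members.tsv")
    flanks = prof.extract_flanks(clusters, genome)
    mono = prof.nucleotide_profile(flanks, 1)
    di = prof.nucleotide_profile(flanks, 2)
    table = prof.hexamer_position_scan(flanks)
    calls = prof.assign_pas_all(flanks)
    usage = prof.usage_frequency_table(calls)

    mono.to_frame().to_csv(args.dir / "profile_mono.tsv", sep="\t", index=False)
    di.to_frame().to_csv(args.dir / "profile_di.tsv", sep="\t", index=False)
    usage.to_csv(args.dir / "pas_usage.tsv", sep="\t", index=False,
                 float_format="%.2f")
    prof.chisq_profile_table(mono, args.gc).to_csv(
        args.dir / "chisq_mono.tsv", sep="\t", index=False)
    with open(args.dir / "pas_calls.tsv", "w") as fh:
        fh.write("cluster_id\thexamer\toffset\n")
        for c in calls:
            fh.write(f"{c.cluster_id}\t{c.hexamer}\t"
                     f"{'' if c.offset is None else c.offset}\n")

    print("PAS usage (%):")
    for _, row in usage.iterrows():
        if row.percent >= 1.0 or row.hexamer == "Other":
            print(f"  {row.hexamer:8s} {row.percent:6.2f}")
    for hx in ("AAUAAA", "AUUAAA", "UUUUUU"):
        sig = prof.classify_hexamer_signal(table, hx)
        print(f"{hx}: {sig.classification} "
              f"(peak {sig.peak_position}, score {sig.peak_score:.1f})")
    dse = prof.dse_enrichment(mono, di, args.gc)
    print(f"A frequency at position 0: {mono.freq_of('A', 0):.1%}")
    print(f"mean U in +3..+27: {dse['mean_u']:.1%} "
          f"(background {dse['expected_u']:.1%}, "
          f"far window {dse['mean_u_far']:.1%})")


if __name__ == "__main__":
    main()
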