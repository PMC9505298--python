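"""Small DNA/RNA sequence helpers shared across the pipeline.

All genomic computation is done on the DNA alphabet (A/C/G/T/N); the RNA
alphabet (T -> U) is applied only at reporting boundaries, matching the
convention of the 3'-end processing literature where signals are written
as RNA (AAUAAA) but scanned on genomic DNA (AATAAA).
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The 14 canonical poly(A)-signal hexamers in descending usage order
#: (AAUAAA first, then its single-nucleotide variants by reported frequency).
#: This order doubles as the assignment priority: when several hexamers are
#: present upstream of a cleavage site, the highest-priority one is called.
PAS_HEXAMERS_RNA: tuple[str, ...] = (
    "AAUAAA",
    "AUUAAA",
    "UAUAAA",
    "AGUAAA",
    "AAGAAA",
    "AAUAUA",
    "AAUACA",
    "CAUAAA",
    "GAUAAA",
    "AAUGAA",
    "UUUAAA",
    "ACUAAA",
    "AAUAGA",
    "AAAAAG",
)

PAS_HEXAMERS_DNA: tuple[str, ...] = tuple(h.replace("U", "T") for h in PAS_HEXAMERS_RNA)

DNA_TO_RNA = str.maketrans("Tt", "Uu")
RNA_TO_DNA = str.maketrans("Uu", "Tt")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.translate(DNA_TO_RNA)


def to_dna(seq: str) -> str:
    return seq.translate(RNA_TO_DNA)


def homopolymer_run(seq: str, base: str, from_end: bool) -> int:
    """Length of the terminal run of ``base`` at the 3' end (``from_end``)
    or 5' start of ``seq``.  Any other character, including N, terminates
    the run."""
    n = 0
    it = reversed(seq) if from_end else iter(seq)
    for c in it:
        if c != base:
            break
        n += 1
    return n


def max_run(seq: str, base: str) -> int:
    """Longest run of ``base`` anywhere in ``seq``."""
    best = cur = 0
    for c in seq:
        if c == base:
            cur += 1
            if cur > best:
                best = cur
        else:
            cur = 0
    return best
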