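"""Sequence structure around cleavage sites.

Given the clustered pA sites, this module extracts sense-strand flanking
windows (default 100 nt each side of the cleavage base, position 0),
computes positional mono-/di-nucleotide frequency profiles, scans hexamer
occurrences by position, classifies hexamer distributions into signal
vs noise, assigns the poly(A)-signal (PAS) hexamer per site from a
40-nt upstream search window with canonical-first priority, tabulates
PAS usage percentages, tests per-position nucleotide frequencies against
the genome-composition background with 1-df chi-square goodness-of-fit
tests, and reports downstream U/GU enrichment (the DSE).

All genomic computation is on DNA; symbols are reported in the RNA
alphabet (T -> U).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dna import PAS_HEXAMERS_RNA, to_dna, to_rna
from .sites import PolyACluster

__all__ = ["FlankSet", "ProfileMatrix", "HexamerPositionTable", "HexamerSignal",
           "PASCall", "ChiSquareResult", "extract_flanks", "nucleotide_profile",
           "hexamer_position_scan", "classify_hexamer_signal", "assign_pas",
           "assign_pas_all", "usage_frequency_table", "chisq_vs_background",
           "profile_chisq", "dse_enrichment"]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_MONO_RNA = ("A", "C", "G", "U")
_DI_RNA = tuple(a + b for a, b in product(_MONO_RNA, _MONO_RNA))

DEFAULT_HALFWIDTH = 100
DEFAULT_PAS_WINDOW = 40
DEFAULT_SCAN_RANGE = (-50, -1)


@dataclass
class FlankSet:
    """Sense-strand windows centred on cluster representatives.

    ``codes`` is an (n_sites, 2*halfwidth+1) array of 2-bit base codes with
    255 at masked (off-contig) positions; column j is relative position
    j - halfwidth."""

    cluster_ids: list[str]
    codes: np.ndarray
    halfwidth: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.halfwidth, self.halfwidth + 1)

    def __len__(self) -> int:
        return self.codes.shape[0]

    def col(self, rel: int) -> np.ndarray:
        return self.codes[:, rel + self.halfwidth]

    def sense_seq(self, i: int, rel_lo: int, rel_hi: int) -> str:
        """DNA string of flank ``i`` over [rel_lo, rel_hi]; masked -> N."""
        sub = self.codes[i, rel_lo + self.halfwidth: rel_hi + self.halfwidth + 1]
        return "".join("ACGTN"[min(c, 4)] for c in sub)


@dataclass
class ProfileMatrix:
    """Positional symbol frequencies; symbols in the RNA alphabet."""

    positions: np.ndarray          # relative positions (first base for order 2)
    alphabet: tuple[str, ...]
    freq: np.ndarray               # (n_positions, len(alphabet))
    counts: np.ndarray             # unmasked denominators per position
    order: int = 1

    def freq_of(self, symbol: str, position: int) -> float:
        i = int(np.flatnonzero(self.positions == position)[0])
        return float(self.freq[i, self.alphabet.index(symbol)])

    def count_at(self, position: int) -> int:
        i = int(np.flatnonzero(self.positions == position)[0])
        return int(self.counts[i])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pos in enumerate(self.positions):
            for j, sym in enumerate(self.alphabet):
                rows.append((int(pos), sym, float(self.freq[i, j]), int(self.counts[i])))
        return pd.DataFrame(rows, columns=["position", "symbol", "frequency", "n"])


@dataclass
class HexamerPositionTable:
    scan_range: tuple[int, int]
    start_positions: np.ndarray            # valid 5'-base positions
    counts: dict[str, np.ndarray]          # RNA hexamer -> counts per start
    sites_with: dict[str, int]             # sites containing >= 1 occurrence
    occurrences: dict[str, int]            # total occurrence counts
    n_sites: int = 0

    def counts_for(self, hexamer_rna: str) -> np.ndarray:
        return self.counts.get(hexamer_rna,
                               np.zeros(len(self.start_positions), dtype=np.int64))


@dataclass
class HexamerSignal:
    hexamer: str
    classification: str        # "signal" | "noise"
    peak_position: int | None
    peak_score: float


@dataclass
class PASCall:
    cluster_id: str
    hexamer: str               # RNA, or "none"
    offset: int | None         # 5'-base position of the assigned occurrence
    window: int = DEFAULT_PAS_WINDOW


@dataclass
class ChiSquareResult:
    position: int | None
    nucleotide: str
    n: int
    observed_freq: float
    expected_freq: float
    statistic: float | None
    p_value: float | None

    @property
    def defined(self) -> bool:
        return self.statistic is not None


# ---------------------------------------------------------------------------

def extract_flanks(clusters: Sequence[PolyACluster], genome: Mapping[str, str],
                   halfwidth: int = DEFAULT_HALFWIDTH) -> FlankSet:
    """Sense-strand +-halfwidth windows around cluster representatives;
    positions beyond contig edges are masked."""
    width = 2 * halfwidth + 1
    codes = np.full((len(clusters), width), 255, dtype=np.uint8)
    ids = []
    encoded = {c: _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
               for c, s in genome.items()}
    for i, cl in enumerate(clusters):
        if cl.chrom not in encoded:
            raise KeyError(f"contig {cl.chrom!r} absent from genome")
        arr = encoded[cl.chrom]
        ids.append(cl.cluster_id)
        pos = cl.representative_position
        lo, hi = pos - halfwidth, pos + halfwidth
        lo_c, hi_c = max(lo, 0), min(hi, len(arr) - 1)
        window = arr[lo_c:hi_c + 1]
        if cl.strand == "+":
            codes[i, lo_c - lo: lo_c - lo + window.size] = window
        else:
            comp = np.where(window < 4, 3 - window, window).astype(np.uint8)[::-1]
            off = hi - hi_c
            codes[i, off: off + comp.size] = comp
    return FlankSet(ids, codes, halfwidth)


def nucleotide_profile(flanks: FlankSet, order: int = 1) -> ProfileMatrix:
    """Per-position symbol frequencies over unmasked flanks; order 2
    counts overlapping dinucleotides indexed by their first base."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    h = flanks.halfwidth
    if order == 1:
        positions = np.arange(-h, h + 1)
        alphabet = _MONO_RNA
        nsym = 4
        cols = flanks.codes
        valid = cols < 4
        sym_codes = cols
    else:
        positions = np.arange(-h, h)
        alphabet = _DI_RNA
        nsym = 16
        first = flanks.codes[:, :-1]
        second = flanks.codes[:, 1:]
        valid = (first < 4) & (second < 4)
        sym_codes = (first.astype(np.int32) * 4 + second.astype(np.int32))
    n_pos = positions.size
    freq = np.zeros((n_pos, nsym))
    counts = np.zeros(n_pos, dtype=np.int64)
    for j in range(n_pos):
        v = valid[:, j]
        counts[j] = int(v.sum())
        if counts[j]:
            freq[j] = np.bincount(sym_codes[v, j], minlength=nsym) / counts[j]
    return ProfileMatrix(positions, alphabet, freq, counts, order)


def hexamer_position_scan(flanks: FlankSet,
                          scan_range: tuple[int, int] = DEFAULT_SCAN_RANGE
                          ) -> HexamerPositionTable:
    """Exact positional occurrence counts for every hexamer whose span
    lies wholly within the scan range (5'-base indexing)."""
    lo, hi = scan_range
    starts = np.arange(lo, hi - 4)          # span p..p+5 must end <= hi
    counts: dict[str, np.ndarray] = {}
    sites_with: dict[str, set | int] = {}
    occurrences: dict[str, int] = {}
    n_starts = starts.size
    if n_starts <= 0:
        return HexamerPositionTable(scan_range, np.arange(0), {}, {}, {}, len(flanks))
    for i in range(len(flanks)):
        s = flanks.sense_seq(i, lo, hi)
        seen: set[str] = set()
        for j in range(n_starts):
            hx = s[j:j + 6]
            if "N" in hx or len(hx) < 6:
                continue
            rna = to_rna(hx)
            if rna not in counts:
                counts[rna] = np.zeros(n_starts, dtype=np.int64)
            counts[rna][j] += 1
            occurrences[rna] = occurrences.get(rna, 0) + 1
            seen.add(rna)
        for rna in seen:
            sites_with[rna] = sites_with.get(rna, 0) + 1
    return HexamerPositionTable(scan_range, starts, counts, sites_with,
                                occurrences, len(flanks))


def classify_hexamer_signal(table: HexamerPositionTable, hexamer_rna: str,
                            peak_range: tuple[int, int] = (-40, -10),
                            threshold: float = 5.0) -> HexamerSignal:
    """Peak-versus-background classification of one hexamer's positional
    distribution: the peak score is the maximal count inside the expected
    PAS region divided by (median count over the whole scan + 1); a
    distribution is "signal" when the score reaches the threshold and the
    global argmax falls inside the PAS region.  Flat distributions (e.g.
    UUUUUU) score ~1 and classify as noise."""
    counts = table.counts_for(hexamer_rna).astype(float)
    if counts.size == 0 or counts.sum() == 0:
        return HexamerSignal(hexamer_rna, "noise", None, 0.0)
    positions = table.start_positions
    in_peak = (positions >= peak_range[0]) & (positions <= peak_range[1])
    background = float(np.median(counts)) + 1.0
    if not in_peak.any():
        return HexamerSignal(hexamer_rna, "noise", None, 0.0)
    peak_idx = int(np.argmax(np.where(in_peak, counts, -1.0)))
    peak_pos = int(positions[peak_idx])
    score = counts[peak_idx] / background
    global_max_pos = int(positions[int(np.argmax(counts))])
    is_signal = (score >= threshold
                 and peak_range[0] <= global_max_pos <= peak_range[1])
    return HexamerSignal(hexamer_rna, "signal" if is_signal else "noise",
                         peak_pos, float(score))


def assign_pas(flanks: FlankSet, i: int,
               priority: Sequence[str] = PAS_HEXAMERS_RNA,
               window: int = DEFAULT_PAS_WINDOW) -> PASCall:
    """PAS hexamer call for one site: the highest-priority hexamer found
    wholly within the ``window`` nt upstream of the cleavage base
    (canonical AAUAAA first).  Among several occurrences of the winning
    hexamer the one closest to the modal PAS region is chosen: the
    largest offset <= -11, else the offset nearest -11."""
    s = flanks.sense_seq(i, -window, -1)
    for rna in priority:
        dna = to_dna(rna)
        cands = []
        start = s.find(dna)
        while start != -1:
            cands.append(start - window)       # relative 5'-base offset
            start = s.find(dna, start + 1)
        if cands:
            modal = [c for c in cands if c <= -11]
            offset = max(modal) if modal else max(cands, key=lambda c: (-abs(c + 11), c))
            return PASCall(flanks.cluster_ids[i], rna, offset, window)
    return PASCall(flanks.cluster_ids[i], "none", None, window)


def assign_pas_all(flanks: FlankSet,
                   priority: Sequence[str] = PAS_HEXAMERS_RNA,
                   window: int = DEFAULT_PAS_WINDOW) -> list[PASCall]:
    return [assign_pas(flanks, i, priority, window) for i in range(len(flanks))]


def usage_frequency_table(calls: Sequence[PASCall],
                          priority: Sequence[str] = PAS_HEXAMERS_RNA
                          ) -> pd.DataFrame:
    """Per-hexamer usage percentages over all sites ("Other" = none of the
    canonical hexamers found); percentages sum to 100 up to rounding."""
    if not calls:
        return pd.DataFrame(columns=["hexamer", "count", "percent"])
    tallies = {rna: 0 for rna in priority}
    tallies["Other"] = 0
    for call in calls:
        key = call.hexamer if call.hexamer != "none" else "Other"
        tallies[key] = tallies.get(key, 0) + 1
    total = len(calls)
    return pd.DataFrame(
        [(hx, n, 100.0 * n / total) for hx, n in tallies.items()],
        columns=["hexamer", "count", "percent"])


def chisq_vs_background(n: int, observed_count: int, expected_freq: float,
                        nucleotide: str = "", position: int | None = None
                        ) -> ChiSquareResult:
    """1-df goodness of fit on the two-cell split (is-nucleotide vs not)
    against background proportions (e, 1-e)."""
    if n <= 0:
        return ChiSquareResult(position, nucleotide, 0, float("nan"),
                               expected_freq, None, None)
    obs = np.array([observed_count, n - observed_count], dtype=float)
    exp = np.array([n * expected_freq, n * (1.0 - expected_freq)])
    statistic, p = stats.chisquare(obs, f_exp=exp)
    return ChiSquareResult(position, nucleotide, n, observed_count / n,
                           expected_freq, float(statistic), float(p))


def background_freq(nucleotide_rna: str, gc: float) -> float:
    """Expected background frequency under the genome GC model:
    P(G)=P(C)=gc/2, P(A)=P(U)=(1-gc)/2."""
    return gc / 2 if nucleotide_rna in ("G", "C") else (1 - gc) / 2


def profile_chisq(profile: ProfileMatrix, position: int, nucleotide_rna: str,
                  gc: float) -> ChiSquareResult:
    n = profile.count_at(position)
    e = background_freq(nucleotide_rna, gc)
    if n == 0:
        return ChiSquareResult(position, nucleotide_rna, 0, float("nan"), e, None, None)
    x = int(round(profile.freq_of(nucleotide_rna, position) * n))
    return chisq_vs_background(n, x, e, nucleotide_rna, position)


def chisq_profile_table(profile: ProfileMatrix, gc: float,
                        bonferroni: bool = True) -> pd.DataFrame:
    """Per-position, per-nucleotide chi-square tests against background;
    a Bonferroni-adjusted column is included for transparency (the
    headline presentation is unadjusted)."""
    rows = []
    n_tests = profile.positions.size * len(profile.alphabet)
    for pos in profile.positions:
        for sym in profile.alphabet:
            r = profile_chisq(profile, int(pos), sym, gc)
            rows.append((int(pos), sym, r.n, r.observed_freq, r.expected_freq,
                         r.statistic, r.p_value,
                         min(r.p_value * n_tests, 1.0) if r.defined else None))
    return pd.DataFrame(rows, columns=["position", "nucleotide", "n",
                                       "observed_freq", "expected_freq",
                                       "statistic", "p_value", "p_bonferroni"])


def dse_enrichment(mono: ProfileMatrix, di: ProfileMatrix, gc: float,
                   window: tuple[int, int] = (3, 27),
                   far_window: tuple[int, int] = (60, 84)) -> dict:
    """Descriptive report of downstream U/GU enrichment: mean U, UU and GU
    frequencies over the downstream-sequence-element window versus the
    background expectation and a distal control window, plus the
    downstream window of the same width with maximal mean U."""
    def mean_freq(profile: ProfileMatrix, symbol: str, lo: int, hi: int) -> float:
        sel = (profile.positions >= lo) & (profile.positions <= hi)
        j = profile.alphabet.index(symbol)
        return float(profile.freq[sel, j].mean())

    lo, hi = window
    width = hi - lo + 1
    u_bg = (1 - gc) / 2
    report = {
        "window": window,
        "mean_u": mean_freq(mono, "U", lo, hi),
        "mean_u_far": mean_freq(mono, "U", *far_window),
        "expected_u": u_bg,
        "mean_uu": mean_freq(di, "UU", lo, hi - 1),
        "expected_uu": u_bg * u_bg,
        "mean_gu": mean_freq(di, "GU", lo, hi - 1),
        "expected_gu": (gc / 2) * u_bg,
    }
    down = mono.positions[(mono.positions >= 1)
                          & (mono.positions <= mono.positions.max() - width + 1)]
    best, best_start = -1.0, None
    for s in down:
        m = mean_freq(mono, "U", int(s), int(s) + width - 1)
        if m > best:
            best, best_start = m, int(s)
    report["max_u_window"] = (best_start, best_start + width - 1) if best_start else None
    report["max_u_mean"] = best
    return report
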