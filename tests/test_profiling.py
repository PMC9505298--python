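"""Flank extraction, positional profiles, hexamer scans, PAS assignment,
chi-square tests and the DSE report."""

from __future__ import annotations

import random

import numpy as np
import pytest

from pasite.dna import revcomp, to_dna
from pasite.profiling import (DEFAULT_PAS_WINDOW, FlankSet, assign_pas,
                              assign_pas_all, background_freq,
                              chisq_vs_background, classify_hexamer_signal,
                              dse_enrichment, extract_flanks,
                              hexamer_position_scan, nucleotide_profile,
                              profile_chisq, usage_frequency_table)
from pasite.sites import PolyACluster


def _cluster(pos, strand="+", chrom="chr1", cid="c1"):
    return PolyACluster(cid, chrom, strand, [pos], [1], pos, 1)


def _flanks_from_seqs(seqs: list[str]) -> FlankSet:
    """Build a FlankSet directly from equal-length sense windows (odd
    length; centre = position 0)."""
    h = len(seqs[0]) // 2
    genome = {}
    clusters = []
    for i, s in enumerate(seqs):
        genome[f"c{i}"] = s
        clusters.append(_cluster(h, chrom=f"c{i}", cid=f"cl{i}"))
    return extract_flanks(clusters, genome, halfwidth=h)


class TestExtractFlanks:
    def test_plus_strand_window(self):
        rng = random.Random(1)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        genome = {"chr1": seq}
        fl = extract_flanks([_cluster(150)], genome, 100)
        assert fl.sense_seq(0, -100, 100) == seq[50:251]
        assert fl.sense_seq(0, 0, 0) == seq[150]

    def test_minus_strand_mirror_hand_case(self):
        # 21-nt genome, - cluster at 10, halfwidth 2:
        # sense window = revcomp(genome[8..12]); position -1 holds the
        # complement of genomic base 11.
        genome = {"chr1": "AAAAAAAAGCTAGAAAAAAAA"}
        fl = extract_flanks([_cluster(10, strand="-")], genome, 2)
        assert fl.sense_seq(0, -2, 2) == revcomp(genome["chr1"][8:13])
        assert fl.sense_seq(0, -1, -1) == revcomp(genome["chr1"][11]) == "T"
        assert fl.sense_seq(0, 0, 0) == revcomp(genome["chr1"][10]) == "A"
        assert fl.sense_seq(0, -2, 2) == "CTAGC"

    def test_edge_positions_masked(self):
        genome = {"chr1": "ACGT" * 100}
        fl = extract_flanks([_cluster(40)], genome, 100)
        s = fl.sense_seq(0, -100, 100)
        assert s[:60] == "N" * 60          # positions -100..-41 masked
        assert s[60] == genome["chr1"][0]
        prof = nucleotide_profile(fl)
        assert prof.count_at(-50) == 0 and prof.count_at(0) == 1

    def test_missing_contig_raises(self):
        with pytest.raises(KeyError):
            extract_flanks([_cluster(5, chrom="nope")], {"chr1": "ACGT"}, 2)


class TestNucleotideProfile:
    def test_hand_tally_matrix(self):
        """Four hand-written 11-nt flanks reproduce a manual tally."""
        fl = _flanks_from_seqs(["AAAAACAAAAA",
                                "CCCCCACCCCC",
                                "GGGGGAGGGGG",
                                "TTTTTATTTTT"])
        prof = nucleotide_profile(fl)
        # centres: C, A, A, A
        assert prof.freq_of("A", 0) == pytest.approx(0.75)
        assert prof.freq_of("C", 0) == pytest.approx(0.25)
        # at -1 the four flanks hold A, C, G, T respectively
        assert prof.freq_of("A", -1) == pytest.approx(0.25)
        assert prof.freq_of("U", 5) == pytest.approx(0.25)
        assert prof.count_at(3) == 4

    def test_point_frequencies(self):
        fl = _flanks_from_seqs(["GCA" + "CG" * 0 + "CG",  # odd-length: 5
                                "GCAGG"])
        prof = nucleotide_profile(fl)
        assert prof.freq_of("A", 0) == 1.0
        assert prof.freq_of("C", 1) == 0.5
        assert prof.freq_of("G", 1) == 0.5

    def test_row_sums_and_dinucleotides(self, small_run):
        mono = small_run.mono_profile
        ok = mono.counts > 0
        assert np.allclose(mono.freq[ok].sum(axis=1), 1.0, atol=1e-9)
        di = small_run.di_profile
        ok2 = di.counts > 0
        assert np.allclose(di.freq[ok2].sum(axis=1), 1.0, atol=1e-9)
        assert di.positions[0] == -100 and di.positions[-1] == 99

    def test_dinucleotide_hand_case(self):
        fl = _flanks_from_seqs(["ACGTA"])
        di = nucleotide_profile(fl, order=2)
        assert di.freq_of("AC", -2) == 1.0
        assert di.freq_of("CG", -1) == 1.0
        assert di.freq_of("UA", 1) == 1.0


class TestHexamerScan:
    def test_planted_hexamer_counted_at_its_start(self):
        seqs = []
        for _ in range(3):
            s = list("G" * 101 + "C" * 100)   # 201 wide, centre index 100
            s[100 - 16:100 - 10] = to_dna("AAUAAA")   # 5' base at -16
            seqs.append("".join(s))
        fl = _flanks_from_seqs(seqs)
        table = hexamer_position_scan(fl)
        counts = table.counts_for("AAUAAA")
        idx = int(np.flatnonzero(table.start_positions == -16)[0])
        assert counts[idx] == 3
        assert counts.sum() == 3
        assert table.sites_with["AAUAAA"] == 3

    def test_overlapping_poly_u_starts(self):
        """U x 9 spanning -20..-12 yields UUUUUU occurrences at the four
        starts -20..-17 (whole-hexamer-in-range indexing)."""
        s = list("G" * 201)
        s[100 - 20:100 - 11] = "T" * 9
        fl = _flanks_from_seqs(["".join(s)])
        table = hexamer_position_scan(fl)
        counts = table.counts_for("UUUUUU")
        hits = {int(p) for p, c in zip(table.start_positions, counts) if c}
        assert hits == {-20, -19, -18, -17}
        assert table.occurrences["UUUUUU"] == 4
        assert table.sites_with["UUUUUU"] == 1

    def test_empty_scan_range(self):
        fl = _flanks_from_seqs(["ACGTACGTA"])
        table = hexamer_position_scan(fl, scan_range=(-50, -45))
        assert table.counts == {}

    def test_matches_naive_substring_oracle(self):
        """Positional counts equal an independent sliding re-scan for 50
        random hexamers over 100 random flanks."""
        rng = random.Random(3)
        seqs = ["".join(rng.choice("ACGT") for _ in range(201))
                for _ in range(100)]
        fl = _flanks_from_seqs(seqs)
        table = hexamer_position_scan(fl)
        hexamers = {to_dna(h) for h in
                    ("AAUAAA", "UUUUUU")} | {
            "".join(rng.choice("ACGT") for _ in range(6)) for _ in range(50)}
        for dna in hexamers:
            from pasite.dna import to_rna
            expected = np.zeros(len(table.start_positions), dtype=int)
            for s in seqs:
                for j, p in enumerate(table.start_positions):
                    if s[100 + p:100 + p + 6] == dna:
                        expected[j] += 1
            assert np.array_equal(table.counts_for(to_rna(dna)), expected), dna


class TestSignalClassification:
    def _table(self, counts):
        from pasite.profiling import HexamerPositionTable
        starts = np.arange(-50, -5)
        arr = np.zeros(starts.size, dtype=np.int64)
        for pos, c in counts.items():
            arr[int(np.flatnonzero(starts == pos)[0])] = c
        return HexamerPositionTable((-50, -1), starts, {"AAUAAA": arr},
                                    {"AAUAAA": 1}, {"AAUAAA": int(arr.sum())}, 1)

    def test_flat_distribution_is_noise(self):
        table = self._table({p: 7 for p in range(-50, -5)})
        sig = classify_hexamer_signal(table, "AAUAAA")
        assert sig.classification == "noise"
        assert sig.peak_score == pytest.approx(7 / 8)

    def test_delta_distribution_is_signal(self):
        table = self._table({-16: 500})
        sig = classify_hexamer_signal(table, "AAUAAA")
        assert sig.classification == "signal"
        assert sig.peak_position == -16

    def test_peak_outside_pas_region_is_noise(self):
        table = self._table({-48: 500})
        sig = classify_hexamer_signal(table, "AAUAAA")
        assert sig.classification == "noise"


def _flank_with(hexes: dict[int, str], width: int = 201) -> FlankSet:
    s = list("C" * width)
    h = width // 2
    for off, rna in hexes.items():
        s[h + off:h + off + 6] = to_dna(rna)
    return _flanks_from_seqs(["".join(s)])


class TestAssignPAS:
    def test_priority_canonical_first(self):
        fl = _flank_with({-20: "AUUAAA", -28: "AAUAAA"})
        call = assign_pas(fl, 0)
        assert call.hexamer == "AAUAAA" and call.offset == -28

    def test_scrubbed_window_gives_none(self):
        fl = _flanks_from_seqs(["C" * 201])
        assert assign_pas(fl, 0).hexamer == "none"

    def test_hexamer_overlapping_cleavage_base_ineligible(self):
        """An AAUAAA whose span crosses position 0 is not wholly upstream
        and cannot be assigned."""
        fl = _flank_with({-3: "AAUAAA"})
        assert assign_pas(fl, 0).hexamer == "none"

    def test_occurrence_closest_to_modal_region(self):
        fl = _flank_with({-29: "AAUAAA", -13: "AAUAAA"})
        assert assign_pas(fl, 0).offset == -13      # largest offset <= -11
        fl = _flank_with({-10: "AAUAAA"})
        assert assign_pas(fl, 0).offset == -10      # nearest to -11 otherwise

    def test_priority_monotone(self):
        """Adding a higher-priority hexamer never downgrades the call."""
        base = _flank_with({-20: "UAUAAA"})
        assert assign_pas(base, 0).hexamer == "UAUAAA"
        upgraded = _flank_with({-20: "UAUAAA", -30: "AAUAAA"})
        assert assign_pas(upgraded, 0).hexamer == "AAUAAA"


class TestUsageTable:
    def test_small_mix(self):
        fl = _flank_with({-20: "AAUAAA"})
        calls = assign_pas_all(fl) * 2 + [
            assign_pas(_flank_with({-20: "AUUAAA"}), 0),
            assign_pas(_flanks_from_seqs(["C" * 201]), 0)]
        table = usage_frequency_table(calls)
        pct = dict(zip(table.hexamer, table.percent))
        assert pct["AAUAAA"] == pytest.approx(50.0)
        assert pct["AUUAAA"] == pytest.approx(25.0)
        assert pct["Other"] == pytest.approx(25.0)
        assert table.percent.sum() == pytest.approx(100.0)

    def test_all_none(self):
        calls = [assign_pas(_flanks_from_seqs(["C" * 201]), 0)] * 4
        table = usage_frequency_table(calls)
        assert dict(zip(table.hexamer, table.percent))["Other"] == 100.0

    def test_empty(self):
        assert usage_frequency_table([]).empty


class TestChiSquare:
    def test_null_case(self):
        r = chisq_vs_background(1000, 318, 0.318)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_background_frequencies_from_gc(self):
        assert background_freq("A", 0.364) == pytest.approx(0.318)
        assert background_freq("U", 0.364) == pytest.approx(0.318)
        assert background_freq("G", 0.364) == pytest.approx(0.182)
        assert background_freq("C", 0.364) == pytest.approx(0.182)

    def test_hand_computed_statistic(self):
        """n=100 with 50 A observed against expected 31.8:
        (50-31.8)^2/31.8 + (50-68.2)^2/68.2 = 15.272..."""
        r = chisq_vs_background(100, 50, 0.318)
        assert r.statistic == pytest.approx(15.272, abs=1e-2)
        assert 0 < r.p_value < 1e-3

    def test_zero_n_is_undefined_not_an_exception(self):
        r = chisq_vs_background(0, 0, 0.318)
        assert not r.defined and r.p_value is None

    def test_profile_chisq_wiring(self):
        fl = _flanks_from_seqs(["GCAGC", "GCAGC"])
        prof = nucleotide_profile(fl)
        r = profile_chisq(prof, 0, "A", 0.364)
        assert r.n == 2 and r.observed_freq == 1.0 and r.defined


class TestDSE:
    def test_pure_u_downstream(self):
        s = "C" * 100 + "A" + "T" * 100
        fl = _flanks_from_seqs([s])
        mono = nucleotide_profile(fl)
        di = nucleotide_profile(fl, 2)
        rep = dse_enrichment(mono, di, gc=0.364)
        assert rep["mean_u"] == pytest.approx(1.0)
        assert rep["mean_uu"] == pytest.approx(1.0)
        assert rep["expected_u"] == pytest.approx(0.318)

    def test_background_flanks_near_expectation(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 201,
                                   p=[0.318, 0.182, 0.182, 0.318]))
                for _ in range(400)]
        fl = _flanks_from_seqs(seqs)
        mono = nucleotide_profile(fl)
        di = nucleotide_profile(fl, 2)
        rep = dse_enrichment(mono, di, gc=0.364)
        se = np.sqrt(0.318 * 0.682 / (400 * 25))
        assert abs(rep["mean_u"] - 0.318) < 4 * se
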