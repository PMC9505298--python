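"""Cleavage calling, internal-priming filter, clustering."""

from __future__ import annotations

import random

import pysam
import pytest
from hypothesis import given, strategies as hst

from pasite.dna import revcomp
from pasite.sites import (CleavageEvent, FilterConfig, apply_filter,
                          call_cleavage, cluster_events, downstream_window,
                          events_from_sam, internal_priming_filter,
                          summarize_sites)

LENGTHS = {"chr1": 1000}


def _record(pos: int, length: int = 8, reverse: bool = False,
            cigar: str | None = None, mapq: int = 60) -> pysam.AlignedSegment:
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1000}]})
    rec = pysam.AlignedSegment(header)
    rec.query_name = "r"
    rec.flag = 16 if reverse else 0
    rec.reference_id = 0
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigarstring = cigar or f"{length}M"
    rec.query_sequence = "A" * sum(
        n for op, n in rec.cigartuples if op in (0, 1, 4))
    return rec


class TestCallCleavage:
    def test_plus_strand_attachment_base(self):
        """A sense read aligned + over bases 10..17: the cleavage base is
        the poly(A) attachment base one step 3' of the last aligned base,
        i.e. position 18."""
        ev, reason = call_cleavage(_record(10, 8), LENGTHS)
        assert reason is None
        assert (ev.strand, ev.position) == ("+", 18)

    def test_minus_strand_attachment_base(self):
        """Mirror case: alignment covering 30..37 on the - strand cleaves
        one base 3' in transcription direction, position 29."""
        ev, reason = call_cleavage(_record(30, 8, reverse=True), LENGTHS)
        assert reason is None
        assert (ev.strand, ev.position) == ("-", 29)

    def test_clipped_tail_end_rejected(self):
        ev, reason = call_cleavage(_record(10, cigar="8M3S"), LENGTHS)
        assert ev is None and reason == "clipped-end"
        ev, reason = call_cleavage(_record(30, reverse=True, cigar="2S8M"),
                                   LENGTHS)
        assert ev is None and reason == "clipped-end"

    def test_clip_at_five_prime_end_is_fine(self):
        ev, reason = call_cleavage(_record(10, cigar="3S8M"), LENGTHS)
        assert reason is None and ev.position == 18
        ev, reason = call_cleavage(_record(30, reverse=True, cigar="8M2S"),
                                   LENGTHS)
        assert reason is None and ev.position == 29

    def test_contig_edge_rejected(self):
        ev, reason = call_cleavage(_record(992, 8), LENGTHS)   # ends at 999
        assert ev is None and reason == "contig-edge"
        ev, reason = call_cleavage(_record(0, 8, reverse=True), LENGTHS)
        assert ev is None and reason == "contig-edge"


class TestInternalPrimingFilter:
    """The inspected window is the 10 sense-strand bases starting at the
    cleavage (attachment) base."""

    def _genome_for_window(self, window: str, strand: str = "+"):
        if strand == "+":
            genome = {"chr1": "GG" + window + "GGGG"}
            ev = CleavageEvent("chr1", "+", 2, "r")
        else:
            genome = {"chr1": "GGGG" + revcomp(window) + "GG"}
            ev = CleavageEvent("chr1", "-", 4 + len(window) - 1, "r")
        return genome, ev

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_window_rule_nine_of_ten(self, strand):
        genome, ev = self._genome_for_window("AAAAAAAAAC", strand)
        assert downstream_window(genome, ev) == "AAAAAAAAAC"
        keep, reason = internal_priming_filter(ev, genome)
        assert not keep and reason == "window-rule"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_run_rule_eight_consecutive(self, strand):
        """A buried 8-A run trips the run rule but not the 9-of-10 window
        rule alone."""
        genome, ev = self._genome_for_window("CAAAAAAAAG", strand)
        keep, reason = internal_priming_filter(ev, genome)
        assert not keep and reason == "run-rule"
        keep, _ = internal_priming_filter(
            ev, genome, FilterConfig(mode="window"))
        assert keep

    def test_benign_window_kept_in_every_mode(self):
        genome, ev = self._genome_for_window("ACGTACGTAC")
        for mode in ("window", "run", "either"):
            keep, _ = internal_priming_filter(ev, genome,
                                              FilterConfig(mode=mode))
            assert keep

    def test_truncated_window_at_contig_edge(self):
        genome = {"chr1": "GGGAAAA"}
        ev = CleavageEvent("chr1", "+", 3, "r")
        assert downstream_window(genome, ev) == "AAAA"
        keep, _ = internal_priming_filter(ev, genome)
        assert keep

    def test_missing_contig_raises(self):
        ev = CleavageEvent("chrX", "+", 0, "r")
        with pytest.raises(KeyError, match="chrX"):
            internal_priming_filter(ev, {"chr1": "ACGT"})


def _events(positions, strand="+", chrom="chr1"):
    return [CleavageEvent(chrom, strand, p, f"r{i}")
            for i, p in enumerate(positions)]


class TestClustering:
    def test_singleton(self):
        (c,) = cluster_events(_events([100]))
        assert c.member_positions == [100]
        assert c.representative_position == 100
        assert c.total_support == 1

    def test_gap_boundaries(self):
        # gaps 15 and 25: {100,115} and {140}
        cl = cluster_events(_events([100, 115, 140]))
        assert [c.member_positions for c in cl] == [[100, 115], [140]]
        # gaps of exactly 20 chain transitively into one 40-nt cluster
        cl = cluster_events(_events([100, 120, 140]))
        assert [c.member_positions for c in cl] == [[100, 120, 140]]
        # gap 21 splits
        cl = cluster_events(_events([100, 121, 142]))
        assert [c.member_positions for c in cl] == [[100], [121], [142]]

    def test_representative_support_and_tiebreak(self):
        cl = cluster_events(_events([100, 105, 105]))
        assert cl[0].representative_position == 105
        # tie on + strand: 5'-most = smallest coordinate
        cl = cluster_events(_events([100, 105]))
        assert cl[0].representative_position == 100
        # tie on - strand: 5'-most = largest coordinate
        cl = cluster_events(_events([100, 105], strand="-"))
        assert cl[0].representative_position == 105

    def test_sources_clustered_separately_and_totals_add(self):
        ev = _events([100, 105])
        for e in ev:
            e.source_tag = "EST"
        ev2 = _events([103])
        for e in ev2:
            e.source_tag = "long-read"
        cl = cluster_events(ev + ev2)
        stats = summarize_sites(cl)
        assert stats.per_source == {"EST": 1, "long-read": 1}
        assert stats.total == 2
        merged = cluster_events(ev + ev2, merge_sources=True)
        assert len(merged) == 1

    @given(hst.lists(hst.integers(0, 500), min_size=1, max_size=60))
    def test_matches_bruteforce_single_linkage(self, positions):
        """Clustering equals an O(n^2) union-find oracle and is invariant
        to event order."""
        events = _events(positions)
        clusters = cluster_events(events)
        shuffled = list(events)
        random.Random(0).shuffle(shuffled)
        assert ([c.member_positions for c in cluster_events(shuffled)]
                == [c.member_positions for c in clusters])

        # oracle: union-find over all pairs within merge distance
        uniq = sorted(set(positions))
        parent = {p: p for p in uniq}

        def find(p):
            while parent[p] != p:
                parent[p] = parent[parent[p]]
                p = parent[p]
            return p

        for a in uniq:
            for b in uniq:
                if abs(a - b) <= 20:
                    parent[find(a)] = find(b)
        oracle: dict[int, list[int]] = {}
        for p in uniq:
            oracle.setdefault(find(p), []).append(p)
        expected = sorted(sorted(v) for v in oracle.values())
        assert sorted(c.member_positions for c in clusters) == expected

    def test_idempotent_on_representatives(self):
        clusters = cluster_events(_events([10, 25, 80, 95, 300]))
        reps = [c.representative_position for c in clusters]
        again = cluster_events(_events(reps))
        assert len(again) <= len(clusters)

    def test_strand_mirror(self):
        """Reverse complementing the coordinate system (pos -> L-1-pos,
        strand flip) yields the mirrored clusters."""
        L = 1000
        positions = [100, 105, 105, 140, 400]
        fwd = cluster_events(_events(positions, strand="+"))
        rev = cluster_events(_events([L - 1 - p for p in positions],
                                     strand="-"))
        fwd_view = sorted((sorted(c.member_positions),
                           c.representative_position) for c in fwd)
        rev_view = sorted((sorted(L - 1 - p for p in c.member_positions),
                           L - 1 - c.representative_position) for c in rev)
        assert fwd_view == rev_view

    def test_empty_input(self):
        assert cluster_events([]) == []


def test_summarize_member_fractions():
    clusters = cluster_events(
        _events([100]) + _events([200, 210], chrom="chr2")
        + _events([400, 410, 420, 430, 440], chrom="chr3"))
    stats = summarize_sites(clusters)
    assert stats.total == 3
    assert stats.fraction_one == pytest.approx(1 / 3)
    assert stats.fraction_two == pytest.approx(1 / 3)
    assert stats.fraction_several == pytest.approx(1 / 3)


def test_events_from_sam_skips_unanchored(tmp_path):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1000}]}
    path = tmp_path / "t.sam"
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        fh.write(_record(10, 8))                     # ok -> event at 18
        fh.write(_record(50, cigar="8M3S"))          # clipped 3' end
        low = _record(70, 8, mapq=0)                 # multi-mapper floor
        fh.write(low)
    events, counts = events_from_sam(path, {"chr1": 1000})
    assert [e.position for e in events] == [18]
    assert counts["clipped-end"] == 1 and counts["low_mapq"] == 1
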