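"""Seed-chain-extend aligner vs an exhaustive alignment-score oracle.

The oracle is an independent score-only Gotoh dynamic program over the full
doubled genome (no seeding, no windowing, no traceback); the implementation
must reach the same optimal local score.
"""

import numpy as np
import pytest
from oracles import PARAMS, oracle_best_score

from circends.align import (AlignParams, KmerIndex, align_end_to_end,
                            align_local, extract_clips, group_segments)
from circends.genome import CircularGenome, revcomp


class TestKmerIndex:
    def test_every_position_indexed(self):
        g = CircularGenome("c", "ACGTACGG")
        idx = KmerIndex(g, k=4)
        assert sorted(p for ps in idx._fwd.values() for p in ps) == list(range(8))

    def test_origin_spanning_kmer_present(self):
        g = CircularGenome("c", "ACGTACGG")
        idx = KmerIndex(g, k=4)
        assert 6 in idx.positions("GGAC")  # wraps GG|AC

    def test_k_longer_than_genome(self):
        with pytest.raises(ValueError):
            KmerIndex(CircularGenome("c", "ACGTACGGTT"), k=20)


class TestAlignLocal:
    def test_exact_substring_is_full_match(self, genome, index):
        a = align_local(genome.sequence[5000:5100], index, genome)
        assert (a.qstart, a.qend, a.gstart, a.gend) == (0, 100, 5000, 5100)
        assert a.cigar == "100M" and a.edit_distance == 0 and a.strand == "+"

    def test_minus_strand_placement(self, genome, index):
        a = align_local(revcomp(genome.sequence[7000:7090]), index, genome)
        assert (a.gstart, a.gend, a.strand) == (7000, 7090, "-")

    def test_origin_spanning_read(self, genome, index):
        L = genome.length
        seq = genome.sequence[-60:] + genome.sequence[:60]
        a = align_local(seq, index, genome)
        assert a.gstart == L - 60 and a.gend == L + 60
        assert a.edit_distance == 0

    def test_chimeric_read_is_soft_clipped(self, genome, index):
        seq = genome.sequence[5000:5060] + genome.sequence[9000:9060]
        a = align_local(seq, index, genome)
        assert a.read_span == 60 and "60S" in a.cigar
        assert a.score == oracle_best_score(seq, genome)

    def test_random_sequence_unaligned(self, genome, index):
        rng = np.random.default_rng(30)
        seq = "".join(rng.choice(list("ACGT"), size=30))
        assert oracle_best_score(seq, genome) < PARAMS.min_score
        assert align_local(seq, index, genome) is None

    def test_score_matches_oracle_on_simulated_reads(self, genome, annotation, index):
        """Error-free library reads reach the oracle's optimal score."""
        from circends.readprep import prepare_pairs
        from circends.simulate import SimConfig, make_default_templates, simulate_library
        tpl = make_default_templates(annotation, "WT", L=genome.length)
        sim = simulate_library(tpl, genome, SimConfig(n_molecules=15, seed=31))
        reads, _ = prepare_pairs(sim.pairs, sim.config.adapter1, sim.config.adapter2)
        sample = reads[:40]
        assert len(sample) == 40
        for r in sample:
            a = align_local(r.seq, index, genome)
            assert a is not None
            assert a.score == oracle_best_score(r.seq, genome), r.read_id

    def test_placed_sequence_matches_genome_within_edits(self, genome, annotation, index):
        from circends.readprep import prepare_pairs
        from circends.simulate import SimConfig, make_default_templates, simulate_library
        tpl = make_default_templates(annotation, "WT", L=genome.length)
        sim = simulate_library(tpl, genome,
                               SimConfig(n_molecules=10, seed=32,
                                         substitution_error_rate=0.005))
        reads, _ = prepare_pairs(sim.pairs, sim.config.adapter1, sim.config.adapter2)
        for r in reads[:30]:
            a = align_local(r.seq, index, genome)
            if a is None or "I" in a.cigar or "D" in a.cigar:
                continue
            t = r.seq if a.strand == "+" else revcomp(r.seq)
            gseq = genome.fetch(a.gstart, a.gend)
            mism = sum(x != y for x, y in zip(t[a.qstart:a.qend], gseq))
            assert mism == a.edit_distance

    def test_circular_consistency_under_rotation(self, genome, index):
        """Aligning against the genome rotated by r shifts coordinates by r."""
        r = 4321
        rot = CircularGenome("rot", genome.sequence[r:] + genome.sequence[:r])
        rot_index = KmerIndex(rot)
        for start in (100, 5000, 12000):
            seq = genome.fetch(start, start + 120)
            a = align_local(seq, index, genome)
            b = align_local(seq, rot_index, rot)
            assert a is not None and b is not None
            assert (b.gstart + r) % genome.length == a.gstart % genome.length
            assert b.score == a.score


class TestExtractClips:
    def _seg(self, cigar, qstart, qend, read_len):
        from circends.align import SegmentAlignment
        return SegmentAlignment("r", "whole", qstart, qend, 0, qend - qstart,
                                "+", cigar, 0, 0), read_len

    def test_left_clip(self):
        seg, n = self._seg("45S100M", 45, 145, 145)
        assert extract_clips(seg, n) == [("left", 0, 45)]

    def test_short_clip_ignored(self):
        seg, n = self._seg("100M8S", 0, 100, 108)
        assert extract_clips(seg, n) == []

    def test_both_clips(self):
        seg, n = self._seg("30S90M30S", 30, 120, 150)
        assert extract_clips(seg, n) == [("left", 0, 30), ("right", 120, 150)]


class TestAlignEndToEnd:
    def test_exact_45mer(self, genome):
        a = align_end_to_end(genome.sequence[3000:3045], genome)
        assert (a.gstart, a.gend, a.edit_distance) == (3000, 3045, 0)
        assert a.cigar == "45M"

    def test_too_many_edits_rejected(self, genome):
        seq = list(genome.sequence[3000:3045])
        for i in (2, 9, 16, 23, 30, 37):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        assert align_end_to_end("".join(seq), genome) is None  # 6 > max(2, 4)

    def test_tail_bearing_clip_rejected(self, genome):
        clip = "A" * 8 + genome.sequence[4000:4020]
        assert align_end_to_end(clip, genome) is None  # 8 edits > max(2, 2)

    def test_tie_breaks_to_lowest_coordinate(self):
        unit = "ACGGTTCAGGCCATTAGCAATGCGTAGGTC"
        g = CircularGenome("dup", unit + "T" * 50 + unit + "G" * 50)
        a = align_end_to_end(unit, g)
        assert a.gstart == 0


class TestGroupSegments:
    def _seg(self, qstart, qend, gstart, score=100, part="middle", strand="+"):
        from circends.align import SegmentAlignment
        return SegmentAlignment("r", part, qstart, qend, gstart,
                                gstart + (qend - qstart), strand,
                                f"{qend - qstart}M", 0, score)

    def test_ordering_and_completeness(self):
        g = group_segments([self._seg(45, 145, 5000), self._seg(0, 45, 9000, part="left")],
                           read_len=145)
        assert [s.part for s in g.segments] == ["left", "middle"]
        assert g.complete

    def test_unplaced_stretch_marks_incomplete(self):
        g = group_segments([self._seg(0, 100, 5000, part="middle")], read_len=140)
        assert not g.complete

    def test_accounted_tail_interval_counts_as_placed(self):
        g = group_segments([self._seg(0, 100, 5000)], read_len=130,
                           accounted=[(100, 130)])
        assert g.complete

    def test_conflicting_duplicates_keep_higher_score(self):
        g = group_segments([self._seg(0, 100, 5000, score=150),
                            self._seg(5, 105, 8000, score=90)], read_len=105)
        assert len(g.segments) == 1 and g.segments[0].gstart == 5000
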