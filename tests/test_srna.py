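"""Small-RNA tail classification, feature assignment and statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from circends.align import SegmentAlignment
from circends.monomerize import Monomer
from circends.srna import (SmallRNA, TailAnnotation, assign_feature, cca_ratio,
                           detect_tail, extract_srnas, length_histogram,
                           polya_proportion, srna_from_monomer)


def _placement(gstart, body, strand="+", tail_clip=0, rid="r"):
    cigar = f"{body}M" + (f"{tail_clip}S" if tail_clip else "")
    return SegmentAlignment(rid, "whole", 0, body, gstart, gstart + body,
                            strand, cigar, 0, 2 * body)


def _srna(genome, gstart, body, tail_seq="", strand="+", rid="r"):
    seq = genome.fetch(gstart, gstart + body, strand) + tail_seq
    p = _placement(gstart if strand == "+" else gstart,
                   body, strand=strand, tail_clip=len(tail_seq), rid=rid)
    tail = detect_tail(seq, p, genome)
    return SmallRNA(read_id=rid, seq=seq, placement=p, tail=tail)


class TestDetectTail:
    def test_nontemplated_cca(self, genome):
        pos = 3000
        if genome.sequence[pos + 25:pos + 28] == "CCA":
            pos += 100
        s = _srna(genome, pos, 25, "CCA")
        assert s.tail == TailAnnotation("CCA", 3, templated=False)

    def test_nontemplated_polya(self, genome):
        pos = genome.sequence.find("GTC", 2000)
        s = _srna(genome, pos - 25, 25, "AAAAA")
        if genome.sequence[pos:pos + 5] == "AAAAA":  # pathological; not in toy
            pytest.skip("flank encodes the run")
        assert s.tail.kind == "polyA" and s.tail.length == 5
        assert not s.tail.templated

    def test_run_of_two_is_no_tail(self, genome):
        # body must not itself end in A, or the run would be longer than 2
        pos = next(p for p in range(4000, 5000) if genome.sequence[p + 24] != "A")
        s = _srna(genome, pos, 25, "AA")
        assert s.tail.kind == "none"

    def test_templated_a_run_is_body(self, genome):
        """A trailing A-run that the genome encodes at the flank is body."""
        pos = genome.sequence.find("AAA", 1000)
        body_start = pos - 22
        seq = genome.fetch(body_start, pos) + "AAA"  # genome encodes AAA at flank
        p = _placement(body_start, 22, tail_clip=3)
        tail = detect_tail(seq, p, genome)
        assert tail.kind == "none" and tail.templated

    def test_cca_beats_polya(self, genome):
        pos = 5000
        s = _srna(genome, pos, 25, "AACCA")
        assert s.tail.kind == "CCA"


class TestAssignFeature:
    def test_trna_with_extension(self, genome, annotation):
        f = annotation["tRNA-K"]
        s = _srna(genome, f.end - 20, 20, "CCA", rid="t")
        assign_feature(s, annotation, genome.length)
        assert s.feature_class == "tRNA" and s.feature.gene_id == "tRNA-K"

    def test_below_80pct_overlap_not_trna(self, genome, annotation):
        f = annotation["tRNA-K"]
        # 20 nt body with only 10 inside the tRNA
        s = _srna(genome, f.end - 10, 20, rid="t")
        assign_feature(s, annotation, genome.length)
        assert s.feature_class != "tRNA"

    def test_interior_polya_fragment_is_mrna(self, genome, annotation):
        f = annotation["mRNA-CO1"]
        s = _srna(genome, f.start + 200, 25, "AAAAAA")
        assign_feature(s, annotation, genome.length)
        assert s.feature_class == "mRNA" and s.feature.gene_id == "mRNA-CO1"

    def test_canonical_polya_at_mrna_end_excluded(self, genome, annotation):
        f = annotation["mRNA-CO1"]
        s = _srna(genome, f.end - 25, 25, "AAAAAA")
        assert s.tail.kind == "polyA"
        assign_feature(s, annotation, genome.length)
        assert s.feature_class == "unassigned"

    def test_rrna_containment(self, genome, annotation):
        f = annotation["rRNA-12S"]
        s = _srna(genome, f.start + 50, 30)
        assign_feature(s, annotation, genome.length)
        assert s.feature_class == "rRNA"

    def test_partition(self, genome, annotation):
        """Every candidate lands in exactly one class."""
        rng = np.random.default_rng(60)
        classes = set()
        for _ in range(40):
            start = int(rng.integers(0, genome.length - 60))
            s = _srna(genome, start, int(rng.integers(16, 40)))
            assign_feature(s, annotation, genome.length)
            assert s.feature_class in {"tRNA", "rRNA", "mRNA", "unassigned"}
            classes.add(s.feature_class)
        assert "unassigned" in classes  # intergenic/partial placements exist


class TestExtractSrnas:
    def _mono(self, n, copies, collapsed=True):
        return Monomer("r", "A" * n, n, copies, 1.0, collapsed)

    def test_length_and_copy_gates(self):
        assert extract_srnas([self._mono(22, 5.0)])
        assert not extract_srnas([self._mono(300, 3.0)])
        assert not extract_srnas([self._mono(22, 1.2)])
        assert not extract_srnas([self._mono(22, 3.0, collapsed=False)])


class TestCcaRatio:
    def test_ratio_and_missing(self, genome, annotation):
        f = annotation["tRNA-K"]
        srnas = []
        for i in range(10):
            tail = "CCA" if i < 8 else ""
            s = _srna(genome, f.end - 22, 22, tail, rid=f"r{i}")
            assign_feature(s, annotation, genome.length)
            srnas.append(s)
        tab = cca_ratio(srnas, annotation, genome.length).set_index("gene")
        assert tab.loc["tRNA-K", "ratio"] == pytest.approx(0.8)
        assert np.isnan(tab.loc["tRNA-V", "ratio"])  # no reads there


class TestPolyaProportion:
    def _rep(self, genome, annotation, gene, n, n_polya, rid_prefix):
        f = annotation[gene]
        out = []
        for i in range(n):
            tail = "AAAAAA" if i < n_polya else ""
            s = _srna(genome, f.start + 100, 25, tail, rid=f"{rid_prefix}:{i}")
            assign_feature(s, annotation, genome.length)
            out.append(s)
        return out

    def test_matches_closed_form_t(self, genome, annotation):
        """Proportions (0.1,0.2,0.3) vs (0.2,0.3,0.4) reproduce the pooled-
        variance Student's t statistic computed from the textbook formula."""
        reps_a = [self._rep(genome, annotation, "mRNA-CO1", 10, k, f"a{k}")
                  for k in (1, 2, 3)]
        reps_b = [self._rep(genome, annotation, "mRNA-CO1", 10, k, f"b{k}")
                  for k in (2, 3, 4)]
        out = polya_proportion({"WT": reps_a, "KO": reps_b}).set_index("gene")
        row = out.loc["mRNA-CO1"]
        a, b = np.array([0.1, 0.2, 0.3]), np.array([0.2, 0.3, 0.4])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_expect = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        p_expect = 2 * sps.t.sf(abs(t_expect), df=4)
        assert row["t"] == pytest.approx(t_expect)
        assert row["p"] == pytest.approx(p_expect)

    def test_identical_groups_p_one(self, genome, annotation):
        reps = [self._rep(genome, annotation, "mRNA-CO1", 10, 1, f"x{i}")
                for i in range(3)]
        out = polya_proportion({"WT": reps, "KO": reps}).set_index("gene")
        assert out.loc["mRNA-CO1", "p"] == 1.0

    def test_separation_with_zero_variance(self, genome, annotation):
        a = [self._rep(genome, annotation, "mRNA-CO1", 10, 1, f"a{i}") for i in range(3)]
        b = [self._rep(genome, annotation, "mRNA-CO1", 10, 3, f"b{i}") for i in range(3)]
        out = polya_proportion({"WT": a, "KO": b}).set_index("gene")
        assert out.loc["mRNA-CO1", "p"] == 0.0

    def test_single_replicate_skips_test(self, genome, annotation):
        a = [self._rep(genome, annotation, "mRNA-CO1", 10, 1, "a")]
        b = [self._rep(genome, annotation, "mRNA-CO1", 10, 3, "b")]
        out = polya_proportion({"WT": a, "KO": b}).set_index("gene")
        assert np.isnan(out.loc["mRNA-CO1", "p"])
        assert out.loc["mRNA-CO1", "mean_WT"] == pytest.approx(0.1)


class TestSrnaFromMonomer:
    def test_rotation_canonicalised(self, genome, annotation, index):
        from circends.links import call_from_monomer
        f = annotation["tRNA-K"]
        rna = genome.fetch(f.start, f.end, "+") + "CCA"
        monomer = rna[40:] + rna[:40]
        call = call_from_monomer(monomer, "m", index, genome, annotation)
        assert call is not None
        mono = Monomer("m", monomer, len(monomer), 3.0, 1.0, True)
        s = srna_from_monomer(mono, call, genome, annotation)
        assert s.seq == rna  # back in transcript orientation, tail last
        assert s.tail.kind == "CCA"
        assert s.feature_class == "tRNA"


class TestLengthHistogram:
    def test_bimodal(self, genome):
        srnas = [_srna(genome, 1000, n, rid=f"r{n}:{i}")
                 for n in (19, 22) for i in range(3)]
        h = length_histogram(srnas).set_index("length")
        assert h.loc[19, "count"] == 3 and h.loc[22, "count"] == 3
        assert h["count"].sum() == 6

    def test_empty(self):
        h = length_histogram([])
        assert (h["count"] == 0).all()
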