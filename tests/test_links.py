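"""Junction calling, link aggregation, fold changes and Circos export."""

import numpy as np
import pandas as pd
import pytest

from circends.align import SegmentAlignment, SplitGroup
from circends.genome import revcomp
from circends.links import (PrecursorCall, aggregate, call_from_monomer,
                            call_precursor, compare_links, export_circos,
                            parse_circos_links, split_fraction)


def _seg(qstart, qend, gstart, strand="+", part="middle", rid="r"):
    return SegmentAlignment(rid, part, qstart, qend, gstart,
                            gstart + (qend - qstart), strand,
                            f"{qend - qstart}M", 0, 2 * (qend - qstart))


def _group(segments, read_len, accounted=None):
    from circends.align import group_segments
    return group_segments(segments, read_len, accounted=accounted or [])


class TestCallPrecursor:
    def _junction_read(self, genome, five, three, flank=60, tail=""):
        """Read crossing the ligation junction: ...three | tail | five..."""
        a = genome.fetch(three - flank + 1, three + 1)
        b = genome.fetch(five, five + flank)
        return a + tail + b

    def test_plus_strand_junction(self, genome):
        five, three = 2000, 3500
        seq = self._junction_read(genome, five, three)
        segs = [_seg(0, 60, three - 59), _seg(60, 120, five)]
        call = call_precursor(_group(segs, 120), genome, seq=seq)
        assert call is not None
        assert (call.five_prime, call.three_prime, call.strand) == (five, three, "+")
        assert call.support_class == "junction_spanning"

    def test_minus_strand_roles_mirror(self, genome):
        # molecule on the minus strand covering [lo, lo+200); 5' end at lo+199;
        # pick a locus whose junction is unambiguous (the base after the
        # body's genome end differs from the body's first base)
        lo = next(p for p in range(3000, 4000)
                  if genome.sequence[p + 200] != genome.sequence[p])
        flank = 50
        rna = genome.fetch(lo, lo + 200, "-")
        read = rna[-flank:] + rna[:flank]  # 3' end then 5' start
        t = revcomp(read)
        segs = [_seg(0, flank, lo + 150, strand="-"),
                _seg(flank, 2 * flank, lo, strand="-")]
        call = call_precursor(_group(segs, 2 * flank), genome, seq=t)
        assert call is not None
        assert (call.five_prime, call.three_prime, call.strand) == (lo + 199, lo, "-")

    def test_contiguous_segments_are_not_links(self, genome):
        segs = [_seg(0, 60, 5000), _seg(60, 120, 5060)]
        seq = genome.fetch(5000, 5120)
        assert call_precursor(_group(segs, 120), genome, seq=seq) is None

    def test_whole_read_single_gene_no_call(self, genome):
        g = _group([_seg(0, 120, 5000, part="whole")], 120)
        assert call_precursor(g, genome, seq=genome.fetch(5000, 5120)) is None

    def test_polya_tail_recorded_and_excluded_from_termini(self, genome):
        # unambiguous flanks: neither side of the junction continues the A-run
        five = next(p for p in range(2000, 3000) if genome.sequence[p - 1] != "A")
        three = next(p for p in range(3500, 4500) if genome.sequence[p + 1] != "A")
        seq = self._junction_read(genome, five, three, tail="A" * 12)
        segs = [_seg(0, 60, three - 59), _seg(72, 132, five)]
        call = call_precursor(_group(segs, 132, accounted=[(60, 72)]), genome, seq=seq)
        assert call is not None
        assert (call.five_prime, call.three_prime) == (five, three)
        assert (call.tail_kind, call.tail_len) == ("polyA", 12)

    def test_inconsistent_triple_is_chimera(self, genome):
        segs = [_seg(0, 40, 1000, part="left"), _seg(40, 140, 5000),
                _seg(140, 180, 9000, part="right")]
        seq = (genome.fetch(960, 1000) + genome.fetch(5000, 5100)
               + genome.fetch(9000, 9040))
        assert call_precursor(_group(segs, 180), genome, seq=seq) is None

    def test_mixed_strand_group_rejected(self, genome):
        segs = [_seg(0, 60, 1000, strand="+"), _seg(60, 120, 5000, strand="-")]
        g = SplitGroup("r", segs, complete=True, read_len=120)
        assert call_precursor(g, genome, seq="A" * 120) is None


class TestCallFromMonomer:
    def test_collapsed_trna_with_cca(self, genome, annotation, index):
        f = annotation["tRNA-K"]
        rna = genome.fetch(f.start, f.end, f.strand) + "CCA"
        rot = 31
        monomer = rna[rot:] + rna[:rot]
        call = call_from_monomer(monomer, "m", index, genome, annotation)
        assert call is not None
        assert (call.five_prime, call.three_prime) == (f.start, f.end - 1)
        assert call.tail_kind == "CCA"
        assert call.support_class == "rotation_consistent"

    def test_minus_strand_monomer(self, genome, annotation, index):
        f = annotation["tRNA-Q"]
        rna = genome.fetch(f.start, f.end, "-") + "CCA"
        monomer = rna[10:] + rna[:10]
        call = call_from_monomer(monomer, "m", index, genome, annotation)
        assert call is not None
        assert (call.five_prime, call.three_prime, call.strand) == (f.end - 1, f.start, "-")
        assert call.tail_kind == "CCA"

    def test_unmappable_monomer(self, genome, index):
        rng = np.random.default_rng(40)
        monomer = "".join(rng.choice(list("ACGT"), size=40))
        assert call_from_monomer(monomer, "m", index, genome) is None


class TestAggregateAndFractions:
    def _call(self, five, three, strand="+", rid="r", n_genes=2):
        return PrecursorCall(read_id=rid, five_prime=five, three_prime=three,
                             strand=strand, junction_in_read=0,
                             support_class="junction_spanning", n_genes_spanned=n_genes)

    def test_identical_calls_pool(self, annotation, genome):
        calls = [self._call(100, 500, rid=f"r{i}") for i in range(3)]
        table, profile = aggregate(calls, annotation, genome.length)
        assert len(table) == 1 and table.loc[0, "read_count"] == 3
        assert profile.five["+"][100] == 3 and profile.three["+"][500] == 3

    def test_conservation(self, annotation, genome):
        calls = [self._call(100, 500), self._call(700, 900, rid="r2"),
                 self._call(100, 500, rid="r3")]
        table, profile = aggregate(calls, annotation, genome.length)
        assert table["read_count"].sum() == len(calls)
        assert profile.five["+"].sum() == len(calls)

    def test_split_fraction_bounds(self):
        assert split_fraction(10, []) == 0.0
        calls = [self._call(1, 2, rid=f"r{i}") for i in range(10)]
        assert split_fraction(10, calls) == 1.0
        with pytest.raises(ValueError):
            split_fraction(0, [])


class TestCompareLinks:
    def _table(self, rows, total):
        df = pd.DataFrame(rows, columns=["five_prime", "three_prime", "strand",
                                         "read_count"])
        df["n_genes"] = 2
        df["classes"] = "mRNA;tRNA"
        df["cpm"] = df["read_count"] * 1e6 / total
        return df

    def test_identical_tables_zero(self):
        t = self._table([(1, 2, "+", 5)], 1000)
        fc = compare_links(t, t)
        assert (fc["log2fc"] == 0).all()

    def test_pseudocount_arithmetic(self):
        a = self._table([(1, 2, "+", 1)], 10 ** 6)  # cpm 1
        b = self._table([], 10 ** 6)
        fc = compare_links(a, b, pseudocount=1.0)
        assert fc.loc[0, "log2fc"] == pytest.approx(1.0)  # log2((1+1)/1)

    def test_antisymmetry(self):
        rng = np.random.default_rng(41)
        rows_a = [(i, i + 100, "+", int(rng.integers(1, 50))) for i in range(8)]
        rows_b = [(i, i + 100, "+", int(rng.integers(1, 50))) for i in range(2, 10)]
        a, b = self._table(rows_a, 5000), self._table(rows_b, 7000)
        ab = compare_links(a, b).set_index(["five_prime", "three_prime"])
        ba = compare_links(b, a).set_index(["five_prime", "three_prime"])
        assert np.allclose(ab["log2fc"], -ba.loc[ab.index, "log2fc"])

    def test_requires_cpm(self):
        t = pd.DataFrame({"five_prime": [1], "three_prime": [2], "strand": ["+"],
                          "read_count": [1], "n_genes": [2], "classes": ["x"]})
        with pytest.raises(ValueError, match="cpm"):
            compare_links(t, t)


class TestCircosExport:
    def test_round_trip(self, annotation, genome, tmp_path):
        table = pd.DataFrame({"five_prime": [100, 7000], "three_prime": [500, 9000],
                              "strand": ["+", "-"], "read_count": [7, 2]})
        links = tmp_path / "links.txt"
        kar = tmp_path / "karyotype.txt"
        export_circos(table, annotation, genome, links, kar)
        back = parse_circos_links(links)
        pd.testing.assert_frame_equal(
            back, table[["five_prime", "three_prime", "strand", "read_count"]])
        assert kar.read_text().startswith("chr -")

    def test_empty_table_valid_karyotype(self, annotation, genome, tmp_path):
        table = pd.DataFrame(columns=["five_prime", "three_prime", "strand",
                                      "read_count"])
        links = tmp_path / "links.txt"
        kar = tmp_path / "karyotype.txt"
        export_circos(table, annotation, genome, links, kar)
        assert links.read_text() == ""
        assert len(kar.read_text().splitlines()) == 1 + len(annotation)
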