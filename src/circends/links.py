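"""Infer molecule termini ("links") from split read placements.

A circularized molecule read across its ligation junction shows its 3' end
immediately followed by its 5' end. After split alignment, two adjacent
segments of one read whose genome placements are non-contiguous therefore
pin both termini of the original linear molecule: on the plus strand the
earlier segment ends at the molecule's 3' nucleotide and the later segment
starts at its 5' nucleotide; on the minus strand the roles mirror (segments
live in transcript-sense read coordinates against the forward genome).

Non-templated tails complicate the junction: a 3'-CCA or short poly(A) sits
between the two segments in read coordinates. Such gap sequence is
recognised, recorded on the call, and excluded from the termini — otherwise
every tailed molecule's 3' end would be mis-assigned.

Collapsed rolling-circle monomers carry the junction between their own
ends; doubling the monomer and aligning it linearises the molecule, and the
single contiguous placement gives both termini directly
(``call_from_monomer``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignParams, KmerIndex, SplitGroup, align_local
from .genome import AnnotationSet, CircularGenome, revcomp

__all__ = [
    "PrecursorCall",
    "EndProfile",
    "call_precursor",
    "call_from_monomer",
    "aggregate",
    "split_fraction",
    "compare_links",
    "export_circos",
    "parse_circos_links",
]

MAX_TAIL = 45  # longest non-templated junction tail considered (poly(A))
REFINE_WINDOW = 60


@dataclass
class PrecursorCall:
    """Termini of one original molecule, inferred from one read."""

    read_id: str
    five_prime: int
    three_prime: int
    strand: str
    junction_in_read: int
    support_class: str  # junction_spanning | rotation_consistent
    tail_kind: str = "none"
    tail_len: int = 0
    n_genes_spanned: int = 0
    classes: tuple[str, ...] = ()
    wraps_origin: bool = False

    def molecule_interval(self, L: int) -> tuple[int, int]:
        """Plus-strand genome interval [lo, lo+len) of the molecule body."""
        if self.strand == "+":
            lo = self.five_prime
            length = (self.three_prime - self.five_prime) % L + 1
        else:
            lo = self.three_prime
            length = (self.five_prime - self.three_prime) % L + 1
        return lo, lo + length


@dataclass
class EndProfile:
    """Per-position 5'-end and 3'-end counts for both strands."""

    L: int
    five: dict[str, np.ndarray]
    three: dict[str, np.ndarray]
    normalization: str = "raw"
    library_total: int = 0

    @classmethod
    def zeros(cls, L: int) -> "EndProfile":
        return cls(L=L, five={"+": np.zeros(L), "-": np.zeros(L)},
                   three={"+": np.zeros(L), "-": np.zeros(L)})

    def to_cpm(self, library_total: int) -> "EndProfile":
        if self.normalization == "CPM":
            raise ValueError("profile already CPM-normalized")
        if library_total <= 0:
            raise ValueError("library_total must be positive")
        f = 1e6 / library_total
        return EndProfile(L=self.L,
                          five={s: v * f for s, v in self.five.items()},
                          three={s: v * f for s, v in self.three.items()},
                          normalization="CPM", library_total=library_total)


def _refine_junction(seq: str, a, b, genome: CircularGenome,
                     window: int = REFINE_WINDOW,
                     max_tail: int = MAX_TAIL):
    """Mismatch-minimising split-point search around a candidate junction.

    ``a`` and ``b`` are the junction-flanking segments in strand-resolved
    read coordinates against the forward genome. Within a window around
    the junction every read base is assigned to segment A's diagonal, a
    non-templated tail (empty, CCA, or an A-run — reverse-complemented in
    these coordinates on the minus strand), or segment B's diagonal, and
    the assignment with the fewest genome mismatches wins. Ties prefer the
    longest A-side body (templated bases are body, not tail), then the
    shortest tail. This makes the called termini independent of exactly
    where the local aligner stopped extending.

    Returns (cost, n_compared, j1, j2, tail_kind, tail_len) or None; the
    A body ends at read position j1 - 1 and the B body starts at j2.
    """
    L = genome.length
    g = genome.sequence
    lo = max(a.qstart + 1, min(a.qend, b.qstart) - window)
    hi = min(b.qend - 1, max(a.qend, b.qstart) + window, len(seq) - 1)
    if lo >= hi:
        return None
    strand = a.strand
    a_char = "A" if strand == "+" else "T"
    cca = "CCA" if strand == "+" else "TGG"
    span = np.arange(lo, hi + 1)
    seq_w = np.frombuffer(seq[lo:hi + 1].encode(), dtype=np.uint8)

    def _mismatch_cumsum(diag: int) -> np.ndarray:
        gd = np.frombuffer("".join(g[(p + diag) % L] for p in span).encode(), np.uint8)
        return np.concatenate([[0], np.cumsum(seq_w != gd)])

    # a segment that over-extended across the junction (possibly with an
    # indel) has a corrupted anchor on that side, so try both anchors and
    # keep the cheapest explanation
    diags_a = {a.gstart - a.qstart, a.gend - a.qend}
    diags_b = {b.gstart - b.qstart, b.gend - b.qend}
    best = None
    for da in diags_a:
        ca = _mismatch_cumsum(da)
        for db in diags_b:
            cb = _mismatch_cumsum(db)
            total_b = cb[-1]
            for j1 in range(lo, hi + 2):
                cost_a = ca[j1 - lo]
                cands = [(j1, "none", 0)]
                if seq[j1:j1 + 3] == cca:
                    cands.append((j1 + 3, "CCA", 3))
                run = 0
                while (j1 + run <= hi and run < max_tail
                       and seq[j1 + run] == a_char):
                    run += 1
                    if run >= 3:
                        cands.append((j1 + run, "polyA", run))
                for j2, kind, tlen in cands:
                    if j2 > hi + 1:
                        continue
                    cost = cost_a + (total_b - cb[j2 - lo])
                    key = (cost, -j1, tlen)
                    if best is None or key < best[0]:
                        best = (key, j1, j2, kind, tlen, da, db)
    if best is None:
        return None
    key, j1, j2, kind, tlen, da, db = best
    n_compared = (hi + 1 - lo) - (j2 - j1)
    return int(key[0]), int(n_compared), j1, j2, kind, tlen, da, db


def _annotate(call: PrecursorCall, annotation: AnnotationSet | None, L: int) -> PrecursorCall:
    lo, hi = call.molecule_interval(L)
    call.wraps_origin = hi > L
    if annotation is not None:
        feats = annotation.overlapping(lo, hi, L, strand=call.strand)
        call.n_genes_spanned = len(feats)
        call.classes = tuple(sorted({f.biotype for f in feats}))
    return call


def call_precursor(group: SplitGroup, genome: CircularGenome,
                   annotation: AnnotationSet | None = None, seq: str = "",
                   contiguity_tol: int = 2,
                   min_molecule_len: int = 20) -> PrecursorCall | None:
    """Junction call from a split group, or None.

    Adjacent segments separated by more than ``contiguity_tol`` on the
    genome define a junction. All junctions of a three-part
    (left/middle/right) group must agree within the tolerance — consistent
    with being successive rolling-circle copies — or the read is discarded
    as chimeric. ``seq`` is the strand-resolved read sequence, used to
    classify tail bases sitting in the junction gap.
    """
    if not group.complete or len(group.segments) < 2:
        return None
    strand = group.strand
    if strand is None:
        return None  # mixed-strand chimera
    L = genome.length
    junctions: list[tuple[int, int, int, str, int]] = []
    for a, b in zip(group.segments, group.segments[1:]):
        read_gap = b.qstart - a.qend
        expected = (a.gend + read_gap) % L
        diff = (b.gstart - expected) % L
        if min(diff, L - diff) <= contiguity_tol:
            continue  # one genomic locus; alignment jitter only
        refined = _refine_junction(seq, a, b, genome) if seq else None
        if refined is None:
            return None  # no usable junction context
        cost, n_compared, j1, j2, tail_kind, tail_len, da, db = refined
        if cost > max(2, 0.15 * n_compared):
            return None  # unexplained sequence at the junction: chimera
        end_a = (j1 - 1 + da) % L
        start_b = (j2 + db) % L
        if strand == "+":
            three, five = end_a, start_b
        else:
            five, three = end_a, start_b
        junctions.append((five, three, j1, tail_kind, tail_len))
    if not junctions:
        return None
    five0, three0 = junctions[0][0], junctions[0][1]
    for five, three, *_ in junctions[1:]:
        d5 = min((five - five0) % L, (five0 - five) % L)
        d3 = min((three - three0) % L, (three0 - three) % L)
        if d5 > contiguity_tol or d3 > contiguity_tol:
            return None  # inconsistent junctions: chimera
    # prefer a tail-bearing junction's annotation (the gap was observable there)
    tailed = [j for j in junctions if j[3] != "none"]
    five, three, joff, tail_kind, tail_len = (tailed or junctions)[0]
    support = "rotation_consistent" if len(junctions) > 1 else "junction_spanning"
    call = PrecursorCall(read_id=group.read_id, five_prime=five, three_prime=three,
                         strand=strand, junction_in_read=joff, support_class=support,
                         tail_kind=tail_kind, tail_len=tail_len)
    mol_len = (three - five) % L + 1 if strand == "+" else (five - three) % L + 1
    if not (min_molecule_len <= mol_len <= L):
        return None
    return _annotate(call, annotation, L)


def call_from_monomer(monomer_seq: str, read_id: str, index: KmerIndex,
                      genome: CircularGenome,
                      annotation: AnnotationSet | None = None,
                      params: AlignParams = AlignParams(),
                      contiguity_tol: int = 2) -> PrecursorCall | None:
    """Termini of a collapsed rolling-circle monomer.

    The doubled monomer contains the full molecule contiguously regardless
    of the rotation at which reverse transcription entered the circle; its
    single best local placement spans the molecule body, and the unaligned
    remainder of one period holds any non-templated tail.
    """
    import dataclasses

    P = len(monomer_seq)
    L = genome.length
    if P < 15 or P > L:
        return None
    aln = align_local(monomer_seq * 2, index, genome, params=params, read_id=read_id)
    if aln is None:
        return None
    body = aln.qend - aln.qstart
    # over-extension across the junction is tolerated (the refinement
    # re-derives the boundaries); placements far from one period are not
    if body > P + 30 or body < P - MAX_TAIL - contiguity_tol:
        return None
    # refine on a tripled context: the extra period gives the B side enough
    # downstream bases to reject coincidental local matches on a wrong
    # diagonal (e.g. after an indel-corrupted anchor)
    t_context = (monomer_seq * 3 if aln.strand == "+"
                 else revcomp(monomer_seq * 3))
    # the next rolling-circle copy maps to the same locus one period later
    # (same diagonals shifted by one period in read coordinates)
    pseudo_b = dataclasses.replace(aln, qstart=aln.qstart + P,
                                   qend=aln.qend + P)
    refined = _refine_junction(t_context, aln, pseudo_b, genome)
    if refined is None:
        return None
    cost, n_compared, j1, j2, tail_kind, tail_len, da, db = refined
    if cost > max(2, 0.15 * n_compared):
        return None
    end_a = (j1 - 1 + da) % L
    start_b = (j2 + db) % L
    if aln.strand == "+":
        three, five = end_a, start_b
    else:
        five, three = end_a, start_b
    call = PrecursorCall(read_id=read_id, five_prime=five, three_prime=three,
                         strand=aln.strand, junction_in_read=j1,
                         support_class="rotation_consistent",
                         tail_kind=tail_kind, tail_len=tail_len)
    return _annotate(call, annotation, L)


def aggregate(calls: list[PrecursorCall], annotation: AnnotationSet | None,
              L: int, condition: str = "",
              library_total: int | None = None) -> tuple[pd.DataFrame, EndProfile]:
    """Pool identical calls into a link table and fill end profiles.

    The link table has one row per distinct (5', 3', strand) with its read
    count (reads are not de-duplicated: abundance is read-level), the genes
    its molecule spans, and — when ``library_total`` is given — a CPM
    column.
    """
    profile = EndProfile.zeros(L)
    rows = []
    for c in calls:
        profile.five[c.strand][c.five_prime] += 1
        profile.three[c.strand][c.three_prime] += 1
        rows.append((c.five_prime, c.three_prime, c.strand,
                     c.n_genes_spanned, ";".join(c.classes)))
    cols = ["five_prime", "three_prime", "strand", "n_genes", "classes"]
    if not rows:
        table = pd.DataFrame(columns=cols + ["read_count"])
    else:
        df = pd.DataFrame(rows, columns=cols)
        table = (df.groupby(cols, as_index=False).size()
                   .rename(columns={"size": "read_count"}))
    table["condition"] = condition
    if library_total:
        table["cpm"] = table["read_count"] * 1e6 / library_total
        profile.library_total = library_total
    return table.sort_values(["strand", "five_prime", "three_prime"],
                             ignore_index=True), profile


def split_fraction(n_aligned_reads: int, calls: list[PrecursorCall]) -> float:
    """Fraction of genome-aligned reads whose call spans more than one gene."""
    if n_aligned_reads <= 0:
        raise ValueError("no aligned reads")
    multi = sum(1 for c in calls if c.n_genes_spanned >= 2)
    return multi / n_aligned_reads


def compare_links(table_a: pd.DataFrame, table_b: pd.DataFrame,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-link log2 fold change between two CPM-normalised link tables.

    Links absent from one condition enter with CPM 0; the pseudocount keeps
    every ratio finite. log2FC is A over B.
    """
    for t, name in ((table_a, "A"), (table_b, "B")):
        if "cpm" not in t.columns:
            raise ValueError(f"table {name} lacks a cpm column (not CPM-normalised)")
    key = ["five_prime", "three_prime", "strand"]
    a = table_a[key + ["cpm", "n_genes", "classes"]].rename(columns={"cpm": "cpm_a"})
    b = table_b[key + ["cpm"]].rename(columns={"cpm": "cpm_b"})
    merged = a.merge(b, on=key, how="outer")
    for col in ("cpm_a", "cpm_b"):
        merged[col] = merged[col].astype(float).fillna(0.0)
    merged["log2fc"] = np.log2((merged["cpm_a"] + pseudocount) /
                               (merged["cpm_b"] + pseudocount))
    return merged.sort_values(key, ignore_index=True)


_BIOTYPE_COLORS = {"rRNA": "green", "mRNA": "blue", "tRNA": "grey",
                   "ncRNA": "orange", "dloop": "purple"}


def export_circos(link_table: pd.DataFrame, annotation: AnnotationSet | None,
                  genome: CircularGenome, links_path: str | Path,
                  karyotype_path: str | Path) -> None:
    """Write Circos link and karyotype text files (1-based inclusive)."""
    chrom = genome.name
    with open(links_path, "w") as fh:
        for row in link_table.itertuples():
            fh.write(f"{chrom} {row.five_prime + 1} {row.five_prime + 1} "
                     f"{chrom} {row.three_prime + 1} {row.three_prime + 1} "
                     f"thickness={row.read_count},strand={row.strand}\n")
    with open(karyotype_path, "w") as fh:
        fh.write(f"chr - {chrom} {chrom} 0 {genome.length} grey\n")
        if annotation is not None:
            for f in annotation:
                color = _BIOTYPE_COLORS.get(f.biotype, "black")
                fh.write(f"band {chrom} {f.gene_id} {f.gene_id} "
                         f"{f.start} {min(f.end, genome.length)} {color}\n")


def parse_circos_links(path: str | Path) -> pd.DataFrame:
    """Read a link file written by :func:`export_circos` back into a table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 7:
                continue
            opts = dict(kv.split("=") for kv in parts[6].split(","))
            rows.append((int(parts[1]) - 1, int(parts[4]) - 1,
                         opts.get("strand", "+"), int(opts["thickness"])))
    return pd.DataFrame(rows, columns=["five_prime", "three_prime", "strand",
                                       "read_count"])
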