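"""Small-RNA extraction and 3'-tail classification.

Small RNAs are recovered from the rolling-circle repeats: a monomer
collapsed from at least two tandem copies, 15-60 nt long, is a candidate.
Each candidate is rotated into transcript orientation (5' to 3', tail last)
using its genome placement, its 3' tail is classified (CCA, short poly(A),
or none, with CCA taking precedence), and it is assigned to a gene class by
a strand-aware overlap cascade:

* tRNA — the body overlaps a same-strand tRNA by at least 80% (3'
  extensions beyond the tRNA, e.g. the CCA, are allowed);
* rRNA / mRNA — the body is entirely inside a same-strand feature and the
  3' terminus is not at the feature's annotated 3' end (a poly(A) there is
  the canonical mRNA tail, not a decay mark);
* unassigned otherwise.

A trailing A-run that the genome itself encodes at the placement's 3' flank
is part of the body, never a poly(A) tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import SegmentAlignment
from .genome import AnnotationSet, CircularGenome, GeneFeature, overlap_fraction, revcomp
from .links import PrecursorCall
from .monomerize import Monomer

__all__ = [
    "TailAnnotation",
    "SmallRNA",
    "extract_srnas",
    "detect_tail",
    "assign_feature",
    "srna_from_monomer",
    "cca_ratio",
    "polya_proportion",
    "length_histogram",
]

MIN_TAIL = 3
MAX_POLYA = 20


@dataclass(frozen=True)
class TailAnnotation:
    kind: str  # none | CCA | polyA
    length: int
    templated: bool = False


@dataclass
class SmallRNA:
    read_id: str
    seq: str  # transcript orientation, tail (if any) at the 3' end
    placement: SegmentAlignment
    tail: TailAnnotation
    feature: GeneFeature | None = None
    feature_class: str = "unassigned"  # tRNA | rRNA | mRNA | unassigned

    @property
    def body_len(self) -> int:
        return len(self.seq) - self.tail.length


def extract_srnas(monomers: list[Monomer], min_len: int = 15,
                  max_len: int = 60, min_copies: float = 2.0) -> list[Monomer]:
    """Candidate small RNAs: collapsed repeats in the length window."""
    return [m for m in monomers
            if m.was_collapsed and m.copies >= min_copies
            and min_len <= len(m.monomer_seq) <= max_len]


def _three_prime_flank(placement: SegmentAlignment, genome: CircularGenome,
                       n: int) -> str:
    """Genome sequence continuing n nt past the placement's 3' terminus,
    in transcript sense."""
    L = genome.length
    if placement.strand == "+":
        return genome.fetch(placement.gend % L, placement.gend % L + n, "+")
    start = (placement.gstart - n) % L
    return genome.fetch(start, start + n, "-")


def detect_tail(seq: str, placement: SegmentAlignment,
                genome: CircularGenome) -> TailAnnotation:
    """Classify the 3' tail of a transcript-oriented sequence.

    Exact trailing ``CCA`` beats a trailing A-run of 3-20 nt. The tail is
    templated when the genome encodes the identical bases immediately past
    the placement's 3' end; a fully templated A-run is body, not poly(A).
    """
    cand: tuple[str, int] | None = None
    if seq.endswith("CCA"):
        cand = ("CCA", 3)
    else:
        run = len(seq) - len(seq.rstrip("A"))
        if run >= MIN_TAIL:
            cand = ("polyA", min(run, MAX_POLYA))
    if cand is None:
        return TailAnnotation("none", 0)
    kind, tlen = cand
    bases = seq[-tlen:]
    aligned_through = placement.qend >= len(seq)
    flank = _three_prime_flank(placement, genome, tlen)
    templated = aligned_through or bases == flank
    if kind == "polyA" and templated:
        return TailAnnotation("none", 0, templated=True)
    return TailAnnotation(kind, tlen, templated=templated)


def assign_feature(srna: SmallRNA, annotation: AnnotationSet, L: int) -> SmallRNA:
    """Strand-aware overlap cascade assigning each candidate to one class."""
    p = srna.placement
    if p.strand == "+":
        body = (p.gstart, p.gstart + srna.body_len)
        terminus = (body[1] - 1) % L
    else:
        body = (p.gend - srna.body_len, p.gend)
        terminus = body[0] % L
    best_trna = None
    for f in annotation.of_biotype("tRNA"):
        if f.strand != p.strand:
            continue
        frac = overlap_fraction(body, f, L)
        if frac >= 0.8 and (best_trna is None or frac > best_trna[0]):
            best_trna = (frac, f)
    if best_trna is not None:
        srna.feature, srna.feature_class = best_trna[1], "tRNA"
        return srna
    for f in annotation:
        if f.biotype not in ("rRNA", "mRNA") or f.strand != p.strand:
            continue
        if overlap_fraction(body, f, L) >= 1.0 - 1e-9:
            if srna.tail.kind == "polyA" and terminus == f.three_prime_terminal(L):
                continue  # canonical 3' poly(A) tail, not a decay fragment
            srna.feature, srna.feature_class = f, f.biotype
            return srna
    srna.feature, srna.feature_class = None, "unassigned"
    return srna


def srna_from_monomer(monomer: Monomer, call: PrecursorCall,
                      genome: CircularGenome,
                      annotation: AnnotationSet | None = None) -> SmallRNA:
    """Canonical small RNA from a collapsed monomer and its junction call.

    The monomer is an arbitrary rotation of the molecule; the call's
    junction offset rotates it back so the 5' end leads and the tail
    trails, after which tail detection and feature assignment apply.
    """
    L = genome.length
    t_mono = monomer.monomer_seq if call.strand == "+" else revcomp(monomer.monomer_seq)
    P = len(t_mono)
    lo, hi = call.molecule_interval(L)
    body_len = hi - lo
    qs = (call.junction_in_read - body_len) % P
    canonical = t_mono[qs:] + t_mono[:qs]
    placement = SegmentAlignment(
        read_id=monomer.read_id, part="whole", qstart=0, qend=body_len,
        gstart=lo % L, gend=lo % L + body_len, strand=call.strand,
        cigar=f"{body_len}M" + (f"{P - body_len}S" if P > body_len else ""),
        edit_distance=0, score=2 * body_len)
    tail = detect_tail(canonical, placement, genome)
    srna = SmallRNA(read_id=monomer.read_id, seq=canonical,
                    placement=placement, tail=tail)
    if annotation is not None:
        assign_feature(srna, annotation, L)
    return srna


def _covers(placement: SegmentAlignment, pos: int, L: int) -> bool:
    off = (pos - placement.gstart) % L
    return off < placement.ref_span


def cca_ratio(srnas: list[SmallRNA], annotation: AnnotationSet, L: int) -> pd.DataFrame:
    """Per-tRNA ratio of CCA-bearing to total reads at the 3' terminal nt.

    tRNAs with no read covering the terminal nucleotide report NaN.
    """
    rows = []
    for f in annotation.of_biotype("tRNA"):
        pos = f.three_prime_terminal(L)
        at_end = [s for s in srnas
                  if s.feature_class == "tRNA" and s.feature is not None
                  and s.feature.gene_id == f.gene_id
                  and _covers(s.placement, pos, L)]
        n_total = len(at_end)
        n_cca = sum(1 for s in at_end if s.tail.kind == "CCA")
        rows.append((f.gene_id, n_total, n_cca,
                     n_cca / n_total if n_total else np.nan))
    return pd.DataFrame(rows, columns=["gene", "n_total", "n_cca", "ratio"])


def polya_proportion(replicates_by_condition: dict[str, list[list[SmallRNA]]],
                     genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene polyadenylated proportion per replicate, with a two-sided
    equal-variance Student's t-test between the two conditions.

    With fewer than two replicates in either condition only the proportions
    are reported. Identical groups report p = 1; complete separation with
    zero within-group variance reports p = 0.
    """
    conds = list(replicates_by_condition)
    per_gene: dict[str, dict[str, list[float]]] = {}
    for cond, reps in replicates_by_condition.items():
        for rep in reps:
            counts: dict[str, list[int]] = {}
            for s in rep:
                if s.feature_class in ("mRNA", "rRNA") and s.feature is not None:
                    tot_pa = counts.setdefault(s.feature.gene_id, [0, 0])
                    tot_pa[0] += 1
                    if s.tail.kind == "polyA":
                        tot_pa[1] += 1
            for gene, (tot, pa) in counts.items():
                per_gene.setdefault(gene, {c: [] for c in conds})[cond].append(
                    pa / tot if tot else np.nan)
    rows = []
    for gene, by_cond in sorted(per_gene.items()):
        if genes is not None and gene not in genes:
            continue
        row = {"gene": gene}
        for c in conds:
            row[f"props_{c}"] = by_cond[c]
            row[f"mean_{c}"] = float(np.nanmean(by_cond[c])) if by_cond[c] else np.nan
        if len(conds) == 2 and all(len(by_cond[c]) >= 2 for c in conds):
            a = np.asarray(by_cond[conds[0]], dtype=float)
            b = np.asarray(by_cond[conds[1]], dtype=float)
            if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
                if np.allclose(a.mean(), b.mean()):
                    t, p = 0.0, 1.0
                else:
                    t, p = np.inf if a.mean() > b.mean() else -np.inf, 0.0
            else:
                with warnings.catch_warnings():
                    # nearly identical replicate proportions trip scipy's
                    # precision-loss warning; the guard above handles the
                    # exactly-identical case
                    warnings.simplefilter("ignore", RuntimeWarning)
                    t, p = stats.ttest_ind(a, b, equal_var=True)
            row["t"], row["p"] = float(t), float(p)
        else:
            row["t"], row["p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def length_histogram(srnas: list[SmallRNA], min_len: int = 15,
                     max_len: int = 60) -> pd.DataFrame:
    """Counts of small RNAs by body length (tail excluded)."""
    counts = {n: 0 for n in range(min_len, max_len + 1)}
    for s in srnas:
        n = s.body_len
        if min_len <= n <= max_len:
            counts[n] += 1
    return pd.DataFrame({"length": list(counts), "count": list(counts.values())})
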