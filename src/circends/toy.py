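"""Deterministic toy circular genome with a mitochondria-like gene layout.

The layout mirrors a vertebrate mitochondrial genome: two rRNAs up front,
mRNAs punctuated by interleaved tRNA genes (the punctuation marks the
processing sites), a handful of light-strand tRNAs and one light-strand
mRNA, and a non-coding control region at the end. Sequence content is
random (seeded), so alignment behaves like it does on a real organellar
genome without shipping one.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .genome import AnnotationSet, CircularGenome, GeneFeature

__all__ = ["toy_genome", "toy_annotation", "write_fasta", "write_bed"]

# (gene_id, biotype, length, strand) in genome order; compact like real mtDNA
_LAYOUT = [
    ("tRNA-F", "tRNA", 68, "+"),
    ("rRNA-12S", "rRNA", 950, "+"),
    ("tRNA-V", "tRNA", 69, "+"),
    ("rRNA-16S", "rRNA", 1550, "+"),
    ("tRNA-L1", "tRNA", 75, "+"),
    ("mRNA-ND1", "mRNA", 950, "+"),
    ("tRNA-I", "tRNA", 69, "+"),
    ("tRNA-Q", "tRNA", 72, "-"),
    ("tRNA-M", "tRNA", 68, "+"),
    ("mRNA-ND2", "mRNA", 1040, "+"),
    ("tRNA-W", "tRNA", 68, "+"),
    ("tRNA-A", "tRNA", 69, "-"),
    ("tRNA-N", "tRNA", 73, "-"),
    ("tRNA-C", "tRNA", 66, "-"),
    ("tRNA-Y", "tRNA", 66, "-"),
    ("mRNA-CO1", "mRNA", 1540, "+"),
    ("tRNA-S1", "tRNA", 69, "-"),
    ("tRNA-D", "tRNA", 68, "+"),
    ("mRNA-CO2", "mRNA", 684, "+"),
    ("tRNA-K", "tRNA", 70, "+"),
    ("mRNA-ATP8", "mRNA", 204, "+"),
    ("mRNA-ATP6", "mRNA", 680, "+"),
    ("mRNA-CO3", "mRNA", 784, "+"),
    ("tRNA-G", "tRNA", 68, "+"),
    ("mRNA-ND3", "mRNA", 345, "+"),
    ("tRNA-R", "tRNA", 65, "+"),
    ("mRNA-ND4", "mRNA", 1378, "+"),
    ("tRNA-H", "tRNA", 69, "+"),
    ("tRNA-S2", "tRNA", 59, "+"),
    ("tRNA-L2", "tRNA", 71, "+"),
    ("mRNA-ND5", "mRNA", 1824, "+"),
    ("mRNA-ND6", "mRNA", 528, "-"),
    ("tRNA-E", "tRNA", 69, "-"),
    ("mRNA-CYTB", "mRNA", 1144, "+"),
    ("tRNA-T", "tRNA", 67, "+"),
    ("tRNA-P", "tRNA", 66, "-"),
]


def toy_genome(L: int = 16299, seed: int = 1234, name: str = "chrM_toy") -> CircularGenome:
    """Random-sequence circular genome of length ``L`` (seeded).

    Boundary contexts are made junction-decodable: on a fully random
    sequence the base following a molecule's 3' end can by chance equal its
    5'-start base (or continue a tail homopolymer), in which case the exact
    ligation-junction position is information-theoretically ambiguous from
    reads alone. Real genomes carry the ambiguity they carry; a ground-truth
    simulator must not, or it cannot verify junction recovery. The fixer
    below mutates single bases flanking each laid-out gene boundary until no
    default template's junction is ambiguous.
    """
    gene_total = sum(n for _, _, n, _ in _LAYOUT)
    if L < gene_total + 100:
        raise ValueError(f"L must leave room for the control region (>= {gene_total + 100})")
    rng = np.random.default_rng(seed)
    seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=L)]))
    genome = CircularGenome(name=name, sequence="".join(seq))
    annotation = toy_annotation(genome)
    _deambiguate(seq, annotation, L)
    return CircularGenome(name=name, sequence="".join(seq))


def _junction_constraints(annotation, L: int):
    """(position, forbidden) pairs making every default template decodable.

    ``forbidden`` is either a literal base or a genome position whose
    current base must differ. Constraint per template with body [lo, hi)
    and tail kind K (transcript-sense coordinates against the forward
    genome; poly(A) appears as a T-run on the minus strand):

    * no tail: base at hi must differ from base at lo (else the junction
      slides by one at zero cost);
    * poly(A): base at hi must not continue the tail homopolymer, and base
      at lo-1 must not start it (else tail/body assignment is ambiguous);
    * CCA: base at hi must not start the tail and base at lo-1 must not
      end it (else the three tail bases can be reassigned to the flanking
      bodies at zero cost).
    """
    from .simulate import make_default_templates

    constraints: list[tuple[int, object]] = []
    for scenario in ("WT", "KO"):
        for t in make_default_templates(annotation, scenario, L=L):
            lo, hi = t.body_interval(L)
            pa, pb = hi % L, (lo - 1) % L
            a_char = "A" if t.strand == "+" else "T"
            cca_t = "CCA" if t.strand == "+" else "TGG"
            if t.tail == "none":
                constraints.append((pa, lo % L))
            elif t.tail == "polyA":
                constraints.append((pa, a_char))
                constraints.append((pb, a_char))
            elif t.tail == "CCA":
                constraints.append((pa, cca_t[0]))
                constraints.append((pb, cca_t[2]))
    return constraints


def _deambiguate(seq: list[str], annotation, L: int, max_rounds: int = 5) -> None:
    constraints = _junction_constraints(annotation, L)
    bases = "ACGT"
    for _ in range(max_rounds):
        by_pos: dict[int, set[str]] = {}
        for pos, forb in constraints:
            banned = seq[forb] if isinstance(forb, int) else forb
            if seq[pos] == banned:
                by_pos.setdefault(pos, set()).add(banned)
        if not by_pos:
            return
        for pos, _ in by_pos.items():
            banned_all = {seq[f] if isinstance(f, int) else f
                          for p, f in constraints if p == pos}
            banned_all.add(seq[pos])
            for b in bases:
                if b not in banned_all:
                    seq[pos] = b
                    break
    raise RuntimeError("could not de-ambiguate toy genome boundaries")


def toy_annotation(genome: CircularGenome) -> AnnotationSet:
    """Gene features laid out back-to-back, control region filling the rest."""
    feats = []
    pos = 0
    for gene_id, biotype, length, strand in _LAYOUT:
        feats.append(GeneFeature(gene_id=gene_id, biotype=biotype,
                                 start=pos, end=pos + length, strand=strand))
        pos += length
    feats.append(GeneFeature(gene_id="dloop-CR", biotype="dloop",
                             start=pos, end=genome.length, strand="+"))
    ann = AnnotationSet(features=feats, genome_name=genome.name)
    ann.validate_against(genome)
    return ann


def reference_template_panel(annotation: AnnotationSet, L: int):
    """Fixed 10-template molecule panel for parameter-recovery studies.

    Four mature species (an rRNA, a polyadenylated mRNA, and one CCA-bearing
    tRNA per strand), four multi-gene precursors spanning unprocessed tRNA
    boundaries, and two degradation intermediates with ORF-internal termini.
    Weights: 0.70 mature, 0.24 precursor, 0.06 degradation.
    """
    from .simulate import make_default_templates, _reweight

    pool = {t.template_id: t for t in make_default_templates(annotation, "WT", L=L)}
    mature_ids = ["mature:rRNA-12S", "mature:mRNA-CO1", "mature:tRNA-K",
                  "mature:tRNA-Q"]
    precursor_ids = [tid for tid in pool if tid.startswith("precursor:")][:4]
    deg_ids = ["deg:mRNA-ND1", "deg:mRNA-ND2"]
    panel = []
    for tid in mature_ids:
        panel.append(_reweight(pool[tid], 0.70 / 4))
    for tid in precursor_ids:
        panel.append(_reweight(pool[tid], 0.24 / 4))
    for tid in deg_ids:
        panel.append(_reweight(pool[tid], 0.06 / 2))
    assert len(panel) == 10
    return panel


def write_fasta(genome: CircularGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i:i + 70] + "\n")


def write_bed(annotation: AnnotationSet, path: str | Path,
              chrom: str | None = None) -> None:
    chrom = chrom or annotation.genome_name or "chrM_toy"
    with open(path, "w") as fh:
        for f in annotation:
            fh.write(f"{chrom}\t{f.start}\t{f.end}\t{f.gene_id}\t0\t{f.strand}\n")
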