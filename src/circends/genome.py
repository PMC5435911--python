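"""Circular genome model with strand-aware gene annotation.

A mitochondrial genome is a single circular DNA molecule; both strands are
transcribed end to end, and genes (rRNAs, mRNAs, tRNAs, the non-coding
D-loop) sit on either strand. Everything downstream — read placement,
junction calling, coverage — needs wraparound-safe coordinate arithmetic,
which is centralised here.

Conventions
-----------
* Internal coordinates are 0-based half-open. Exported reports use 1-based
  inclusive positions.
* An interval may have ``end > L`` to denote a feature or molecule spanning
  the origin; positions are normalised modulo L on demand.
* The annotated ``+`` strand of the reference is the heavy strand;
  light-strand sequence is obtained by reverse complement, never by
  re-indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "BIOTYPES",
    "CircularGenome",
    "GeneFeature",
    "AnnotationSet",
    "load_genome",
    "load_annotation",
    "overlap_fraction",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Closed set of feature classes the pipeline understands.
BIOTYPES = frozenset({"tRNA", "rRNA", "mRNA", "ncRNA", "dloop"})

_VALID_CHARS = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """A single circular reference sequence.

    Attributes
    ----------
    name : str
        Sequence name (used as the chromosome name in SAM/BEDGraph output).
    sequence : str
        Upper-case DNA over ``{A, C, G, T, N}``.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence is empty")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(f"illegal characters in genome sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)``, wrapping through the origin.

        ``strand='-'`` returns the reverse complement of the plus-strand
        sequence (i.e. the light-strand transcript sense).
        """
        L = self.length
        if end <= start:
            raise ValueError(f"empty or inverted interval [{start}, {end})")
        if end - start > L:
            raise ValueError(f"interval longer than genome: {end - start} > {L}")
        span_len = end - start
        start %= L
        span = self.fetch_span(start, start + span_len)
        return span if strand == "+" else revcomp(span)

    def fetch_span(self, start: int, end: int) -> str:
        """Plus-strand fetch helper; ``start`` already in ``[0, L)``."""
        L = self.length
        if end <= L:
            return self.sequence[start:end]
        return self.sequence[start:] + self.fetch_span(0, end - L)

    def doubled(self) -> str:
        """Genome concatenated with itself — linearises origin-spanning hits."""
        return self.sequence + self.sequence


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the circular genome.

    ``start``/``end`` are 0-based half-open; ``end`` may exceed the genome
    length for an origin-spanning feature. ``strand`` is ``+`` (heavy) or
    ``-`` (light).
    """

    gene_id: str
    biotype: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r} for {self.gene_id}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad coordinates for {self.gene_id}: [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def three_prime_terminal(self, L: int) -> int:
        """Genome position of the last transcribed (3'-most) nucleotide."""
        return (self.end - 1) % L if self.strand == "+" else self.start

    def five_prime_terminal(self, L: int) -> int:
        return self.start if self.strand == "+" else (self.end - 1) % L


@dataclass
class AnnotationSet:
    """Ordered collection of gene features for one genome."""

    features: list[GeneFeature]
    genome_name: str = ""
    _by_id: dict[str, GeneFeature] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.gene_id for f in self.features]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_ids: {dup}")
        self._by_id = {f.gene_id: f for f in self.features}

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, gene_id: str) -> GeneFeature:
        return self._by_id[gene_id]

    def validate_against(self, genome: CircularGenome) -> None:
        L = genome.length
        for f in self.features:
            if f.start >= L or f.length > L:
                raise ValueError(f"{f.gene_id} out of range for genome of length {L}")

    def of_biotype(self, biotype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.biotype == biotype]

    def overlapping(self, start: int, end: int, L: int, strand: str | None = None) -> list[GeneFeature]:
        """Features with >=1 nt circular overlap with ``[start, end)``."""
        out = []
        for f in self.features:
            if strand is not None and f.strand != strand:
                continue
            if _circular_intersection(start, end, f.start, f.end, L) > 0:
                out.append(f)
        return out


def load_genome(path: str | Path) -> CircularGenome:
    """Read a single-record FASTA as the circular reference.

    The sequence is upper-cased and RNA ``U`` converted to ``T``. Multiple
    records are an error: the pipeline targets a single organellar genome.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(f"multiple records in {path}; expected a single circular genome")
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    return CircularGenome(name=rec.id, sequence=seq)


def _biotype_from_name(name: str) -> str:
    for prefix, biotype in (("tRNA", "tRNA"), ("rRNA", "rRNA"), ("mRNA", "mRNA"),
                            ("ncRNA", "ncRNA"), ("dloop", "dloop")):
        if name.startswith(prefix):
            return biotype
    raise ValueError(f"cannot infer biotype from feature name {name!r}; "
                     "expected a tRNA-/rRNA-/mRNA-/ncRNA-/dloop- prefix")


def load_annotation(path: str | Path, fmt: str | None = None) -> AnnotationSet:
    """Read gene features from BED6 or GFF3 into 0-based half-open form.

    BED is 0-based half-open with the biotype taken from the name-column
    prefix (``tRNA-X`` etc.). GFF3 is 1-based inclusive, converted on read,
    with the biotype from the record type or a ``biotype=`` attribute.
    """
    path = Path(path)
    if fmt is None:
        fmt = "GFF3" if path.suffix.lower() in (".gff", ".gff3") else "BED"
    fmt = fmt.upper()
    if fmt == "BED":
        features = list(_parse_bed(path))
    elif fmt == "GFF3":
        features = list(_parse_gff3(path))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    names = {ln for ln in (getattr(f, "_chrom", None) for f in features) if ln}
    return AnnotationSet(features=features, genome_name=next(iter(names), ""))


def _parse_bed(path: Path) -> Iterable[GeneFeature]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 6:
                raise ValueError(f"BED6 line with {len(cols)} columns: {line!r}")
            chrom, start, end, name, _score, strand = cols[:6]
            start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                raise ValueError(f"BED interval with end <= start: {line!r}")
            feat = GeneFeature(gene_id=name, biotype=_biotype_from_name(name),
                               start=start_i, end=end_i, strand=strand)
            object.__setattr__(feat, "_chrom", chrom)
            yield feat


def _parse_gff3(path: Path) -> Iterable[GeneFeature]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"GFF3 line with {len(cols)} columns: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols[:9]
            attr_map = {}
            for item in attrs.strip(";").split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = attr_map.get("ID") or attr_map.get("Name")
            if gene_id is None:
                raise ValueError(f"GFF3 record without ID/Name attribute: {line!r}")
            biotype = attr_map.get("biotype", ftype)
            if biotype not in BIOTYPES:
                biotype = _biotype_from_name(gene_id)
            start_i, end_i = int(start) - 1, int(end)  # 1-based inclusive -> 0-based half-open
            if end_i <= start_i:
                raise ValueError(f"GFF3 interval with end < start: {line!r}")
            feat = GeneFeature(gene_id=gene_id, biotype=biotype,
                               start=start_i, end=end_i, strand=strand)
            object.__setattr__(feat, "_chrom", chrom)
            yield feat


def _circular_intersection(s1: int, e1: int, s2: int, e2: int, L: int) -> int:
    """Length of the intersection of two arcs on a circle of circumference L."""
    s1, e1 = s1 % L, s1 % L + min(e1 - s1, L)
    s2, e2 = s2 % L, s2 % L + min(e2 - s2, L)
    total = 0
    for shift in (-L, 0, L):
        total += max(0, min(e1, e2 + shift) - max(s1, s2 + shift))
    return min(total, min(e1 - s1, e2 - s2))


def overlap_fraction(interval: tuple[int, int], feature: GeneFeature | tuple[int, int], L: int) -> float:
    """Fraction of ``interval`` covered by ``feature`` on the circle.

    Returns ``|interval ∩ feature| / |interval|``; both may span the origin.
    """
    s1, e1 = interval
    if isinstance(feature, GeneFeature):
        s2, e2 = feature.start, feature.end
    else:
        s2, e2 = feature
    inter = _circular_intersection(s1, e1, s2, e2, L)
    return inter / (e1 - s1)
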