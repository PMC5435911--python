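"""Ground-truth simulator for circularized-RNA sequencing libraries.

The library chemistry being emulated: RNA molecules with defined 5'/3'
termini are circularized by single-stranded ligation; remaining linear
molecules are destroyed by RNase R (so only circles yield reads);
random-primed reverse transcription proceeds rolling-circle around each
circle, producing cDNAs that are tandem repeats of the molecule entered at a
random rotation; second-strand synthesis tags the cDNA, which is then
fragmented and sequenced as 250 bp paired-end reads. A read that crosses the
ligation junction carries the molecule's 3' end immediately followed by its
5' end — the signal every downstream stage exists to recover.

Tail chemistry is part of the molecule: mature tRNAs carry a non-templated
3'-CCA, and mRNA decay fragments may carry short non-templated poly(A)
tails. Tails are appended *before* circularization, so the junction reads
``...tail|5'-end...``.

Every simulated molecule and read is recorded in truth tables so junction
recovery, abundance contrasts and tail statistics can be scored exactly.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AnnotationSet, CircularGenome, GeneFeature

__all__ = [
    "TranscriptTemplate",
    "SimConfig",
    "SimResult",
    "make_default_templates",
    "simulate_library",
    "truth_end_table",
    "write_fastq_pairs",
]

# Read-through adapters: the reverse complements of the RT / second-strand
# tagging primer stems, i.e. what a short insert runs into at its 3' end.
DEFAULT_ADAPTER1 = "AGATCGGAAGAGCACACGTC"
DEFAULT_ADAPTER2 = "AGATCGGAAGAGCGTCGTGT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TranscriptTemplate:
    """One molecular species in the input RNA population.

    ``five_prime`` / ``three_prime`` are 0-based genome positions of the
    first and last transcribed nucleotide (circular-aware; on the minus
    strand the 5' position is the higher genome coordinate). ``tail`` is
    non-templated sequence appended at the 3' end before circularization.
    """

    template_id: str
    five_prime: int
    three_prime: int
    strand: str
    klass: str  # mature | precursor | degradation_intermediate | sRNA
    tail: str = "none"  # none | CCA | polyA
    tail_len: int = 0
    abundance_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.klass not in ("mature", "precursor", "degradation_intermediate", "sRNA"):
            raise ValueError(f"unknown template class {self.klass!r}")
        if self.tail == "CCA" and self.tail_len != 3:
            object.__setattr__(self, "tail_len", 3)
        if self.tail == "polyA" and not (0 <= self.tail_len <= 60):
            raise ValueError("polyA tail length out of [0, 60]")
        if self.abundance_weight <= 0:
            raise ValueError("abundance_weight must be positive")

    def body_interval(self, L: int) -> tuple[int, int]:
        """Plus-strand genome interval [lo, lo+len) of the transcribed body."""
        if self.strand == "+":
            lo = self.five_prime
            length = (self.three_prime - self.five_prime) % L + 1
        else:
            lo = self.three_prime
            length = (self.five_prime - self.three_prime) % L + 1
        return lo, lo + length

    def body_length(self, L: int) -> int:
        lo, hi = self.body_interval(L)
        return hi - lo

    def tail_seq(self) -> str:
        if self.tail == "CCA":
            return "CCA"
        if self.tail == "polyA":
            return "A" * self.tail_len
        return ""

    def molecule_seq(self, genome: CircularGenome) -> str:
        """Transcript-sense sequence including the non-templated tail."""
        lo, hi = self.body_interval(genome.length)
        if hi - lo < 15:
            raise ValueError(f"{self.template_id}: transcribed length < 15 nt")
        if hi - lo > genome.length:
            raise ValueError(f"{self.template_id}: longer than the genome")
        return genome.fetch(lo, hi, self.strand) + self.tail_seq()


@dataclass
class SimConfig:
    """Library and sequencing parameters.

    ``copy_mean`` is the mean rolling-circle copy number; copies are drawn
    as ``1 + Geometric`` so every cDNA holds at least one full pass.
    ``fragment_length`` is (mean, sd) of the sheared insert size, truncated
    to [30, 500] nt.
    """

    n_molecules: int = 2000
    circularization_prob: float = 0.85
    copy_mean: float = 2.5
    fragment_length: tuple[float, float] = (350.0, 80.0)
    read_length: int = 250
    substitution_error_rate: float = 0.0
    adapter1: str = DEFAULT_ADAPTER1
    adapter2: str = DEFAULT_ADAPTER2
    min_fragment: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.circularization_prob <= 1.0):
            raise ValueError("circularization_prob out of [0, 1]")
        if not (0.0 <= self.substitution_error_rate <= 0.05):
            raise ValueError("substitution_error_rate out of [0, 0.05]")
        if self.read_length < 30:
            raise ValueError("read_length < 30")
        if self.copy_mean < 1.0:
            raise ValueError("copy_mean < 1")


@dataclass
class SimResult:
    """Reads plus ground truth from one simulated library."""

    pairs: list[tuple[str, str, str, str, str]]  # (read_id, seq1, qual1, seq2, qual2)
    molecules: pd.DataFrame
    reads: pd.DataFrame
    config: SimConfig


def _same_strand_runs(features: list[GeneFeature]) -> list[list[GeneFeature]]:
    runs: list[list[GeneFeature]] = []
    for f in sorted(features, key=lambda f: f.start):
        if runs and runs[-1][-1].strand == f.strand:
            runs[-1].append(f)
        else:
            runs.append([f])
    return runs


def make_default_templates(
    annotation: AnnotationSet,
    scenario: str = "WT",
    L: int | None = None,
    precursor_fraction: float = 0.05,
    degradation_fraction: float = 0.03,
    srna_fraction: float = 0.10,
    cca_fraction: float = 0.6,
    polya_fraction: float | None = None,
    ko_precursor_multiplier: float = 2.0,
    polya_tail_len: int = 8,
) -> list[TranscriptTemplate]:
    """Default molecular population for a wild-type or knockout scenario.

    Weights are fractions of total abundance. The knockout scenario models a
    stalled-processing phenotype: multi-gene precursor and ORF-internal
    degradation-intermediate weight are multiplied by
    ``ko_precursor_multiplier`` (default 2), and the polyadenylated fraction
    of mRNA-derived small fragments rises (default 0.1 -> 0.3). Tail-bearing
    and tail-less versions of each small-RNA species are emitted as separate
    templates whose weights encode the tail probabilities, which keeps the
    population exactly specified.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    if scenario not in ("WT", "KO"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if polya_fraction is None:
        polya_fraction = 0.1 if scenario == "WT" else 0.3
    mult = ko_precursor_multiplier if scenario == "KO" else 1.0
    p_frac = precursor_fraction * mult
    d_frac = degradation_fraction * mult
    s_frac = srna_fraction
    mature_frac = 1.0 - p_frac - d_frac - s_frac
    if mature_frac <= 0:
        raise ValueError("class fractions exceed 1")

    templates: list[TranscriptTemplate] = []

    # --- mature species: exact annotated termini ------------------------
    class_weight = {"rRNA": 10.0, "mRNA": 3.0, "tRNA": 2.0, "ncRNA": 1.0, "dloop": 1.0}
    mature: list[TranscriptTemplate] = []
    for f in annotation:
        tail, tlen = "none", 0
        if f.biotype == "tRNA":
            tail, tlen = "CCA", 3
        elif f.biotype == "mRNA":
            tail, tlen = "polyA", 30
        five = f.start if f.strand == "+" else f.end - 1
        three = f.end - 1 if f.strand == "+" else f.start
        mature.append(TranscriptTemplate(
            template_id=f"mature:{f.gene_id}", five_prime=five, three_prime=three,
            strand=f.strand, klass="mature", tail=tail, tail_len=tlen,
            abundance_weight=class_weight.get(f.biotype, 1.0)))
    total = sum(t.abundance_weight for t in mature)
    templates += [_reweight(t, t.abundance_weight / total * mature_frac) for t in mature]

    # --- multi-gene precursors spanning unprocessed tRNA boundaries -----
    precursors: list[TranscriptTemplate] = []
    for run in _same_strand_runs(list(annotation)):
        for i in range(len(run) - 1):
            for width in (2, 3):
                if i + width > len(run):
                    continue
                block = run[i:i + width]
                if not any(g.biotype == "tRNA" for g in block):
                    continue
                strand = block[0].strand
                lo, hi = block[0].start, block[-1].end
                five = lo if strand == "+" else hi - 1
                three = hi - 1 if strand == "+" else lo
                precursors.append(TranscriptTemplate(
                    template_id="precursor:" + "+".join(g.gene_id for g in block),
                    five_prime=five, three_prime=three, strand=strand,
                    klass="precursor", abundance_weight=1.0))
        if len(precursors) >= 6:
            break
    if p_frac > 0 and precursors:
        w = p_frac / len(precursors)
        templates += [_reweight(t, w) for t in precursors]

    # --- degradation intermediates with ends internal to ORFs -----------
    degs: list[TranscriptTemplate] = []
    for f in annotation.of_biotype("mRNA")[:3]:
        q = f.length // 4
        lo, hi = f.start + q, f.end - q
        five = lo if f.strand == "+" else hi - 1
        three = hi - 1 if f.strand == "+" else lo
        degs.append(TranscriptTemplate(
            template_id=f"deg:{f.gene_id}", five_prime=five, three_prime=three,
            strand=f.strand, klass="degradation_intermediate", abundance_weight=1.0))
    if d_frac > 0 and degs:
        w = d_frac / len(degs)
        templates += [_reweight(t, w) for t in degs]

    # --- small RNAs: tRNA 3' fragments (CCA) and mRNA decay fragments ---
    srnas: list[tuple[TranscriptTemplate, float]] = []
    for f in annotation.of_biotype("tRNA"):
        frag = min(25, f.length)
        if f.strand == "+":
            five, three = f.end - frag, f.end - 1
        else:
            five, three = f.start + frag - 1, f.start
        for tail, tlen, p in (("CCA", 3, cca_fraction), ("none", 0, 1.0 - cca_fraction)):
            if p <= 0:
                continue
            srnas.append((TranscriptTemplate(
                template_id=f"sRNA:{f.gene_id}:3p:{tail}", five_prime=five,
                three_prime=three, strand=f.strand, klass="sRNA",
                tail=tail, tail_len=tlen, abundance_weight=1.0), p))
    for j, f in enumerate(annotation.of_biotype("mRNA")[:4]):
        frag = 19 if j % 2 == 0 else 22
        off = f.length // 3
        if f.strand == "+":
            five, three = f.start + off, f.start + off + frag - 1
        else:
            five, three = f.end - 1 - off, f.end - off - frag
        for tail, tlen, p in (("polyA", polya_tail_len, polya_fraction),
                              ("none", 0, 1.0 - polya_fraction)):
            if p <= 0:
                continue
            srnas.append((TranscriptTemplate(
                template_id=f"sRNA:{f.gene_id}:frag:{tail}", five_prime=five,
                three_prime=three, strand=f.strand, klass="sRNA",
                tail=tail, tail_len=tlen, abundance_weight=1.0), p))
    if s_frac > 0 and srnas:
        n_species = len({t.template_id.rsplit(":", 1)[0] for t, _ in srnas})
        for t, p in srnas:
            templates.append(_reweight(t, s_frac * p / n_species))

    return templates


def _reweight(t: TranscriptTemplate, w: float) -> TranscriptTemplate:
    d = asdict(t)
    d["abundance_weight"] = w
    return TranscriptTemplate(**d)


def _add_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        # replace with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=hit.size)
        idx = np.searchsorted(_BASES, arr[hit])
        idx[idx >= 4] = 0  # N or pad treated as A before shifting
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def simulate_library(
    templates: list[TranscriptTemplate],
    genome: CircularGenome,
    config: SimConfig,
) -> SimResult:
    """Simulate one library: molecules -> circles -> rolling-circle cDNA ->
    fragments -> paired 250 nt reads with substitution errors.

    Truth tables: ``molecules`` has one row per sampled molecule (including
    non-circularized ones, which yield no reads); ``reads`` has one row per
    emitted pair with the fragment's coordinates on its cDNA and the offsets
    of any ligation junctions it contains.
    """
    if not templates:
        raise ValueError("no templates")
    rng = np.random.default_rng(config.seed)
    L = genome.length
    weights = np.array([t.abundance_weight for t in templates], dtype=float)
    weights /= weights.sum()
    seqs = [t.molecule_seq(genome) for t in templates]

    # geometric parameter for copies = 1 + Geometric(p), mean 1 + 1/p
    geo_p = 1.0 / (config.copy_mean - 1.0) if config.copy_mean > 1.0 else None
    frag_mean, frag_sd = config.fragment_length
    rlen = config.read_length

    choice = rng.choice(len(templates), size=config.n_molecules, p=weights)
    pairs: list[tuple[str, str, str, str, str]] = []
    mol_rows = []
    read_rows = []
    qual = "I" * rlen

    for mi in range(config.n_molecules):
        t = templates[choice[mi]]
        mol = seqs[choice[mi]]
        P = len(mol)
        circular = bool(rng.random() < config.circularization_prob)
        copies = 1 + int(rng.geometric(geo_p)) if geo_p is not None else 1
        mol_id = f"m{mi:06d}"
        mol_rows.append(dict(
            molecule_id=mol_id, template_id=t.template_id, five_prime=t.five_prime,
            three_prime=t.three_prime, strand=t.strand, klass=t.klass,
            tail=t.tail, tail_len=t.tail_len, length=P,
            circularized=circular, copies_in_cDNA=copies if circular else 0))
        if not circular:
            continue  # RNase R destroys linear molecules
        rot = int(rng.integers(P))
        cdna = (mol[rot:] + mol[:rot]) * copies
        # ligation-junction offsets within the cDNA (molecule 3'+tail -> 5')
        j0 = (P - rot) % P
        junctions = [j0 + k * P for k in range(copies) if 0 < j0 + k * P < len(cdna)]
        if j0 == 0:
            junctions = [k * P for k in range(1, copies)]

        pos = 0
        fi = 0
        while pos < len(cdna):
            flen = int(round(rng.normal(frag_mean, frag_sd)))
            flen = max(config.min_fragment, min(flen, 500))
            frag = cdna[pos:pos + flen]
            fstart = pos
            pos += flen
            if len(frag) < config.min_fragment:
                break
            in_frag = [j - fstart for j in junctions if fstart < j < fstart + len(frag)]
            # a junction is cleanly recoverable when both molecule-body
            # flanks (tail excluded) reach the minimum placeable length
            clear = [o for o in in_frag
                     if o - t.tail_len >= 15 and len(frag) - o >= 15]
            read_id = f"{mol_id}:f{fi}"
            fi += 1
            r1 = frag[:rlen]
            if len(r1) < rlen:
                r1 = (r1 + config.adapter1 + "G" * rlen)[:rlen]
            r2 = _revcomp(frag)[:rlen]
            if len(r2) < rlen:
                r2 = (r2 + config.adapter2 + "G" * rlen)[:rlen]
            r1 = _add_substitutions(r1, config.substitution_error_rate, rng)
            r2 = _add_substitutions(r2, config.substitution_error_rate, rng)
            pairs.append((read_id, r1, qual, r2, qual))
            read_rows.append(dict(
                read_id=read_id, molecule_id=mol_id, template_id=t.template_id,
                strand=t.strand, frag_start=fstart, frag_len=len(frag),
                junction_offsets=",".join(map(str, in_frag)),
                n_junctions=len(in_frag), n_junctions_clear=len(clear)))

    mol_cols = ["molecule_id", "template_id", "five_prime", "three_prime", "strand",
                "klass", "tail", "tail_len", "length", "circularized", "copies_in_cDNA"]
    read_cols = ["read_id", "molecule_id", "template_id", "strand", "frag_start",
                 "frag_len", "junction_offsets", "n_junctions", "n_junctions_clear"]
    molecules = pd.DataFrame(mol_rows, columns=mol_cols)
    reads = pd.DataFrame(read_rows, columns=read_cols)
    return SimResult(pairs=pairs, molecules=molecules, reads=reads, config=config)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def truth_end_table(molecules: pd.DataFrame) -> pd.DataFrame:
    """Expected end counts: circularized molecules by (5', 3', strand)."""
    if molecules.empty:
        return pd.DataFrame(columns=["five_prime", "three_prime", "strand", "n_molecules"])
    circ = molecules[molecules["circularized"]]
    out = (circ.groupby(["five_prime", "three_prime", "strand"], as_index=False)
               .size().rename(columns={"size": "n_molecules"}))
    return out.sort_values("n_molecules", ascending=False, ignore_index=True)


def write_truth_tables(sim: "SimResult", molecules_path: str | Path,
                       reads_path: str | Path) -> None:
    """Write the molecule and read truth tables as TSV.

    A comment header records the simulation seed and key parameters so a
    truth file is always traceable to its generating configuration.
    """
    c = sim.config
    header = ("# circends simulated truth\t"
              f"seed={c.seed}\tn_molecules={c.n_molecules}\t"
              f"circularization_prob={c.circularization_prob}\t"
              f"copy_mean={c.copy_mean}\t"
              f"substitution_error_rate={c.substitution_error_rate}\n")
    for df, path in ((sim.molecules, molecules_path), (sim.reads, reads_path)):
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)


def write_fastq_pairs(pairs, r1_path: str | Path, r2_path: str | Path) -> None:
    """Write standard 4-line FASTQ records; gzip if the path ends in .gz."""
    def _open(p):
        p = str(p)
        return gzip.open(p, "wt") if p.endswith(".gz") else open(p, "w")

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for read_id, s1, q1, s2, q2 in pairs:
            f1.write(f"@{read_id}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{read_id}/2\n{s2}\n+\n{q2}\n")
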