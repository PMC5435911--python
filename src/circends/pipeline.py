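"""End-to-end orchestration: trim -> merge -> monomerize -> align ->
junction calls / coverage / small-RNA statistics, for single samples and
two-condition comparisons.

The per-read routing logic lives in :func:`analyze_reads`:

* collapsed rolling-circle monomers (two or more tandem copies) are doubled
  and placed in one pass, which yields both termini directly;
* uncollapsed reads go through local alignment with soft clips, clip
  realignment (with junction-tail stripping), grouping, and junction
  calling.

Every read ends up in exactly one accounting bin so stage totals always sum
to the input count.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
import yaml

from . import srna as srna_mod
from .align import (AlignParams, KmerIndex, SegmentAlignment, align_end_to_end,
                    align_local, extract_clips, group_segments)
from .coverage import coverage, cpm, log2fc, write_bedgraph
from .genome import AnnotationSet, CircularGenome, revcomp
from .links import (MAX_TAIL, PrecursorCall, aggregate, call_from_monomer,
                    call_precursor, compare_links, export_circos)
from .monomerize import Monomer, monomerize_stream
from .readprep import MergedRead, prepare_pairs
from .simulate import DEFAULT_ADAPTER1, DEFAULT_ADAPTER2

__all__ = [
    "PipelineParams",
    "SampleResult",
    "analyze_reads",
    "run_sample",
    "run_comparison",
    "read_fastq_pairs",
]


@dataclass
class PipelineParams:
    adapter1: str = DEFAULT_ADAPTER1
    adapter2: str = DEFAULT_ADAPTER2
    min_len: int = 20
    min_overlap: int = 10
    max_overlap: int = 245
    min_period: int = 15
    min_clip: int = 15
    contiguity_tol: int = 2
    align: AlignParams = field(default_factory=AlignParams)
    srna_min_len: int = 15
    srna_max_len: int = 60

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        """Load stage parameters from a YAML mapping (missing keys keep
        their defaults; alignment constants under an ``align:`` block)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        align_kw = data.pop("align", {})
        params = cls(**data)
        if align_kw:
            params.align = AlignParams(**{**dataclasses.asdict(params.align),
                                          **align_kw})
        return params


@dataclass
class SampleResult:
    name: str
    condition: str
    monomers: list[Monomer]
    segments: list[SegmentAlignment]
    calls: list[PrecursorCall]
    srnas: list
    n_aligned: int
    stats: dict
    seqs: dict[str, str] = field(default_factory=dict)


def _strip_variants(clip: str, part: str, strand: str):
    """Possible junction tails at the clip's junction-facing edge.

    Returns (core, lead_trim, tail_kind, tail_len) tuples; transcript-sense
    tails appear reverse-complemented on the minus strand.
    """
    a_char = "A" if strand == "+" else "T"
    cca = "CCA" if strand == "+" else "TGG"
    out = []
    if part == "right":
        if clip.startswith(cca):
            out.append((clip[3:], 3, "CCA", 3))
        run = len(clip) - len(clip.lstrip(a_char))
        if run >= 3:
            r = min(run, MAX_TAIL)
            out.append((clip[r:], r, "polyA", r))
    else:
        if clip.endswith(cca):
            out.append((clip[:-3], 0, "CCA", 3))
        run = len(clip) - len(clip.rstrip(a_char))
        if run >= 3:
            r = min(run, MAX_TAIL)
            out.append((clip[:-r], 0, "polyA", r))
    return out


def _tail_residue(clip: str, part: str, strand: str) -> bool:
    """True when an unplaceable clip is pure tail sequence.

    A fragment can end (or start) inside a non-templated tail; such a clip
    carries no body sequence to place and should not count against the
    read's completeness.
    """
    a_char = "A" if strand == "+" else "T"
    cca = "CCA" if strand == "+" else "TGG"
    s = clip
    if part == "right":
        if s.startswith(cca):
            s = s[3:]
        elif cca.startswith(s):
            return True
    else:
        if s.endswith(cca):
            s = s[:-3]
        elif len(s) < 3 and cca.endswith(s):
            return True
    return s == "" or set(s) <= {a_char}


def _place_clip(t_seq: str, part: str, cs: int, ce: int, strand: str,
                genome: CircularGenome, read_id: str, min_clip: int):
    """End-to-end placement of one clip, trying tail-stripped variants.

    The variant with the fewest edits wins; ties keep the unstripped clip
    (the templated interpretation). Returns (segment, tail_interval|None).
    """
    clip = t_seq[cs:ce]
    candidates = []
    full = align_end_to_end(clip, genome, strand=strand, read_id=read_id,
                            part=part, qoffset=cs)
    if full is not None:
        candidates.append((full.edit_distance, 0, full, None))
    for core, lead, _kind, tlen in _strip_variants(clip, part, strand):
        if len(core) < min_clip:
            continue
        seg = align_end_to_end(core, genome, strand=strand, read_id=read_id,
                               part=part, qoffset=cs + lead)
        if seg is None:
            continue
        tail_iv = (cs, cs + lead) if part == "right" else (ce - tlen, ce)
        candidates.append((seg.edit_distance, 1, seg, tail_iv))
    if not candidates:
        return None, None
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, seg, tail_iv = candidates[0]
    return seg, tail_iv


def analyze_reads(reads: list[MergedRead], genome: CircularGenome,
                  annotation: AnnotationSet | None, index: KmerIndex,
                  params: PipelineParams = PipelineParams(),
                  name: str = "", condition: str = "") -> SampleResult:
    """Monomerize, align and call junctions for prepared reads."""
    monomers = list(monomerize_stream(((r.read_id, r.seq) for r in reads),
                                      min_period=params.min_period))
    segments: list[SegmentAlignment] = []
    calls: list[PrecursorCall] = []
    srnas = []
    seqs: dict[str, str] = {}
    stats = {"reads_in": len(reads), "collapsed": 0, "unaligned": 0,
             "aligned_single": 0, "aligned_split": 0}
    L = genome.length
    for m in monomers:
        if m.was_collapsed and m.copies >= 2.0:
            stats["collapsed"] += 1
            call = call_from_monomer(m.monomer_seq, m.read_id, index, genome,
                                     annotation, params=params.align,
                                     contiguity_tol=params.contiguity_tol)
            if call is None:
                aln = align_local(m.monomer_seq, index, genome,
                                  params=params.align, read_id=m.read_id)
                if aln is None:
                    stats["unaligned"] += 1
                else:
                    stats["aligned_single"] += 1
                    segments.append(aln)
                    seqs[m.read_id] = (m.monomer_seq if aln.strand == "+"
                                       else revcomp(m.monomer_seq))
                continue
            stats["aligned_split"] += 1
            calls.append(call)
            lo, hi = call.molecule_interval(L)
            body = SegmentAlignment(
                read_id=m.read_id, part="whole", qstart=0, qend=hi - lo,
                gstart=lo % L, gend=lo % L + (hi - lo), strand=call.strand,
                cigar=f"{hi - lo}M", edit_distance=0, score=2 * (hi - lo))
            segments.append(body)
            if params.srna_min_len <= len(m.monomer_seq) <= params.srna_max_len:
                srnas.append(srna_mod.srna_from_monomer(m, call, genome, annotation))
            continue
        aln = align_local(m.monomer_seq, index, genome, params=params.align,
                          read_id=m.read_id)
        if aln is None:
            stats["unaligned"] += 1
            continue
        t_seq = m.monomer_seq if aln.strand == "+" else revcomp(m.monomer_seq)
        seqs[m.read_id] = t_seq
        aln_parts = [aln]
        accounted = []
        clips = extract_clips(aln, len(t_seq), min_clip=params.min_clip)
        for part, cs, ce in clips:
            seg, tail_iv = _place_clip(t_seq, part, cs, ce, aln.strand, genome,
                                       m.read_id, params.min_clip)
            if seg is not None:
                aln_parts.append(seg)
                if tail_iv is not None:
                    accounted.append(tail_iv)
            elif _tail_residue(t_seq[cs:ce], part, aln.strand):
                accounted.append((cs, ce))
        if len(aln_parts) > 1:
            aln_parts[0] = dataclasses.replace(aln, part="middle")
        group = group_segments(aln_parts, len(t_seq), min_clip=params.min_clip,
                               accounted=accounted)
        segments.extend(group.segments)
        call = call_precursor(group, genome, annotation, seq=t_seq,
                              contiguity_tol=params.contiguity_tol)
        if call is not None:
            calls.append(call)
            stats["aligned_split"] += 1
        else:
            stats["aligned_single"] += 1
    n_aligned = stats["aligned_single"] + stats["aligned_split"]
    return SampleResult(name=name, condition=condition, monomers=monomers,
                        segments=segments, calls=calls, srnas=srnas,
                        n_aligned=n_aligned, stats=stats, seqs=seqs)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path):
    """Iterate (read_id, seq1, qual1, seq2, qual2) from paired FASTQ files."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            rid = e1.name.rsplit("/", 1)[0]
            yield (rid, e1.sequence, e1.quality or "I" * len(e1.sequence),
                   e2.sequence, e2.quality or "I" * len(e2.sequence))


def write_sam(segments: list[SegmentAlignment], genome: CircularGenome,
              path: str | Path, seqs: dict[str, str] | None = None) -> None:
    """SAM export of placed segments for genome-browser inspection.

    Alignments crossing the origin are written at their start with the
    CIGAR running past the reference end — viewers treating the genome as
    linear will truncate them at position L.
    """
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": genome.name, "LN": genome.length}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for seg in segments:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"{seg.read_id}/{seg.part}"
            a.flag = 0 if seg.strand == "+" else 16
            a.reference_id = 0
            a.reference_start = seg.gstart % genome.length
            a.mapping_quality = 60
            a.cigarstring = seg.cigar
            seq = (seqs or {}).get(seg.read_id)
            if seq is not None and len(seq) == sum(
                    int(n) for n, op in re.findall(r"(\d+)([MIS])", seg.cigar)):
                a.query_sequence = seq
            a.set_tag("NM", seg.edit_distance)
            a.set_tag("AS", seg.score)
            fh.write(a)


def run_sample(r1_path: str | Path, r2_path: str | Path,
               genome: CircularGenome, annotation: AnnotationSet | None,
               out_dir: str | Path, name: str = "sample", condition: str = "",
               params: PipelineParams = PipelineParams(),
               index: KmerIndex | None = None) -> SampleResult:
    """Process one sample's FASTQ pair and write all per-sample outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = list(read_fastq_pairs(r1_path, r2_path))
    reads, prep_stats = prepare_pairs(
        pairs, params.adapter1, params.adapter2, min_len=params.min_len,
        min_overlap=params.min_overlap, max_overlap=params.max_overlap)
    if index is None:
        index = KmerIndex(genome, k=params.align.k)
    result = analyze_reads(reads, genome, annotation, index, params,
                           name=name, condition=condition)
    result.stats.update(prep_stats)

    mono_rows = [(m.read_id, m.period, round(m.copies, 3),
                  round(m.consensus_support, 4), m.was_collapsed)
                 for m in result.monomers]
    pd.DataFrame(mono_rows, columns=["read_id", "period", "copies", "support",
                                     "collapsed"]).to_csv(
        out / f"{name}.monomers.tsv", sep="\t", index=False)
    write_sam(result.segments, genome, out / f"{name}.sam", seqs=result.seqs)
    table, profile = aggregate(result.calls, annotation, genome.length,
                               condition=condition,
                               library_total=result.n_aligned or None)
    table.to_csv(out / f"{name}.links.tsv", sep="\t", index=False)
    track = coverage(result.segments, genome.length)
    for strand, tag in (("+", "plus"), ("-", "minus")):
        write_bedgraph(track.depth[strand], genome.name,
                       out / f"{name}.coverage.{tag}.bedgraph")
        write_bedgraph(profile.five[strand], genome.name,
                       out / f"{name}.five_prime_ends.{tag}.bedgraph")
        write_bedgraph(profile.three[strand], genome.name,
                       out / f"{name}.three_prime_ends.{tag}.bedgraph")
    srna_rows = [(s.read_id, len(s.seq), s.body_len,
                  s.feature.gene_id if s.feature else "",
                  s.feature_class, s.tail.kind, s.tail.length, s.tail.templated)
                 for s in result.srnas]
    pd.DataFrame(srna_rows, columns=["read_id", "length", "body_len", "gene",
                                     "class", "tail", "tail_len",
                                     "templated"]).to_csv(
        out / f"{name}.srna.tsv", sep="\t", index=False)
    pd.Series(result.stats).to_csv(out / f"{name}.stats.tsv", sep="\t",
                                   header=False)
    return result


def run_comparison(results_a: list[SampleResult], results_b: list[SampleResult],
                   genome: CircularGenome, annotation: AnnotationSet | None,
                   out_dir: str | Path, labels: tuple[str, str] = ("A", "B"),
                   pseudocount: float = 1.0) -> dict:
    """Two-condition comparison: replicates pooled for links and coverage,
    kept separate for the small-RNA replicate statistics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = genome.length
    pooled = {}
    for label, results in zip(labels, (results_a, results_b)):
        calls = [c for r in results for c in r.calls]
        segs = [s for r in results for s in r.segments]
        n_aligned = sum(r.n_aligned for r in results)
        table, profile = aggregate(calls, annotation, L, condition=label,
                                   library_total=n_aligned or None)
        track = cpm(coverage(segs, L), n_aligned) if n_aligned else None
        pooled[label] = dict(table=table, profile=profile, track=track,
                             calls=calls, n_aligned=n_aligned)
        table.to_csv(out / f"links.{label}.tsv", sep="\t", index=False)
        export_circos(table, annotation, genome, out / f"circos.links.{label}.txt",
                      out / f"circos.karyotype.{label}.txt")
    la, lb = labels
    link_fc = compare_links(pooled[la]["table"], pooled[lb]["table"],
                            pseudocount=pseudocount)
    link_fc.to_csv(out / f"links.log2fc.{la}_vs_{lb}.tsv", sep="\t", index=False)
    diff = None
    if pooled[la]["track"] is not None and pooled[lb]["track"] is not None:
        diff = log2fc(pooled[la]["track"], pooled[lb]["track"], pseudocount)
        for strand, tag in (("+", "plus"), ("-", "minus")):
            write_bedgraph(diff.log2fc[strand], genome.name,
                           out / f"coverage.log2fc.{tag}.bedgraph")
    srna_test = None
    if len(results_a) >= 2 and len(results_b) >= 2:
        srna_test = srna_mod.polya_proportion(
            {la: [r.srnas for r in results_a], lb: [r.srnas for r in results_b]})
        srna_test.to_csv(out / "srna.polya_ttest.tsv", sep="\t", index=False)
    return dict(pooled=pooled, link_log2fc=link_fc, coverage_log2fc=diff,
                srna_test=srna_test)
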