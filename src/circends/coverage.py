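"""Strand-aware depth of coverage, CPM normalisation and log2FC tracks.

Depth counts reference-consuming alignment bases (M and D CIGAR ops;
insertions consume no reference), with circular wraparound. CPM scales raw
depth by 1e6 over the number of reads aligned to the genome — a library-size
normalisation that makes conditions with different sequencing depth
comparable. Differential tracks are log2((A + psi) / (B + psi)) with a
pseudocount psi keeping every position finite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import SegmentAlignment

__all__ = ["CoverageTrack", "DiffTrack", "coverage", "cpm", "log2fc", "write_bedgraph"]

_CIG_RE = re.compile(r"(\d+)([MIDSX=])")


@dataclass
class CoverageTrack:
    L: int
    depth: dict[str, np.ndarray]  # strand -> per-position depth
    library_total: int
    normalization: str = "raw"

    @classmethod
    def zeros(cls, L: int) -> "CoverageTrack":
        return cls(L=L, depth={"+": np.zeros(L), "-": np.zeros(L)}, library_total=0)


@dataclass
class DiffTrack:
    L: int
    log2fc: dict[str, np.ndarray]
    pseudocount: float


def ref_span_from_cigar(cigar: str) -> int:
    return sum(int(n) for n, op in _CIG_RE.findall(cigar) if op in "MDX=")


def coverage(alignments: list[SegmentAlignment], L: int) -> CoverageTrack:
    """Per-position, per-strand depth over the circular genome.

    ``library_total`` is the number of distinct reads contributing at least
    one segment (reads, not bases: the denominator CPM scales by).
    """
    track = CoverageTrack.zeros(L)
    reads = set()
    for a in alignments:
        reads.add(a.read_id)
        span = ref_span_from_cigar(a.cigar) or a.ref_span
        start = a.gstart % L
        end = start + span
        d = track.depth[a.strand]
        if end <= L:
            d[start:end] += 1
        else:
            d[start:] += 1
            d[:end - L] += 1
    track.library_total = len(reads)
    return track


def cpm(track: CoverageTrack, library_total: int | None = None) -> CoverageTrack:
    """Counts-per-million scaling of a raw track."""
    if track.normalization == "CPM":
        raise ValueError("track already CPM-normalised")
    total = library_total if library_total is not None else track.library_total
    if total <= 0:
        raise ValueError("library_total must be positive for CPM")
    f = 1e6 / total
    return CoverageTrack(L=track.L, depth={s: v * f for s, v in track.depth.items()},
                         library_total=total, normalization="CPM")


def log2fc(track_a: CoverageTrack, track_b: CoverageTrack,
           pseudocount: float = 1.0) -> DiffTrack:
    """Per-position log2((A + psi)/(B + psi)); requires CPM-normalised input."""
    if track_a.L != track_b.L:
        raise ValueError("track length mismatch")
    if track_a.normalization != "CPM" or track_b.normalization != "CPM":
        raise ValueError("log2fc requires CPM-normalised tracks")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = {s: np.log2((track_a.depth[s] + pseudocount) /
                      (track_b.depth[s] + pseudocount))
           for s in track_a.depth}
    return DiffTrack(L=track_a.L, log2fc=out, pseudocount=pseudocount)


def write_bedgraph(values: np.ndarray, chrom: str, path: str | Path,
                   one_based_report: bool = False) -> None:
    """Write a per-position vector as a run-length-merged BEDGraph."""
    with open(path, "w") as fh:
        start = 0
        for pos in range(1, len(values) + 1):
            if pos == len(values) or values[pos] != values[start]:
                if values[start] != 0:
                    fh.write(f"{chrom}\t{start}\t{pos}\t{values[start]:g}\n")
                start = pos
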