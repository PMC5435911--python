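"""Split alignment of reads to a small circular genome.

Two passes mirror the read structure produced by rolling-circle cDNA:

1. ``align_local`` — seed (k-mer index), chain hits by diagonal, and extend
   with an affine-gap local alignment; the best-scoring placement keeps
   soft-clipped ends. Scoring follows the common local-mode defaults
   (match +2, mismatch -4, gap open -6, gap extend -1).
2. ``align_end_to_end`` — soft-clipped "left"/"right" parts of at least
   ``min_clip`` nt are realigned over their full length, here by exhaustive
   substitution-only placement against every genome offset (the genome is
   small enough that this is exact and fast).

Coordinate conventions: a read is first strand-resolved — minus-strand
placements are computed on the reverse complement of the read — and all
``read_interval`` coordinates refer to that transcript-sense orientation.
Genome intervals are reported with ``gstart`` in ``[0, L)`` and ``gend``
possibly beyond ``L`` for origin-spanning placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genome import CircularGenome, revcomp

__all__ = [
    "AlignParams",
    "KmerIndex",
    "SegmentAlignment",
    "SplitGroup",
    "build_index",
    "align_local",
    "extract_clips",
    "align_end_to_end",
    "group_segments",
]


@dataclass(frozen=True)
class AlignParams:
    k: int = 12
    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_score: int = 40
    min_clip: int = 15
    band_pad: int = 24
    max_clusters: int = 8


@dataclass(frozen=True)
class SegmentAlignment:
    """One placed part of a read.

    ``qstart``/``qend`` are on the strand-resolved (transcript-sense) read;
    ``gstart`` is in ``[0, L)`` and ``gend = gstart + reference_span``.
    """

    read_id: str
    part: str  # left | middle | right | whole
    qstart: int
    qend: int
    gstart: int
    gend: int
    strand: str
    cigar: str
    edit_distance: int
    score: int

    @property
    def read_span(self) -> int:
        return self.qend - self.qstart

    @property
    def ref_span(self) -> int:
        return self.gend - self.gstart


@dataclass
class SplitGroup:
    """All placed segments of one read, ordered by read coordinate."""

    read_id: str
    segments: list[SegmentAlignment]
    complete: bool
    read_len: int = 0

    @property
    def strand(self) -> str | None:
        strands = {s.strand for s in self.segments}
        return strands.pop() if len(strands) == 1 else None


class KmerIndex:
    """Exact k-mer -> start-position index of a circular genome.

    Every position ``0..L-1`` contributes one k-mer per strand; k-mers
    spanning the origin are included by reading through the doubled
    sequence.
    """

    def __init__(self, genome: CircularGenome, k: int = 12):
        if k > genome.length:
            raise ValueError(f"k={k} exceeds genome length {genome.length}")
        self.k = k
        self.L = genome.length
        self._fwd: dict[str, list[int]] = {}
        self._rev: dict[str, list[int]] = {}
        doubled = genome.doubled()
        rc_doubled = revcomp(doubled)
        for p in range(self.L):
            self._fwd.setdefault(doubled[p:p + k], []).append(p)
            self._rev.setdefault(rc_doubled[p:p + k], []).append(p)

    def positions(self, kmer: str, strand: str = "+") -> list[int]:
        table = self._fwd if strand == "+" else self._rev
        return table.get(kmer, [])


def build_index(genome: CircularGenome, k: int = 12) -> KmerIndex:
    return KmerIndex(genome, k=k)


@njit(cache=True)
def _gotoh_local(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    nq, nr = q.size, r.size
    NEG = -(10 ** 7)
    H = np.zeros((nq + 1, nr + 1), np.int32)
    E = np.full((nq + 1, nr + 1), NEG, np.int32)
    F = np.full((nq + 1, nr + 1), NEG, np.int32)
    PH = np.zeros((nq + 1, nr + 1), np.uint8)  # 0 stop, 1 diag, 2 from F, 3 from E
    PE = np.zeros((nq + 1, nr + 1), np.uint8)  # 0 opened, 1 extended
    PF = np.zeros((nq + 1, nr + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    go_ge = gap_open + gap_extend
    for i in range(1, nq + 1):
        qi = q[i - 1]
        for j in range(1, nr + 1):
            e_open = H[i, j - 1] + go_ge
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 0
            else:
                E[i, j] = e_ext
                PE[i, j] = 1
            f_open = H[i - 1, j] + go_ge
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 0
            else:
                F[i, j] = f_ext
                PF[i, j] = 1
            s = H[i - 1, j - 1] + (match if qi == r[j - 1] else mismatch)
            h = 0
            ph = 0
            if s > h:
                h = s
                ph = 1
            if F[i, j] > h:
                h = F[i, j]
                ph = 2
            if E[i, j] > h:
                h = E[i, j]
                ph = 3
            H[i, j] = h
            PH[i, j] = ph
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, PH, PE, PF


def _window_align(q_arr: np.ndarray, r_arr: np.ndarray, params: AlignParams):
    """Best local alignment of query vs a reference window.

    Returns (score, qstart, qend, rstart, rend, cigar_core, edits) or None.
    """
    best, bi, bj, PH, PE, PF = _gotoh_local(
        q_arr, r_arr, params.match, params.mismatch, params.gap_open, params.gap_extend)
    if best <= 0:
        return None
    ops: list[str] = []
    edits = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=F(insertion), 2=E(deletion)
    while True:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                ops.append("M")
                if q_arr[i - 1] != r_arr[j - 1]:
                    edits += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops.append("I")
            edits += 1
            opened = PF[i, j] == 0
            i -= 1
            state = 0 if opened else 1
        else:
            ops.append("D")
            edits += 1
            opened = PE[i, j] == 0
            j -= 1
            state = 0 if opened else 2
    ops.reverse()
    cigar = _compress_ops(ops)
    return best, i, bi, j, bj, cigar, edits


def _compress_ops(ops: list[str]) -> str:
    out = []
    prev, run = None, 0
    for op in ops:
        if op == prev:
            run += 1
        else:
            if prev is not None:
                out.append(f"{run}{prev}")
            prev, run = op, 1
    if prev is not None:
        out.append(f"{run}{prev}")
    return "".join(out)


def _diagonal_clusters(q: str, index: KmerIndex, params: AlignParams) -> list[tuple[int, int, int]]:
    """Seed the query and group hit diagonals.

    Returns up to ``max_clusters`` of (dmin, dmax, n_hits), normalised to
    diagonal values in [0, L).
    """
    k, L = index.k, index.L
    diag_hits: dict[int, int] = {}
    for qpos in range(0, len(q) - k + 1):
        for p in index.positions(q[qpos:qpos + k]):
            d = (p - qpos) % L
            diag_hits[d] = diag_hits.get(d, 0) + 1
    if not diag_hits:
        return []
    diags = sorted(diag_hits)
    clusters: list[list[int]] = [[diags[0]]]
    for d in diags[1:]:
        if d - clusters[-1][-1] <= params.band_pad:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    # wraparound: merge first and last cluster if adjacent on the circle
    if len(clusters) > 1 and (clusters[0][0] + L) - clusters[-1][-1] <= params.band_pad:
        clusters[0] = clusters.pop() + [d + L for d in clusters[0]]
    scored = [(min(c), max(c), sum(diag_hits[d % L] for d in c)) for c in clusters]
    scored.sort(key=lambda t: (-t[2], t[0]))
    return scored[:params.max_clusters]


def align_local(seq: str, index: KmerIndex, genome: CircularGenome,
                params: AlignParams = AlignParams(), read_id: str = "",
                part: str = "whole") -> SegmentAlignment | None:
    """Single best soft-clipped local placement of ``seq``, or None.

    Ties are broken by lowest genome start coordinate, then plus strand.
    """
    L = genome.length
    ref_arr = np.frombuffer((genome.sequence * 3).encode(), dtype=np.uint8)
    best: tuple | None = None
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        q_arr = np.frombuffer(q.encode(), dtype=np.uint8)
        for dmin, dmax, _hits in _diagonal_clusters(q, index, params):
            rstart = max(0, dmin - params.band_pad)
            rend = min(3 * L, dmax + len(q) + params.band_pad)
            if rend <= rstart:
                continue
            res = _window_align(q_arr, ref_arr[rstart:rend], params)
            if res is None:
                continue
            score, qs, qe, rs, re, cigar, edits = res
            gstart = (rstart + rs) % L
            cand = (-score, gstart, 0 if strand == "+" else 1,
                    qs, qe, gstart + (re - rs), strand, cigar, edits, score)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None or best[9] < params.min_score:
        return None
    _, gstart, _, qs, qe, gend, strand, cigar, edits, score = best
    full_cigar = cigar
    if qs > 0:
        full_cigar = f"{qs}S" + full_cigar
    tail = len(seq) - qe
    if tail > 0:
        full_cigar = full_cigar + f"{tail}S"
    return SegmentAlignment(read_id=read_id, part=part, qstart=qs, qend=qe,
                            gstart=gstart, gend=gend, strand=strand,
                            cigar=full_cigar, edit_distance=edits, score=score)


def extract_clips(aln: SegmentAlignment, read_len: int,
                  min_clip: int = 15) -> list[tuple[str, int, int]]:
    """Soft-clip intervals of at least ``min_clip`` nt, as (part, start, end)."""
    clips = []
    if aln.qstart >= min_clip:
        clips.append(("left", 0, aln.qstart))
    if read_len - aln.qend >= min_clip:
        clips.append(("right", aln.qend, read_len))
    return clips


def align_end_to_end(clip_seq: str, genome: CircularGenome, strand: str = "+",
                     max_edits: int | None = None, read_id: str = "",
                     part: str = "left", qoffset: int = 0) -> SegmentAlignment | None:
    """Full-length substitution-only placement of a clipped part.

    Scans every genome offset (circular) and keeps the placement with the
    fewest mismatches if within ``max_edits`` (default ``max(2, 10%)`` of
    the clip length); ties go to the lowest genome coordinate. ``clip_seq``
    must already be in transcript-sense orientation; ``qoffset`` positions
    the clip on the strand-resolved read.
    """
    m = len(clip_seq)
    L = genome.length
    if m > L:
        return None
    if max_edits is None:
        max_edits = max(2, m // 10)
    arr = np.frombuffer(clip_seq.encode(), dtype=np.uint8)
    doubled = np.frombuffer(genome.doubled().encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(doubled, m)[:L]
    mism = np.count_nonzero(windows != arr, axis=1)
    gstart = int(np.argmin(mism))
    edits = int(mism[gstart])
    if edits > max_edits:
        return None
    score = (m - edits) * 2 - edits * 4
    return SegmentAlignment(read_id=read_id, part=part, qstart=qoffset,
                            qend=qoffset + m, gstart=gstart, gend=gstart + m,
                            strand=strand, cigar=f"{m}M", edit_distance=edits,
                            score=score)


def group_segments(segments: list[SegmentAlignment], read_len: int,
                   min_clip: int = 15,
                   accounted: list[tuple[int, int]] | None = None) -> SplitGroup:
    """Order a read's segments and decide completeness.

    ``accounted`` intervals (e.g. recognised non-templated tails at the
    junction) count as placed when assessing completeness. Duplicate
    placements overlapping by more than 4 nt on the read keep only the
    higher-scoring segment.
    """
    if not segments:
        raise ValueError("no segments")
    read_ids = {s.read_id for s in segments}
    if len(read_ids) > 1:
        raise ValueError(f"segments from multiple reads: {sorted(read_ids)}")
    ordered = sorted(segments, key=lambda s: (s.qstart, -s.score))
    kept: list[SegmentAlignment] = []
    for s in ordered:
        if kept and min(kept[-1].qend, s.qend) - max(kept[-1].qstart, s.qstart) > 4:
            if s.score > kept[-1].score:
                kept[-1] = s
            continue
        kept.append(s)
    covered = [(s.qstart, s.qend) for s in kept] + list(accounted or [])
    covered.sort()
    complete = True
    pos = 0
    for s, e in covered:
        if s - pos >= min_clip:
            complete = False
        pos = max(pos, e)
    if read_len - pos >= min_clip:
        complete = False
    return SplitGroup(read_id=kept[0].read_id, segments=kept,
                      complete=complete, read_len=read_len)
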