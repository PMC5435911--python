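"""Adapter trimming and paired-end overlap merging.

Both stages are computed internally (no external trimmer/merger binaries).
Trimming removes 3' adapter read-through; merging reverse-complements mate 2
and joins the pair over the best overlap. Pairs that do not merge contribute
only read 1 downstream — the overlap either failed because the insert is
longer than two read lengths (read 1 still carries usable sequence) or
because of damage, and mate 2 alone adds nothing the aligner needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import revcomp

__all__ = ["ReadPair", "MergedRead", "trim_adapters", "merge_pair", "prepare_pairs"]


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    read_id: str
    seq: str
    qual: str
    merged: bool
    overlap_len: int = 0


def _find_adapter_start(seq: str, adapter: str,
                        max_error_rate: float = 0.1, min_overlap: int = 3) -> int | None:
    """Start of the best 3'-adapter occurrence, or None.

    A candidate either matches the full adapter internally or a prefix of
    the adapter (>= ``min_overlap``) running off the read's 3' end, with a
    mismatch rate <= ``max_error_rate``. The candidate with the lowest
    mismatch rate wins; ties go to the leftmost (longest trim).
    """
    n, m = len(seq), len(adapter)
    best: tuple[float, int] | None = None
    a = np.frombuffer(adapter.encode(), dtype=np.uint8)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    for start in range(0, n - min_overlap + 1):
        ov = min(m, n - start)
        mism = int(np.count_nonzero(s[start:start + ov] != a[:ov]))
        if mism <= max_error_rate * ov:
            rate = mism / ov
            if best is None or rate < best[0] - 1e-12:
                best = (rate, start)
    return None if best is None else best[1]


def trim_adapters(pair: ReadPair, adapter1: str, adapter2: str,
                  min_len: int = 20, max_error_rate: float = 0.1,
                  min_overlap: int = 3) -> ReadPair | None:
    """Remove 3' adapter read-through from both mates; drop short pairs.

    Returns None when either trimmed mate is shorter than ``min_len``.
    """
    if not adapter1 or not adapter2:
        raise ValueError("adapters must be non-empty")
    out = []
    for seq, qual, adapter in ((pair.seq1, pair.qual1, adapter1),
                               (pair.seq2, pair.qual2, adapter2)):
        start = _find_adapter_start(seq, adapter, max_error_rate, min_overlap)
        if start is not None:
            seq, qual = seq[:start], qual[:start]
        out.append((seq, qual))
    (s1, q1), (s2, q2) = out
    if len(s1) < min_len or len(s2) < min_len:
        return None
    return ReadPair(pair.read_id, s1, q1, s2, q2)


def merge_pair(pair: ReadPair, min_overlap: int = 10, max_overlap: int = 245,
               max_mismatch_density: float = 0.25) -> MergedRead:
    """Join two mates over their best 3' overlap.

    Mate 2 is reverse-complemented; candidate overlap lengths from
    ``max_overlap`` down to ``min_overlap`` are scored by mismatch density,
    and the densest-free candidate wins (ties break to the longest overlap).
    Inside the overlap the higher-quality base is kept; quality ties keep
    the mate-1 base. If no candidate passes the density threshold the pair
    stays unmerged and mate 1 passes through alone.
    """
    s1 = np.frombuffer(pair.seq1.encode(), dtype=np.uint8)
    rc2 = revcomp(pair.seq2)
    q2r = pair.qual2[::-1]
    s2 = np.frombuffer(rc2.encode(), dtype=np.uint8)
    l1, l2 = len(s1), len(s2)
    hi = min(max_overlap, l1, l2)
    best: tuple[float, int] | None = None
    for ov in range(hi, min_overlap - 1, -1):
        mism = int(np.count_nonzero(s1[l1 - ov:] != s2[:ov]))
        density = mism / ov
        if density <= max_mismatch_density and (best is None or density < best[0] - 1e-12):
            best = (density, ov)
    if best is None:
        return MergedRead(pair.read_id, pair.seq1, pair.qual1, merged=False)
    ov = best[1]
    head_s, head_q = pair.seq1[:l1 - ov], pair.qual1[:l1 - ov]
    tail_s, tail_q = rc2[ov:], q2r[ov:]
    mid_s, mid_q = [], []
    for i in range(ov):
        b1, c1 = pair.seq1[l1 - ov + i], pair.qual1[l1 - ov + i]
        b2, c2 = rc2[i], q2r[i]
        if b1 == b2 or ord(c1) >= ord(c2):
            mid_s.append(b1)
            mid_q.append(max(c1, c2))
        else:
            mid_s.append(b2)
            mid_q.append(c2)
    return MergedRead(pair.read_id, head_s + "".join(mid_s) + tail_s,
                      head_q + "".join(mid_q) + tail_q, merged=True, overlap_len=ov)


def prepare_pairs(pairs, adapter1: str, adapter2: str, min_len: int = 20,
                  min_overlap: int = 10, max_overlap: int = 245,
                  max_mismatch_density: float = 0.25):
    """Trim then merge a stream of pairs.

    Returns (reads, stats): ``reads`` are MergedRead objects — merged
    sequences plus unmerged read-1 pass-throughs; ``stats`` counts pairs in,
    dropped at trimming, merged, and unmerged.
    """
    reads: list[MergedRead] = []
    stats = {"pairs_in": 0, "dropped_trim": 0, "merged": 0, "unmerged_r1": 0}
    for p in pairs:
        stats["pairs_in"] += 1
        if not isinstance(p, ReadPair):
            p = ReadPair(*p)
        trimmed = trim_adapters(p, adapter1, adapter2, min_len=min_len)
        if trimmed is None:
            stats["dropped_trim"] += 1
            continue
        merged = merge_pair(trimmed, min_overlap=min_overlap, max_overlap=max_overlap,
                            max_mismatch_density=max_mismatch_density)
        stats["merged" if merged.merged else "unmerged_r1"] += 1
        reads.append(merged)
    return reads, stats
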