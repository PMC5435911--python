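"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the implementation's seeding, windowing and
consensus machinery: the alignment oracle is a score-only Gotoh dynamic
program over the full doubled genome, and the period oracle is a naive
per-character smallest-period scan.
"""

import numpy as np
from numba import njit

from circends.align import AlignParams
from circends.genome import CircularGenome, revcomp

PARAMS = AlignParams()


@njit(cache=True)
def _gotoh_best(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    nq, nr = q.size, r.size
    NEG = -(10 ** 7)
    go_ge = gap_open + gap_extend
    Hprev = np.zeros(nr + 1, np.int32)
    Fcol = np.full(nr + 1, NEG, np.int32)
    best = 0
    for i in range(1, nq + 1):
        Hcur = np.zeros(nr + 1, np.int32)
        e = NEG
        qi = q[i - 1]
        for j in range(1, nr + 1):
            f = Hprev[j] + go_ge
            if Fcol[j] + gap_extend > f:
                f = Fcol[j] + gap_extend
            Fcol[j] = f
            e_open = Hcur[j - 1] + go_ge
            e = e_open if e_open > e + gap_extend else e + gap_extend
            s = Hprev[j - 1] + (match if qi == r[j - 1] else mismatch)
            h = 0
            if s > h:
                h = s
            if e > h:
                h = e
            if f > h:
                h = f
            Hcur[j] = h
            if h > best:
                best = h
        Hprev = Hcur
    return best


def oracle_best_score(seq: str, genome: CircularGenome) -> int:
    """Optimal local alignment score of seq against either strand of the
    circular genome (doubled reference linearises origin-spanning hits)."""
    ref = np.frombuffer(genome.doubled().encode(), dtype=np.uint8)
    best = 0
    for q in (seq, revcomp(seq)):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        best = max(best, _gotoh_best(qa, ref, PARAMS.match, PARAMS.mismatch,
                                     PARAMS.gap_open, PARAMS.gap_extend))
    return int(best)


def oracle_min_period(seq: str, min_p: int = 15, min_copies: float = 2.0,
                      max_rate: float = 0.1):
    """Naive smallest qualifying period, counted character by character."""
    n = len(seq)
    for p in range(min_p, int(n / min_copies) + 1):
        mism = sum(1 for i in range(n - p) if seq[i] != seq[i + p])
        if mism <= max_rate * (n - p):
            return p
    return None


def oracle_consensus(seq: str, period: int) -> str:
    """Column-wise majority vote with first-copy tie-break, by counting."""
    out = []
    for j in range(period):
        col = seq[j::period]
        counts = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        top = max(counts.values())
        winners = {ch for ch, c in counts.items() if c == top}
        out.append(col[0] if col[0] in winners else sorted(winners)[0])
    return "".join(out)
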