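"""Collapse rolling-circle tandem repeats inside reads to consensus monomers.

Reverse transcription around a circularized RNA yields cDNA carrying the
molecule's sequence in tandem; a read from such a cDNA can contain several
copies of a short molecule. Before alignment each read is scanned for a
periodic repeat and, if found, collapsed to a single-copy consensus (the
monomer). Consensus voting across copies also corrects most sequencing
errors when three or more copies are present.

The period scan is a direct self-comparison: the smallest period ``p`` for
which ``seq[i] != seq[i+p]`` holds at no more than ``max_mismatch_rate`` of
positions is accepted. Reads without a qualifying period pass through
unchanged with ``copies = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = ["Monomer", "find_period", "collapse", "monomerize_stream"]


@dataclass
class Monomer:
    read_id: str
    monomer_seq: str
    period: int
    copies: float
    consensus_support: float
    was_collapsed: bool
    source_len: int = 0


def find_period(seq: str, min_period: int = 15, min_copies: float = 2.0,
                max_mismatch_rate: float = 0.1) -> int | None:
    """Smallest qualifying repeat period of ``seq``, or None.

    A period must leave at least ``min_copies`` (possibly fractional) copies
    in the read, i.e. ``p <= len(seq) / min_copies``.
    """
    n = len(seq)
    max_period = int(n / min_copies)
    if max_period < min_period:
        return None
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for p in range(min_period, max_period + 1):
        if np.count_nonzero(arr[:-p] != arr[p:]) <= max_mismatch_rate * (n - p):
            return p
    return None


def collapse(seq: str, period: int, read_id: str = "") -> Monomer:
    """Per-column majority-vote consensus over the repeat copies.

    The partial last copy contributes to the columns it covers. Ties keep
    the base from the first copy. ``consensus_support`` is the mean
    per-column fraction of copies agreeing with the consensus.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(period, dtype=np.uint8)
    agree = np.empty(period, dtype=float)
    for j in range(period):
        col = arr[j::period]
        vals, counts = np.unique(col, return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        first = arr[j]
        base = first if first in winners else winners[0]
        out[j] = base
        agree[j] = counts[vals == base][0] / col.size
    return Monomer(read_id=read_id, monomer_seq=out.tobytes().decode(),
                   period=period, copies=n / period,
                   consensus_support=float(agree.mean()),
                   was_collapsed=True, source_len=n)


def monomerize_stream(reads: Iterable[tuple[str, str]], min_period: int = 15,
                      min_copies: float = 2.0,
                      max_mismatch_rate: float = 0.1) -> Iterator[Monomer]:
    """Apply find_period + collapse to (read_id, seq) records.

    Reads without a detected repeat pass through with ``copies = 1`` and
    ``was_collapsed = False``.
    """
    for read_id, seq in reads:
        p = find_period(seq, min_period=min_period, min_copies=min_copies,
                        max_mismatch_rate=max_mismatch_rate)
        if p is None:
            yield Monomer(read_id=read_id, monomer_seq=seq, period=len(seq),
                          copies=1.0, consensus_support=1.0,
                          was_collapsed=False, source_len=len(seq))
        else:
            yield collapse(seq, p, read_id=read_id)
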