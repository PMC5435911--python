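"""Score pipeline output against simulator ground truth.

A simulated read is *evaluable* for junction recovery when, within the
portion of it that actually reached the caller (the merged fragment, or
only the first mate when the pair did not merge), at least one ligation
junction has both molecule-body flanks at the minimum placeable length.
Reads failing that gate cannot pin both termini and are excluded from the
denominator, matching the pipeline's own minimum-segment-length gates.
"""

from __future__ import annotations

import pandas as pd

from .links import PrecursorCall

__all__ = ["junction_recovery"]


def _circ_dist(a: int, b: int, L: int) -> int:
    d = (a - b) % L
    return min(d, L - d)


def junction_recovery(molecules: pd.DataFrame, reads_truth: pd.DataFrame,
                      analyzed_len: dict[str, int],
                      calls: list[PrecursorCall], L: int,
                      min_clip: int = 15, tol: int = 0) -> dict:
    """Fraction of evaluable reads whose call matches truth within ``tol``.

    Returns a dict with ``n_evaluable``, ``n_called``, ``n_matched`` and
    ``rate`` (matched / evaluable). ``tol = 0`` demands exact termini.
    """
    mol = molecules.set_index("molecule_id")
    by_read = {c.read_id: c for c in calls}
    n_eval = n_called = n_matched = 0
    for row in reads_truth.itertuples():
        alen = analyzed_len.get(row.read_id)
        if alen is None or not row.junction_offsets:
            continue
        m = mol.loc[row.molecule_id]
        tail_len = int(m["tail_len"])
        offsets = [int(o) for o in str(row.junction_offsets).split(",") if o]
        clear = [o for o in offsets
                 if o - tail_len >= min_clip and alen - o >= min_clip
                 and o < alen]
        if not clear:
            continue
        n_eval += 1
        c = by_read.get(row.read_id)
        if c is None:
            continue
        n_called += 1
        if (c.strand == m["strand"]
                and _circ_dist(c.five_prime, int(m["five_prime"]), L) <= tol
                and _circ_dist(c.three_prime, int(m["three_prime"]), L) <= tol):
            n_matched += 1
    return {"n_evaluable": n_eval, "n_called": n_called,
            "n_matched": n_matched,
            "rate": n_matched / n_eval if n_eval else float("nan")}
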