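"""Confusion-count scoring of alignments against ground-truth peak groups.

A ground-truth table states, per peak group, in which chromatograms the
peak is present (a scan index) and in which it is absent.  Each truth
group is tested against the predicted alignment: within a matched pair of
rows, per chromatogram,

* present in truth and predicted within tolerance  -> TP,
* present in both but disagreeing beyond tolerance -> FP and FN,
* absent in both                                   -> TN,
* absent in truth, present in prediction           -> FP,
* present in truth, absent in prediction           -> FN,

and a truth group matched by no predicted row contributes its present
entries to FN.  Predicted rows matching no truth group are *unassignable*
(the reference says nothing about them) and are reported separately
rather than inflating FP.  Precision, recall and F1 follow the usual
definitions TP/(TP+FP), TP/(TP+FN) and their harmonic mean.

Profile (DTW) alignments report every scan, so absences and hence TN/FN
are not meaningful there; ``mode="profile"`` restricts reporting to
TP/FP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chromdata import MultipleAlignmentTable

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "match_groups",
    "score",
    "metrics",
    "evaluate_alignment",
]


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0


@dataclass
class Metrics:
    """precision/recall are None when their denominator is zero
    (undefined); F1 is 0 by convention when precision = recall = 0 and
    None when either factor is undefined."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]


def _overlap(truth_row: dict, pred_row: dict, ids, tolerance: int) -> int:
    n = 0
    for cid in ids:
        t, p = truth_row.get(cid), pred_row.get(cid)
        if t is not None and p is not None and abs(t - p) <= tolerance:
            n += 1
    return n


def match_groups(
    predicted: MultipleAlignmentTable,
    truth: MultipleAlignmentTable,
    tolerance: int = 0,
) -> list[tuple[int, Optional[int]]]:
    """Pair each truth row with at most one predicted row.

    Pairing is greedy by descending overlap (number of chromatograms in
    which both rows carry a scan index within ``tolerance`` scans), ties
    broken by the smaller gap in median retention time; each predicted row
    is used at most once and rows sharing no entry stay unpaired.
    Returns ``(truth index, predicted index or None)`` per truth row.
    """
    if list(predicted.chromatogram_ids) != list(truth.chromatogram_ids):
        raise ValueError("predicted and truth tables list different chromatograms")
    ids = truth.chromatogram_ids
    candidates = []
    for ti, trow in enumerate(truth.rows):
        for pi, prow in enumerate(predicted.rows):
            ov = _overlap(trow, prow, ids, tolerance)
            if ov > 0:
                gap = abs(truth.row_median_rt[ti] - predicted.row_median_rt[pi])
                candidates.append((-ov, gap, ti, pi))
    candidates.sort()
    assigned_t: dict[int, int] = {}
    used_p: set[int] = set()
    for negov, _gap, ti, pi in candidates:
        if ti in assigned_t or pi in used_p:
            continue
        assigned_t[ti] = pi
        used_p.add(pi)
    return [(ti, assigned_t.get(ti)) for ti in range(len(truth.rows))]


def score(
    pairings: list[tuple[int, Optional[int]]],
    predicted: MultipleAlignmentTable,
    truth: MultipleAlignmentTable,
    tolerance: int = 0,
) -> tuple[ConfusionCounts, int]:
    """Apply the per-chromatogram counting rules over all pairings.

    Returns the confusion counts and the number of unassignable predicted
    rows (rows matching no truth group).
    """
    ids = truth.chromatogram_ids
    c = ConfusionCounts()
    for ti, pi in pairings:
        trow = truth.rows[ti]
        if pi is None:
            c.FN += sum(1 for cid in ids if trow.get(cid) is not None)
            continue
        prow = predicted.rows[pi]
        for cid in ids:
            t, p = trow.get(cid), prow.get(cid)
            if t is not None and p is not None:
                if abs(t - p) <= tolerance:
                    c.TP += 1
                else:
                    c.FP += 1
                    c.FN += 1
            elif t is None and p is None:
                c.TN += 1
            elif t is None:
                c.FP += 1
            else:
                c.FN += 1
    matched = {pi for _, pi in pairings if pi is not None}
    unassignable = len(predicted.rows) - len(matched)
    return c, unassignable


def metrics(c: ConfusionCounts) -> Metrics:
    """Precision, recall and F1 from confusion counts."""
    p = c.TP / (c.TP + c.FP) if c.TP + c.FP > 0 else None
    r = c.TP / (c.TP + c.FN) if c.TP + c.FN > 0 else None
    if p is None or r is None:
        f1 = None
    elif p + r == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * p * r / (p + r)
    return Metrics(precision=p, recall=r, f1=f1)


def evaluate_alignment(
    predicted: MultipleAlignmentTable,
    truth: MultipleAlignmentTable,
    tolerance: int = 0,
    mode: str = "peak",
) -> dict:
    """One-call evaluation: match, count, derive metrics.

    ``mode="profile"`` (dense DTW output) reports TP/FP only, since a
    profile alignment reports every scan and TN/FN are unavailable.
    """
    pairings = match_groups(predicted, truth, tolerance)
    counts, unassignable = score(pairings, predicted, truth, tolerance)
    out = {
        "TP": counts.TP,
        "FP": counts.FP,
        "unassignable_rows": unassignable,
    }
    if mode == "peak":
        m = metrics(counts)
        out.update(
            FN=counts.FN,
            TN=counts.TN,
            precision=m.precision,
            recall=m.recall,
            f1=m.f1,
        )
    elif mode != "profile":
        raise ValueError("mode must be 'peak' or 'profile'")
    return out
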