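"""Segmentation quality metrics: cell-level counting and the F-measure.

Predicted and reference cells are matched one-to-one, greedily by
descending intersection-over-union; a pair counts as a correct
segmentation (TP) when its IoU reaches the matching threshold (default
0.5).  Unmatched reference cells are FN (leaked or broken cells),
unmatched predictions are FP (red cells or debris segmented as WBCs).
Over-segmentation counts reference cells shattered into several
predictions; under-segmentation counts predictions swallowing several
reference cells — in both cases a secondary overlap must cover at least a
fixed fraction of the reference cell to distinguish genuine splits/merges
from incidental boundary overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Assignment", "EvalReport", "match_regions", "count_outcomes",
           "f_measure", "evaluate_masks"]

#: secondary-overlap floor (fraction of the truth cell's area) used for the
#: over-/under-segmentation bookkeeping
SPLIT_OVERLAP_FLOOR = 0.2


@dataclass
class Assignment:
    """Outcome of matching predicted against reference label masks."""

    matches: list[tuple[int, int, float]]  # (truth, pred, IoU)
    unmatched_truth: list[int]
    unmatched_pred: list[int]
    split_truth: list[int]       # truth cells covered by >= 2 predictions
    merged_pred: list[int]       # predictions covering >= 2 truth cells
    n_truth: int
    n_pred: int


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    overseg: int
    underseg: int
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "overseg": self.overseg, "underseg": self.underseg,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1}


def _overlap_table(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """(n_truth+1) × (n_pred+1) pixel-overlap contingency table."""
    nt, np_ = int(truth.max()), int(pred.max())
    idx = truth.astype(np.int64) * (np_ + 1) + pred.astype(np.int64)
    counts = np.bincount(idx.ravel(), minlength=(nt + 1) * (np_ + 1))
    return counts.reshape(nt + 1, np_ + 1)


def match_regions(pred: np.ndarray, truth: np.ndarray,
                  iou_threshold: float = 0.5) -> Assignment:
    """Greedy one-to-one matching by descending IoU.

    A pair matches when its IoU strictly exceeds the threshold (a perfect
    IoU of 1 still matches at threshold 1), so a prediction covering
    exactly half of a cell does not count as correct at the 0.5 setting.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred/truth shape mismatch")
    if not (0 < iou_threshold <= 1):
        raise ValueError("iou_threshold must be in (0, 1]")
    table = _overlap_table(pred, truth)
    nt, np_ = table.shape[0] - 1, table.shape[1] - 1
    t_area = table.sum(axis=1)
    p_area = table.sum(axis=0)

    cand = []
    for t in range(1, nt + 1):
        for p in range(1, np_ + 1):
            inter = table[t, p]
            if inter == 0:
                continue
            iou = inter / (t_area[t] + p_area[p] - inter)
            cand.append((iou, t, p))
    cand.sort(key=lambda x: (-x[0], x[1], x[2]))

    matches, used_t, used_p = [], set(), set()
    for iou, t, p in cand:
        # strictly exceed the threshold: a half-covering prediction (IoU
        # exactly 0.5) is not a correct segmentation at the 0.5 setting
        if iou <= iou_threshold - (iou_threshold == 1.0) * 1e-9 \
                or t in used_t or p in used_p:
            continue
        matches.append((t, p, float(iou)))
        used_t.add(t)
        used_p.add(p)

    split_truth = []
    for t in range(1, nt + 1):
        if t_area[t] == 0:
            continue
        big = sum(1 for p in range(1, np_ + 1)
                  if table[t, p] >= SPLIT_OVERLAP_FLOOR * t_area[t])
        if big >= 2:
            split_truth.append(t)
    merged_pred = []
    for p in range(1, np_ + 1):
        if p_area[p] == 0:
            continue
        big = sum(1 for t in range(1, nt + 1)
                  if t_area[t] > 0
                  and table[t, p] >= SPLIT_OVERLAP_FLOOR * t_area[t])
        if big >= 2:
            merged_pred.append(p)

    present_t = [t for t in range(1, nt + 1) if t_area[t] > 0]
    present_p = [p for p in range(1, np_ + 1) if p_area[p] > 0]
    return Assignment(
        matches=matches,
        unmatched_truth=[t for t in present_t if t not in used_t],
        unmatched_pred=[p for p in present_p if p not in used_p],
        split_truth=split_truth,
        merged_pred=merged_pred,
        n_truth=len(present_t),
        n_pred=len(present_p),
    )


def f_measure(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean, all in [0, 1].

    Empty-success convention: a zero denominator yields 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def count_outcomes(assignment: Assignment) -> EvalReport:
    tp = len(assignment.matches)
    fn = len(assignment.unmatched_truth)
    fp = len(assignment.unmatched_pred)
    precision, recall, f1 = f_measure(tp, fp, fn)
    return EvalReport(tp=tp, fp=fp, fn=fn,
                      overseg=len(assignment.split_truth),
                      underseg=len(assignment.merged_pred),
                      precision=precision, recall=recall, f1=f1)


def evaluate_masks(pred: np.ndarray, truth: np.ndarray,
                   iou_threshold: float = 0.5) -> EvalReport:
    """Convenience wrapper: match then count."""
    return count_outcomes(match_regions(pred, truth, iou_threshold))
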