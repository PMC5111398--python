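"""Confusion-matrix comparison of a detection table against a truth table.

The comparison grid is the FULL reference-species x sample grid: reference
species never seen in any sample count as true negatives, which is what
makes profiling success (= (TP+TN)/grid size) well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = ["ConfusionSummary", "confusion", "threshold_sweep"]


@dataclass
class ConfusionSummary:
    tp: int
    tn: int
    fp: int
    fn: int
    discrepancy_list: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def detection_rate(self) -> float:
        """True positives over truth-present combinations (TP / (TP + FN))."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else 1.0

    @property
    def profiling_success(self) -> float:
        """(TP + TN) over the full grid."""
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(detected: pd.DataFrame, truth: pd.DataFrame) -> ConfusionSummary:
    """Cell-wise comparison of two boolean species x sample matrices."""
    if set(detected.index) != set(truth.index) or set(detected.columns) != set(truth.columns):
        missing_sp = set(detected.index) ^ set(truth.index)
        missing_sa = set(detected.columns) ^ set(truth.columns)
        raise ValueError(
            f"label mismatch: species diff {sorted(missing_sp)}, sample diff {sorted(missing_sa)}"
        )
    truth = truth.reindex(index=detected.index, columns=detected.columns)
    det = detected.astype(bool)
    tru = truth.astype(bool)
    tp = int((det & tru).to_numpy().sum())
    tn = int((~det & ~tru).to_numpy().sum())
    fp = int((det & ~tru).to_numpy().sum())
    fn = int((~det & tru).to_numpy().sum())
    discrepancies = []
    for sp in det.index:
        for sa in det.columns:
            d, t = bool(det.loc[sp, sa]), bool(tru.loc[sp, sa])
            if d and not t:
                discrepancies.append((sp, sa, "false_positive"))
            elif t and not d:
                discrepancies.append((sp, sa, "false_negative"))
    return ConfusionSummary(tp, tn, fp, fn, discrepancies)


def threshold_sweep(
    coverage_matrix: pd.DataFrame,
    truth: pd.DataFrame,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """One confusion summary per detection threshold (strict > calls).

    Returns a table with columns threshold, tp, tn, fp, fn, detection_rate,
    profiling_success.
    """
    thresholds = list(thresholds)
    if any(not 0 < t < 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    rows = []
    for t in thresholds:
        summ = confusion(coverage_matrix > t, truth)
        rows.append(
            (t, summ.tp, summ.tn, summ.fp, summ.fn, summ.detection_rate, summ.profiling_success)
        )
    return pd.DataFrame(
        rows,
        columns=["threshold", "tp", "tn", "fp", "fn", "detection_rate", "profiling_success"],
    )
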