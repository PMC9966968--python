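"""Patient-wise splitting and classifier evaluation.

Weak effort is the positive class (label 1). Metrics use the standard
confusion-matrix formulas; metrics with a zero denominator are reported as
None, never silently as 0. The respiratory-rate baseline predicts a weak
effort whenever the breath's own rate (60/Ttot) falls below a threshold,
mirroring the bedside rule the classifier is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Confusion",
    "MetricSet",
    "split_by_patient",
    "confusion",
    "metrics",
    "rr_baseline",
    "fp_ptp_distribution",
]


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must be non-empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Fractions in [0, 1]; None marks an undefined (0/0) ratio."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float


def confusion(preds: Sequence, labels: Sequence) -> Confusion:
    """Counts with weak (1/True) as the positive class."""
    p = np.asarray(preds).astype(bool)
    y = np.asarray(labels).astype(bool)
    if p.size != y.size:
        raise ValueError("preds and labels must have equal length")
    if p.size == 0:
        raise ValueError("empty input")
    return Confusion(
        tp=int(np.sum(p & y)),
        fp=int(np.sum(p & ~y)),
        tn=int(np.sum(~p & ~y)),
        fn=int(np.sum(~p & y)),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(c: Confusion) -> MetricSet:
    return MetricSet(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        accuracy=(c.tp + c.tn) / c.total,
    )


def split_by_patient(
    patient_ids: Sequence,
    labels: Sequence,
    fractions: Tuple[float, float, float] = (0.45, 0.15, 0.40),
    seed: int = 0,
    max_retries: int = 200,
) -> Dict[str, List]:
    """Partition patients into train/val/test so no patient spans splits.

    ``patient_ids``/``labels`` are per-breath. Patients are shuffled with
    the given seed; among ``max_retries`` shuffles satisfying
    both-classes-per-split, the one with breath-level class prevalence
    closest to the cohort's in every split is kept. Raises when no shuffle
    achieves class coverage.
    """
    pids = np.asarray(patient_ids)
    y = np.asarray(labels).astype(bool)
    if pids.size != y.size:
        raise ValueError("patient_ids and labels must have equal length")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    unique = np.array(sorted(set(pids.tolist())))
    if unique.size < 3:
        raise ValueError("need at least 3 patients for a 3-way split")
    rng = np.random.default_rng(seed)
    prevalence = y.mean()
    n = unique.size
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = max(1, int(round(fractions[1] * n)))
    n_val = min(n_val, n - n_train - 1)
    best, best_cost = None, np.inf
    for _ in range(max_retries):
        perm = rng.permutation(unique)
        parts = {
            "train": perm[:n_train],
            "val": perm[n_train : n_train + n_val],
            "test": perm[n_train + n_val :],
        }
        ok = True
        cost = 0.0
        for part in parts.values():
            mask = np.isin(pids, part)
            part_y = y[mask]
            if part_y.size == 0 or part_y.all() or not part_y.any():
                ok = False
                break
            cost = max(cost, abs(part_y.mean() - prevalence))
        if ok and cost < best_cost:
            best, best_cost = {k: sorted(v.tolist()) for k, v in parts.items()}, cost
    if best is None:
        raise ValueError("could not build a split with both classes in each part")
    return best


def rr_baseline(
    ttot: Sequence[float], weak: Sequence, rr_threshold: float = 17.0
) -> MetricSet:
    """Respiratory-rate rule: predict weak iff 60/Ttot < rr_threshold."""
    ttot = np.asarray(ttot, dtype=float)
    rr = 60.0 / ttot
    preds = rr < rr_threshold
    return metrics(confusion(preds, weak))


def fp_ptp_distribution(
    pred_weak: Sequence,
    true_weak: Sequence,
    ptp_min: Sequence[float],
    bin_edges: Sequence[float] = (50.0, 75.0, 100.0, 125.0, 150.0, np.inf),
) -> pd.DataFrame:
    """PTP/min histogram among false positives, as % of all FP.

    Bins are [threshold, e1), [e1, e2), ... with the weak threshold taken
    as the first edge's lower bound being the label threshold itself; the
    returned DataFrame has columns ``lo``, ``hi``, ``pct``. Zero false
    positives yield an empty, flagged frame (attribute ``empty`` True).
    """
    pred = np.asarray(pred_weak).astype(bool)
    true = np.asarray(true_weak).astype(bool)
    ptp = np.asarray(ptp_min, dtype=float)
    fp = pred & ~true
    edges = np.asarray(bin_edges, dtype=float)
    lo = edges[:-1]
    hi = edges[1:]
    if fp.sum() == 0:
        return pd.DataFrame({"lo": lo, "hi": hi, "pct": np.full(lo.size, np.nan)})
    vals = ptp[fp]
    counts = np.array(
        [np.sum((vals >= a) & (vals < b)) for a, b in zip(lo, hi)], dtype=float
    )
    return pd.DataFrame({"lo": lo, "hi": hi, "pct": 100.0 * counts / fp.sum()})
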