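"""Confusion matrices, per-class F1 reports, and split protocols.

Per-class scores are one-vs-rest off the confusion matrix:
P = TP / (TP + FP), R = TP / (TP + FN), F1 = 2PR / (P + R), with the 0/0
cases defined as 0. The headline "average" figure is the unweighted mean of
the per-class values (macro averaging), matching how published per-group
averages are formed from per-activity columns.

The split protocol mirrors leave-one-out over fixed-length sequence
recordings: sequences are grouped by activity and divided into k splits so
that each test split holds exactly one sequence per activity; training uses
everything else. When every activity has exactly k sequences the test
splits partition the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "ClassReport",
    "confusion",
    "f1_report",
    "loocv_splits",
    "average_over_splits",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer count matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("counts must be square and match the class list")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass(frozen=True)
class ClassReport:
    """Per-class precision/recall/F1 plus macro averages, all in [0, 1]."""

    classes: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "precision": [float(x) for x in self.precision],
            "recall": [float(x) for x in self.recall],
            "f1": [float(x) for x in self.f1],
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def confusion(true_labels, pred_labels, classes) -> ConfusionMatrix:
    """Tally a confusion matrix over an explicit ordered class list."""
    classes = tuple(classes)
    known = set(classes)
    for lab in list(true_labels) + list(pred_labels):
        if lab not in known:
            raise KeyError(f"label {lab!r} not in class list")
    counts = _sk_confusion(list(true_labels), list(pred_labels), labels=list(classes))
    return ConfusionMatrix(counts, classes)


def f1_report(cm: ConfusionMatrix) -> ClassReport:
    """One-vs-rest precision, recall and F1 per class; 0/0 defined as 0."""
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        r = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(p + r > 0, 2.0 * p * r / (p + r), 0.0)
    return ClassReport(cm.classes, p, r, f1)


def loocv_splits(
    sequence_activities: dict[int, str] | list[tuple[int, str]],
    k: int,
    seed: int = 0,
) -> list[tuple[list[int], list[int]]]:
    """k splits, each test split holding exactly one sequence per activity.

    ``sequence_activities`` maps sequence id -> activity label. Assignment
    of sequences to splits is a seeded shuffle within each activity.
    Sequences beyond k per activity never enter a test split (they stay in
    every training set); with exactly k per activity the test splits
    partition the data. Raises if any activity has fewer than k sequences.
    """
    if isinstance(sequence_activities, dict):
        items = list(sequence_activities.items())
    else:
        items = list(sequence_activities)
    by_act: dict[str, list[int]] = {}
    for sid, act in items:
        by_act.setdefault(act, []).append(sid)
    rng = np.random.default_rng(seed)
    for act, sids in by_act.items():
        if len(sids) < k:
            raise ValueError(
                f"activity {act!r} has {len(sids)} sequences; needs at least {k}"
            )
        rng.shuffle(sids)
    all_ids = [sid for sid, _ in items]
    splits = []
    for i in range(k):
        test = sorted(sids[i] for sids in by_act.values())
        test_set = set(test)
        train = [sid for sid in all_ids if sid not in test_set]
        splits.append((train, test))
    return splits


def average_over_splits(reports: list[ClassReport]) -> ClassReport:
    """Elementwise mean of per-split reports (same class set required)."""
    if not reports:
        raise ValueError("no reports to average")
    classes = reports[0].classes
    for rep in reports[1:]:
        if rep.classes != classes:
            raise ValueError("reports have mismatched class sets")
    return ClassReport(
        classes,
        np.mean([r.precision for r in reports], axis=0),
        np.mean([r.recall for r in reports], axis=0),
        np.mean([r.f1 for r in reports], axis=0),
    )
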