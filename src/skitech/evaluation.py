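"""Confusion matrices and classification metrics.

The confusion matrix follows the orientation used throughout this package:
columns are the labeled (true) class, rows the classified (predicted)
class.  Per-class sensitivity (true positive rate, TP / (TP + FN)) runs
along the bottom margin, per-class precision (positive predictive value,
TP / (TP + FP)) along the right margin, and the overall accuracy
(trace / grand total) sits in the bottom-right corner.  Cycles excluded
because of missing sensor data (EXC) never enter the matrix; they are
tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CLASSES, SubTechnique

__all__ = [
    "ConfusionMatrix",
    "build_confusion",
    "sensitivity",
    "precision",
    "accuracy",
    "render_confusion",
    "merge_classes",
]


@dataclass
class ConfusionMatrix:
    """Labeled-vs-classified count table.

    ``counts[r, c]`` is the number of cycles labeled ``classes[c]`` and
    classified ``classes[r]``.
    """

    counts: np.ndarray
    classes: tuple = CLASSES
    excluded_count: int = 0

    def __post_init__(self) -> None:
        k = len(self.classes)
        m = np.asarray(self.counts)
        if m.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(m < 0) or not np.issubdtype(m.dtype, np.integer):
            m = m.astype(float)
            if np.any(m < 0) or np.any(m != np.rint(m)):
                raise ValueError("counts must be non-negative integers")
        self.counts = np.rint(m).astype(int)

    # -- basic aggregates ---------------------------------------------------
    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def labeled_counts(self) -> np.ndarray:
        """Per-class labeled totals (column sums)."""
        return self.counts.sum(axis=0)

    def classified_counts(self) -> np.ndarray:
        """Per-class classified totals (row sums)."""
        return self.counts.sum(axis=1)

    def _index(self, cls) -> int:
        return self.classes.index(cls)

    # -- metrics ------------------------------------------------------------
    def sensitivity(self, cls) -> float | None:
        """100 * TP / (TP + FN); None when the class was never labeled."""
        i = self._index(cls)
        col = self.counts[:, i].sum()
        if col == 0:
            return None
        return 100.0 * self.counts[i, i] / col

    def precision(self, cls) -> float | None:
        """100 * TP / (TP + FP); None when the class was never predicted."""
        i = self._index(cls)
        row = self.counts[i, :].sum()
        if row == 0:
            return None
        return 100.0 * self.counts[i, i] / row

    def accuracy(self) -> float | None:
        """100 * trace / grand total; None for an empty matrix."""
        if self.total == 0:
            return None
        return 100.0 * np.trace(self.counts) / self.total

    # -- presentation -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        names = [str(c) for c in self.classes]
        return pd.DataFrame(self.counts, index=names, columns=names)

    def render(self) -> str:
        return render_confusion(self)


def build_confusion(
    pairs: Iterable[tuple[SubTechnique, SubTechnique]],
    classes: Sequence[SubTechnique] = CLASSES,
) -> ConfusionMatrix:
    """Count (true label, predicted label) pairs into a confusion matrix.

    Pairs in which either side is EXC are counted only in
    ``excluded_count``.
    """
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    excluded = 0
    for true, pred in pairs:
        if true is SubTechnique.EXC or pred is SubTechnique.EXC:
            excluded += 1
            continue
        counts[idx[pred], idx[true]] += 1
    return ConfusionMatrix(counts, classes, excluded)


def sensitivity(cm: ConfusionMatrix, cls) -> float | None:
    return cm.sensitivity(cls)


def precision(cm: ConfusionMatrix, cls) -> float | None:
    return cm.precision(cls)


def accuracy(cm: ConfusionMatrix) -> float | None:
    return cm.accuracy()


def _fmt(value: float | None) -> str:
    return "N/A" if value is None else f"{value:.1f}%"


def render_confusion(cm: ConfusionMatrix) -> str:
    """Text rendering with sensitivity bottom row, precision right column
    and overall accuracy in the bottom-right corner."""
    names = [str(c) for c in cm.classes]
    width = max(8, max(len(n) for n in names) + 2)
    header = " " * width + "".join(f"{n:>{width}}" for n in names) + f"{'Prec':>{width}}"
    lines = [header]
    for i, name in enumerate(names):
        cells = "".join(f"{cm.counts[i, j]:>{width}d}" for j in range(len(names)))
        lines.append(f"{name:>{width}}" + cells + f"{_fmt(cm.precision(cm.classes[i])):>{width}}")
    sens = "".join(f"{_fmt(cm.sensitivity(c)):>{width}}" for c in cm.classes)
    lines.append(f"{'Sens':>{width}}" + sens + f"{_fmt(cm.accuracy()):>{width}}")
    if cm.excluded_count:
        lines.append(f"(excluded cycles: {cm.excluded_count})")
    return "\n".join(lines)


def merge_classes(
    cm: ConfusionMatrix,
    groups: Mapping[str, Sequence[SubTechnique]],
) -> ConfusionMatrix:
    """Post-hoc merge of classes (e.g. DIA + tDIA + fDIA + HRB into one
    'diagonal family') by summing the corresponding rows and columns.

    Classes not named in any group keep their own singleton group.  The
    returned matrix uses group names (strings) as its class labels.
    """
    assigned: dict[SubTechnique, str] = {}
    for name, members in groups.items():
        for m in members:
            if m in assigned:
                raise ValueError(f"class {m} assigned to multiple groups")
            assigned[m] = name
    order: list[str] = []
    for c in cm.classes:
        g = assigned.get(c, str(c))
        if g not in order:
            order.append(g)
    gidx = {g: i for i, g in enumerate(order)}
    out = np.zeros((len(order), len(order)), dtype=int)
    for i, ci in enumerate(cm.classes):
        for j, cj in enumerate(cm.classes):
            out[gidx[assigned.get(ci, str(ci))], gidx[assigned.get(cj, str(cj))]] += cm.counts[i, j]
    return ConfusionMatrix(out, tuple(order), cm.excluded_count)
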