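"""Binary-classification evaluation for the deficient/excess pulse qualities.

The confusion table is laid out the way the clinical concordance tables are
printed: rows are the expert (reference) label, columns the predicted label,
classes ordered (deficient, excess).  Accuracy is the concordance rate and the
Matthews correlation coefficient (MCC) is the balanced ±1 statistic of the
2×2 table, preferred when the two classes have very different sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFICIENT = "deficient"
EXCESS = "excess"
CLASSES = (DEFICIENT, EXCESS)


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 confusion counts indexed (expert label) × (predicted label).

    ``counts[0, 0]`` is (deficient, deficient), ``counts[1, 1]`` is
    (excess, excess).  Deficient is the bookkeeping "positive" class.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (2, 2):
            raise ValueError(f"confusion table must be 2x2, got {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_counts(cls, dd: int, de: int, ed: int, ee: int) -> "ConfusionTable":
        """Build from the four printed counts, row-major:
        (true deficient, pred deficient), (true deficient, pred excess),
        (true excess, pred deficient), (true excess, pred excess)."""
        return cls(np.array([[dd, de], [ed, ee]], dtype=int))

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(self.counts + other.counts)


def confusion(true_labels, predicted_labels) -> ConfusionTable:
    """Tally a 2×2 confusion table from parallel label vectors.

    Labels must be drawn from {"deficient", "excess"}.
    """
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"label vectors differ in length: {len(t)} vs {len(p)}")
    idx = {DEFICIENT: 0, EXCESS: 1}
    counts = np.zeros((2, 2), dtype=int)
    for ti, pi in zip(t, p):
        if ti not in idx or pi not in idx:
            raise ValueError(f"unknown label value: {ti!r} / {pi!r}")
        counts[idx[ti], idx[pi]] += 1
    return ConfusionTable(counts)


def accuracy(table: ConfusionTable) -> float:
    """Concordance rate: trace / total."""
    if table.total == 0:
        raise ValueError("empty confusion table")
    return float(np.trace(table.counts)) / table.total


def mcc(table: ConfusionTable) -> float:
    """Matthews correlation coefficient of a 2×2 table.

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) with the
    deficient class as TP bookkeeping.  A zero denominator (a degenerate
    margin) returns 0 by the standard convention; the value is symmetric
    under a simultaneous swap of both classes.
    """
    if table.total == 0:
        raise ValueError("empty confusion table")
    tp, fn = (int(x) for x in table.counts[0])
    fp, tn = (int(x) for x in table.counts[1])
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)
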