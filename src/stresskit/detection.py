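"""Signal-detection-theory accounting over classified minute blocks.

Hits and misses are tallied against true-stress blocks, false alarms and
correct rejections against true-non-stress blocks. Accuracy is
(hits + correct rejections) over all blocks; hit rate and false-alarm
rate divide by their class totals and are reported as undefined (None)
rather than zero when a class is empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfusionCounts", "DetectionMetrics", "count_outcomes", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejections

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.hits + other.hits,
            self.misses + other.misses,
            self.false_alarms + other.false_alarms,
            self.correct_rejections + other.correct_rejections,
        )


@dataclass(frozen=True)
class DetectionMetrics:
    """Rates derived from confusion counts; None marks an undefined rate."""

    accuracy: float
    hit_rate: float | None
    false_alarm_rate: float | None


def count_outcomes(
    truth: Sequence[int], predicted: Sequence[int]
) -> ConfusionCounts:
    """Tally block-level outcomes of predictions against ground truth."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.size != p.size:
        raise ValueError(f"length mismatch: {t.size} truth vs {p.size} predicted")
    if t.size == 0:
        raise ValueError("empty input")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("truth and predictions must be 0/1")
    return ConfusionCounts(
        hits=int(np.sum((t == 1) & (p == 1))),
        misses=int(np.sum((t == 1) & (p == 0))),
        false_alarms=int(np.sum((t == 0) & (p == 1))),
        correct_rejections=int(np.sum((t == 0) & (p == 0))),
    )


def compute_metrics(counts: ConfusionCounts) -> DetectionMetrics:
    """Accuracy, hit rate, and false-alarm rate from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    n_stress = counts.hits + counts.misses
    n_nonstress = counts.false_alarms + counts.correct_rejections
    return DetectionMetrics(
        accuracy=(counts.hits + counts.correct_rejections) / counts.total,
        hit_rate=counts.hits / n_stress if n_stress > 0 else None,
        false_alarm_rate=counts.false_alarms / n_nonstress if n_nonstress > 0 else None,
    )
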