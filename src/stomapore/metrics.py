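"""Evaluation metrics for detection and measurement quality.

Detection quality is scored by matching detections to ground-truth stomata
(one-to-one, greedy by center distance, a match requiring the true center to
fall inside the detected box) and summarising the confusion counts as
percentages.  ``accuracy`` here is the critical-success-index form
``TP / (TP + FP + FN)`` — the convention of the plant-phenotyping literature
this tool follows, where true negatives are undefined for detection.

Measurement quality is scored as agreement ``100 − |measured − reference| /
reference · 100`` (percent), and the pore identification rate is the
fraction of accepted identifications that are accurate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .cascade import Detection

__all__ = [
    "ConfusionCounts",
    "DetectionMetrics",
    "MeasurementComparison",
    "match_detection_indices",
    "match_detections",
    "detection_metrics",
    "measurement_agreement",
    "pore_identification_rate",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as tabulated percentages usually are."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Detection confusion counts (true negatives are undefined)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class DetectionMetrics:
    """Percentage summary of detection confusion counts."""

    counts: ConfusionCounts
    precision_pct: float
    recall_pct: float
    accuracy_pct: float
    f1: float


@dataclass(frozen=True)
class MeasurementComparison:
    """Agreement between an estimate and its reference (true) value."""

    y_true: float
    y_est: float
    relative_error_pct: float
    agreement_pct: float


def match_detection_indices(
    detections: Sequence[Detection],
    true_centers: np.ndarray,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One-to-one matching of detections to true stomata centers.

    Candidate pairs are those where the true center lies inside the detected
    box (half-open, as the boxes are); pairs are accepted greedily by
    increasing center distance, each detection and each truth used at most
    once.  Returns ``(matches, unmatched_detections, unmatched_truths)``
    where matches are ``(detection_index, truth_index)`` pairs.
    """
    true_centers = np.asarray(true_centers, dtype=np.float64).reshape(-1, 2)
    pairs = []
    for di, det in enumerate(detections):
        cr, cc = det.center
        r0, c0, r1, c1 = det.box
        for ti, (tr, tc) in enumerate(true_centers):
            if r0 <= tr < r1 and c0 <= tc < c1:
                pairs.append((float(np.hypot(cr - tr, cc - tc)), di, ti))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matches.append((di, ti))
    unmatched_d = [i for i in range(len(detections)) if i not in used_d]
    unmatched_t = [i for i in range(len(true_centers)) if i not in used_t]
    return matches, unmatched_d, unmatched_t


def match_detections(
    detections: Sequence[Detection], true_centers: np.ndarray
) -> ConfusionCounts:
    """Confusion counts under the one-to-one center-in-box matching rule."""
    matches, unmatched_d, unmatched_t = match_detection_indices(detections, true_centers)
    return ConfusionCounts(tp=len(matches), fp=len(unmatched_d), fn=len(unmatched_t))


def detection_metrics(counts: ConfusionCounts) -> DetectionMetrics:
    """Precision, recall, CSI accuracy (percent) and F1 from counts.

    Degenerate zero denominators yield 0 for the affected ratio; all-zero
    counts additionally emit a warning.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp + fn == 0:
        warnings.warn("no detections and no ground truth; all metrics defined as 0", stacklevel=2)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return DetectionMetrics(
        counts=counts,
        precision_pct=100.0 * precision,
        recall_pct=100.0 * recall,
        accuracy_pct=100.0 * accuracy,
        f1=f1,
    )


def measurement_agreement(y_true: float, y_est: float) -> MeasurementComparison:
    """Relative error |(Y − Ŷ)/Y|·100 and its complement, in percent."""
    if y_true == 0:
        raise ValueError("true value must be non-zero")
    rel = 100.0 * abs(y_true - y_est) / abs(y_true)
    return MeasurementComparison(
        y_true=float(y_true),
        y_est=float(y_est),
        relative_error_pct=rel,
        agreement_pct=100.0 - rel,
    )


def pore_identification_rate(n_accurate: int, n_inaccurate: int) -> float:
    """Percentage of accepted pore identifications that are accurate."""
    if n_accurate < 0 or n_inaccurate < 0:
        raise ValueError("counts must be non-negative")
    total = n_accurate + n_inaccurate
    if total == 0:
        raise ValueError("at least one identification is required")
    return 100.0 * n_accurate / total
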