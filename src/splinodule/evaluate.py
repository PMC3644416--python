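"""Scoring: segmentation-area comparison statistics and detection metrics.

The segmentation comparison follows the manual-vs-automatic area convention:
``M_d = |M_a - A_a|`` (mean difference between manual and automatic areas, in
pixels) and the percentage ``100 * M_d / (M_a + A_a)``, implemented exactly as
printed in its source even though that quantity *decreases* as the areas
agree; the repo-defined complement :func:`area_agreement_pct`
(``100 * (1 - M_d / (M_a + A_a))``) is provided under its own name for anyone
wanting a number that grows with agreement.

Detection scoring matches detections to ground-truth nodules greedily by
ascending distance with one-to-one assignment inside a match radius — simple,
deterministic, and permutation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "DetectionScore",
    "SegmentationComparison",
    "accuracy_pct",
    "area_agreement_pct",
    "compare_segmentations",
    "detection_metrics",
    "mean_difference",
]


@dataclass(frozen=True)
class SegmentationComparison:
    manual_area: float
    automatic_area: float
    mean_difference: float
    accuracy_pct: float


def mean_difference(manual_area, automatic_area):
    """``M_d = |M_a - A_a|``, integer-exact for integer inputs."""
    if manual_area < 0 or automatic_area < 0:
        raise ConfigurationError("areas must be non-negative")
    return abs(manual_area - automatic_area)


def accuracy_pct(manual_area, automatic_area) -> float:
    """The printed comparison percentage ``100 * |M_a - A_a| / (M_a + A_a)``."""
    total = manual_area + automatic_area
    if total <= 0:
        raise ConfigurationError("M_a + A_a must be positive")
    return 100.0 * mean_difference(manual_area, automatic_area) / total


def area_agreement_pct(manual_area, automatic_area) -> float:
    """Repo-defined complement: ``100 * (1 - |M_a - A_a| / (M_a + A_a))``."""
    return 100.0 - accuracy_pct(manual_area, automatic_area)


def compare_segmentations(manual_area, automatic_area) -> SegmentationComparison:
    return SegmentationComparison(
        manual_area=manual_area,
        automatic_area=automatic_area,
        mean_difference=mean_difference(manual_area, automatic_area),
        accuracy_pct=accuracy_pct(manual_area, automatic_area),
    )


@dataclass
class DetectionScore:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    match_radius: float
    precision_defined: bool = True
    recall_defined: bool = True
    matches: list[tuple[int, int]] = field(default_factory=list)  # (det_idx, truth_idx)

    @property
    def matched_truth(self) -> frozenset:
        return frozenset(t for _, t in self.matches)


def _position(item):
    """Extract (slice, row, col) from a tuple, dict, or candidate-like object."""
    if isinstance(item, dict):
        return (float(item.get("slice", -1)), float(item["row"]), float(item["col"]))
    if hasattr(item, "center"):
        center = item.center
        if len(center) == 3:
            return tuple(float(v) for v in center)
        s = getattr(item, "slice_index", -1)
        return (float(s), float(center[0]), float(center[1]))
    item = tuple(item)
    if len(item) == 2:
        return (-1.0, float(item[0]), float(item[1]))
    return tuple(float(v) for v in item)


def detection_metrics(detections, truth, match_radius: float) -> DetectionScore:
    """Greedy one-to-one matching of detections against ground truth.

    Pairs within ``match_radius`` (in-plane distance; slice indices must agree
    when both sides carry one) are matched in ascending-distance order;
    unmatched detections count as false positives, unmatched truths as false
    negatives.  Undefined precision/recall (empty denominators) are reported
    as 0 and flagged.
    """
    det_pos = [_position(d) for d in detections]
    tru_pos = [_position(t) for t in truth]
    pairs = []
    for i, dp in enumerate(det_pos):
        for j, tp in enumerate(tru_pos):
            if dp[0] >= 0 and tp[0] >= 0 and dp[0] != tp[0]:
                continue
            dist = float(np.hypot(dp[1] - tp[1], dp[2] - tp[2]))
            if dist <= match_radius:
                pairs.append((dist, i, j))
    pairs.sort()
    used_d, used_t, matches = set(), set(), []
    for dist, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matches.append((i, j))
    tp = len(matches)
    fp = len(det_pos) - tp
    fn = len(tru_pos) - tp
    return DetectionScore(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=tp / (tp + fp) if (tp + fp) else 0.0,
        recall=tp / (tp + fn) if (tp + fn) else 0.0,
        match_radius=float(match_radius),
        precision_defined=bool(tp + fp),
        recall_defined=bool(tp + fn),
        matches=matches,
    )
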