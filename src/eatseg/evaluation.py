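"""Episode-level, boundary, and per-datum scoring of detections.

Episode metrics treat the meal/snack as the unit: a ground-truth meal with any
(strictly positive) overlap with a detection is a true positive, a meal with no
overlap is a miss, and a detection overlapping no meal is a false positive.
One detection covering k meals yields k TPs (each meal is evaluated for its own
TP); one meal covered by k detections is a single TP.  True negatives are not
defined at this level, so we report TPR, FP/TP and FP/day rather than
precision/recall.

Boundary errors are signed (detected - self-reported) in minutes, computed for
TP meals only, using the start of the first and the end of the last overlapping
detection.  A negative start error means detection began before the
self-reported meal start.

Datum metrics are the standard confusion-matrix ratios over per-datum masks;
weighted accuracy ACC_W is the class-balanced accuracy (recall + TNR) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cad_io import Episode, EpisodeList


def _overlap_s(a: Episode, b: Episode) -> float:
    return max(0.0, min(a.end_s, b.end_s) - max(a.start_s, b.start_s))


@dataclass
class EpisodeConfusion:
    """Matched TP / miss / FP structure for one or more days."""

    tp_meals: list[tuple[Episode, Episode, Episode]] = field(default_factory=list)
    # (meal, first overlapping detection, last overlapping detection)
    missed_meals: list[Episode] = field(default_factory=list)
    fp_detections: list[Episode] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.tp_meals)

    @property
    def miss(self) -> int:
        return len(self.missed_meals)

    @property
    def fp(self) -> int:
        return len(self.fp_detections)

    def merge(self, other: "EpisodeConfusion") -> "EpisodeConfusion":
        """Pool counts across days (used when aggregating a test fold)."""
        return EpisodeConfusion(
            tp_meals=self.tp_meals + other.tp_meals,
            missed_meals=self.missed_meals + other.missed_meals,
            fp_detections=self.fp_detections + other.fp_detections,
        )


@dataclass
class EpisodeMetrics:
    tpr: float
    fp_per_tp: float  # NaN when undefined (TP = 0)
    fp_per_day: float

    @property
    def fp_per_tp_defined(self) -> bool:
        return not math.isnan(self.fp_per_tp)


@dataclass
class BoundaryErrors:
    """Signed errors in minutes: mean and (population) sd of start and end."""

    start_mean_min: float
    start_sd_min: float
    end_mean_min: float
    end_sd_min: float

    @property
    def mean_abs_min(self) -> float:
        return (abs(self.start_mean_min) + abs(self.end_mean_min)) / 2


@dataclass
class DatumMetrics:
    precision: float
    recall: float
    tnr: float
    f1: float
    weighted_accuracy: float  # (recall + TNR) / 2


@dataclass
class MetricsReport:
    """Everything one evaluation run produces, episode to datum level."""

    episode: EpisodeMetrics
    boundary: BoundaryErrors | None
    datum: DatumMetrics
    window_accuracy: float | None = None
    n_days: int = 1

    def to_dict(self) -> dict:
        d = {
            "tpr": self.episode.tpr,
            "fp_per_tp": self.episode.fp_per_tp,
            "fp_per_day": self.episode.fp_per_day,
            "precision": self.datum.precision,
            "recall": self.datum.recall,
            "tnr": self.datum.tnr,
            "f1": self.datum.f1,
            "weighted_accuracy": self.datum.weighted_accuracy,
            "window_accuracy": self.window_accuracy,
            "n_days": self.n_days,
        }
        if self.boundary is not None:
            d.update({
                "start_err_mean_min": self.boundary.start_mean_min,
                "start_err_sd_min": self.boundary.start_sd_min,
                "end_err_mean_min": self.boundary.end_mean_min,
                "end_err_sd_min": self.boundary.end_sd_min,
            })
        return d


def _check_sorted_nonoverlapping(episodes: EpisodeList, what: str) -> None:
    prev_end = -math.inf
    for e in episodes:
        if e.start_s < prev_end:
            raise ValueError(f"{what} episodes overlap at [{e.start_s}, {e.end_s})")
        prev_end = e.end_s


def match_episodes(meals: EpisodeList, detections: EpisodeList) -> EpisodeConfusion:
    """Label each meal TP/miss and each detection TP-supporting/FP.

    Overlap means strictly positive shared duration; intervals that merely
    touch at an endpoint do not overlap.
    """
    _check_sorted_nonoverlapping(meals, "ground-truth meal")
    _check_sorted_nonoverlapping(detections, "detection")
    confusion = EpisodeConfusion()
    detection_hit = [False] * len(detections)
    for meal in meals:
        overlapping = [
            (i, d) for i, d in enumerate(detections) if _overlap_s(meal, d) > 0
        ]
        if overlapping:
            for i, _ in overlapping:
                detection_hit[i] = True
            confusion.tp_meals.append((meal, overlapping[0][1], overlapping[-1][1]))
        else:
            confusion.missed_meals.append(meal)
    confusion.fp_detections = [
        d for i, d in enumerate(detections) if not detection_hit[i]
    ]
    return confusion


def episode_metrics(confusion: EpisodeConfusion, n_days: int) -> EpisodeMetrics:
    """TPR = TP/(TP+Miss); FP/TP (NaN-flagged when TP=0); FP per day."""
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    total_meals = confusion.tp + confusion.miss
    if total_meals == 0:
        raise ValueError("no ground-truth meals to evaluate")
    tpr = confusion.tp / total_meals
    fp_per_tp = confusion.fp / confusion.tp if confusion.tp else math.nan
    return EpisodeMetrics(
        tpr=tpr, fp_per_tp=fp_per_tp, fp_per_day=confusion.fp / n_days
    )


def boundary_errors(confusion: EpisodeConfusion) -> BoundaryErrors:
    """Signed start/end errors in minutes over TP meals (first/last overlap rule)."""
    if confusion.tp == 0:
        raise ValueError("boundary errors require at least one TP meal")
    starts = np.array(
        [(first.start_s - meal.start_s) / 60.0
         for meal, first, _ in confusion.tp_meals]
    )
    ends = np.array(
        [(last.end_s - meal.end_s) / 60.0
         for meal, _, last in confusion.tp_meals]
    )
    return BoundaryErrors(
        start_mean_min=float(np.mean(starts)),
        start_sd_min=float(np.std(starts)),
        end_mean_min=float(np.mean(ends)),
        end_sd_min=float(np.std(ends)),
    )


def datum_metrics(truth_mask: np.ndarray, pred_mask: np.ndarray) -> DatumMetrics:
    """Confusion-matrix ratios over equal-length boolean per-datum masks.

    Degenerate denominators yield NaN rather than raising, so sweeps over
    extreme thresholds run to completion.
    """
    truth = np.asarray(truth_mask, dtype=bool)
    pred = np.asarray(pred_mask, dtype=bool)
    if truth.shape != pred.shape:
        raise ValueError("masks must have equal length")
    if truth.size == 0:
        raise ValueError("empty masks")
    tp = int(np.sum(truth & pred))
    fp = int(np.sum(~truth & pred))
    fn = int(np.sum(truth & ~pred))
    tn = int(np.sum(~truth & ~pred))
    precision = tp / (tp + fp) if tp + fp else math.nan
    recall = tp / (tp + fn) if tp + fn else math.nan
    tnr = tn / (tn + fp) if tn + fp else math.nan
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else math.nan
    )
    return DatumMetrics(
        precision=precision,
        recall=recall,
        tnr=tnr,
        f1=f1,
        weighted_accuracy=(recall + tnr) / 2,
    )


def percent_reduction(old: float, new: float) -> float:
    """Percent reduction of a (positive) error magnitude: 100 * (1 - new/old)."""
    if old <= 0:
        raise ValueError("old value must be positive")
    return 100.0 * (1.0 - new / old)
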