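"""Hysteresis segmentation of the probability trace into eating episodes.

A two-state scan opens a segment at the first datum where p(e) rises strictly
above the start threshold TS, and closes it at the first subsequent datum where
p(e) drops strictly below the end threshold TE (TE <= TS).  Requiring a strong
probability to start suppresses false positives; allowing a weaker probability
before ending tolerates the slower eating that often ends a meal.  Detected
segments within one minute of each other are then merged, and segments shorter
than one minute are removed (strictly shorter: a 60 s segment is kept), since
real meals are longer than a minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cad_io import Episode, EpisodeList


@dataclass(frozen=True)
class DetectorConfig:
    TS: float = 0.8
    TE: float = 0.4
    merge_gap_s: float = 60.0
    min_len_s: float = 60.0

    def __post_init__(self) -> None:
        if not 0 <= self.TE <= self.TS <= 1:
            raise ValueError(
                f"thresholds must satisfy 0 <= TE <= TS <= 1; "
                f"got TS={self.TS}, TE={self.TE}"
            )
        if self.merge_gap_s < 0 or self.min_len_s < 0:
            raise ValueError("merge_gap_s and min_len_s must be non-negative")


@dataclass(frozen=True)
class DetectedSegment:
    """Closed-open datum-index interval [start_datum, end_datum)."""

    start_datum: int
    end_datum: int

    def __post_init__(self) -> None:
        if not self.start_datum < self.end_datum:
            raise ValueError("segment must have start_datum < end_datum")

    def duration_s(self, rate: float) -> float:
        return (self.end_datum - self.start_datum) / rate


def hysteresis_segment(
    trace: np.ndarray, TS: float, TE: float
) -> list[DetectedSegment]:
    """Two-threshold state machine over a per-datum probability trace.

    Opens at the first datum with ``p > TS`` (strict), closes at the first
    datum with ``p < TE`` (strict, exclusive end).  A segment still open at the
    end of the trace is closed at the last datum + 1.  Implemented with sorted
    crossing indices so cost scales with the number of detections, not with
    per-datum Python iteration; unit tests compare it against a literal
    per-datum scan.
    """
    if TE > TS:
        raise ValueError(f"TE ({TE}) must be <= TS ({TS})")
    p = np.asarray(trace, dtype=np.float64)
    if p.size and not np.all(np.isfinite(p)):
        raise ValueError("trace contains non-finite values")
    above = np.flatnonzero(p > TS)
    below = np.flatnonzero(p < TE)
    segments: list[DetectedSegment] = []
    pos = 0
    while True:
        i = np.searchsorted(above, pos)
        if i == len(above):
            break
        start = int(above[i])
        j = np.searchsorted(below, start + 1)
        end = int(below[j]) if j < len(below) else p.size
        segments.append(DetectedSegment(start, end))
        pos = end + 1
    return segments


def _check_sorted_disjoint(segments: list[DetectedSegment]) -> None:
    for a, b in zip(segments, segments[1:]):
        if b.start_datum < a.end_datum:
            raise ValueError("segments must be sorted and disjoint")


def merge_close_segments(
    segments: list[DetectedSegment], merge_gap_s: float, rate: float
) -> list[DetectedSegment]:
    """Replace any adjacent pair with gap <= merge_gap_s by its hull.

    Merging is applied left to right until no pair qualifies; the result is
    independent of iteration order.  The gap bound is inclusive ("within one
    minute" includes exactly 60 s).
    """
    _check_sorted_disjoint(segments)
    merged: list[DetectedSegment] = []
    for seg in segments:
        if merged and (seg.start_datum - merged[-1].end_datum) / rate <= merge_gap_s:
            merged[-1] = DetectedSegment(merged[-1].start_datum, seg.end_datum)
        else:
            merged.append(seg)
    return merged


def drop_short_segments(
    segments: list[DetectedSegment], min_len_s: float, rate: float
) -> list[DetectedSegment]:
    """Keep segments of duration >= min_len_s (strictly shorter are removed)."""
    _check_sorted_disjoint(segments)
    return [s for s in segments if s.duration_s(rate) >= min_len_s]


def detect_episodes(
    trace: np.ndarray,
    config: DetectorConfig | None = None,
    rate: float = 15.0,
    reference: str | None = None,
) -> EpisodeList:
    """Hysteresis -> merge -> drop, returned as an EpisodeList in seconds."""
    config = config or DetectorConfig()
    values = trace.values if hasattr(trace, "values") else trace
    segments = hysteresis_segment(values, config.TS, config.TE)
    segments = merge_close_segments(segments, config.merge_gap_s, rate)
    segments = drop_short_segments(segments, config.min_len_s, rate)
    return EpisodeList(
        episodes=[
            Episode(s.start_datum / rate, s.end_datum / rate, "detected")
            for s in segments
        ],
        reference=reference,
    )
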