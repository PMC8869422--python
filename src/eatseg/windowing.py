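"""Cutting labeled fixed-length training windows and balancing classes.

Training windows of length W minutes are cut from each preprocessed day with a
slide of 15 s and labeled eating when more than half of the window (strictly)
overlaps the union of self-reported meals.  Because everyday life is roughly
95% non-eating, the non-eating class is undersampled (uniformly, without
replacement) down to the eating count before training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cad_io import EpisodeList, MotionRecording


class BalanceError(ValueError):
    """No eating windows: a classifier cannot be trained on one class."""


@dataclass(frozen=True)
class WindowConfig:
    W_minutes: float = 6.0
    train_slide_s: float = 15.0
    overlap_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.W_minutes <= 0:
            raise ValueError("W_minutes must be positive")
        if self.train_slide_s <= 0:
            raise ValueError("train_slide_s must be positive")
        if not 0 < self.overlap_threshold < 1:
            raise ValueError("overlap_threshold must be in (0, 1)")

    def n_samples(self, sample_rate: float) -> int:
        return int(round(self.W_minutes * 60.0 * sample_rate))


@dataclass
class LabeledWindow:
    """A fixed-length slice of a preprocessed recording with a binary label."""

    source: str
    start_datum: int
    n_samples: int
    label: int
    data: np.ndarray  # (n_samples, 6) view into the recording

    def __post_init__(self) -> None:
        if self.start_datum < 0:
            raise ValueError("start_datum must be non-negative")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def _overlap_with_union(t0: float, t1: float, meals: EpisodeList) -> float:
    """Total seconds of [t0, t1) covered by the union of meal intervals.

    Ground-truth meals are validated non-overlapping, so per-interval clipped
    overlaps can simply be summed.
    """
    total = 0.0
    for e in meals:
        total += max(0.0, min(t1, e.end_s) - max(t0, e.start_s))
    return total


def label_window(
    window_interval: tuple[float, float],
    meals: EpisodeList,
    overlap_threshold: float = 0.5,
) -> int:
    """1 iff strictly more than ``overlap_threshold`` of the window overlaps meals."""
    t0, t1 = window_interval
    if not t1 > t0:
        raise ValueError("window interval must have positive duration")
    return int(_overlap_with_union(t0, t1, meals) > overlap_threshold * (t1 - t0))


def cut_training_windows(
    recording: MotionRecording,
    meals: EpisodeList,
    config: WindowConfig | None = None,
) -> list[LabeledWindow]:
    """Cut windows starting at 0, S*rate, 2*S*rate, ... and label each.

    A recording shorter than one window yields an empty list (with a warning);
    a window partially off the end of the recording is dropped.  For
    ``n >= n_samples`` the count is exactly
    ``floor((n - n_samples) / (S * rate)) + 1``.
    """
    config = config or WindowConfig()
    rate = recording.sample_rate
    n_samples = config.n_samples(rate)
    step = int(round(config.train_slide_s * rate))
    n = recording.n_samples
    if n < n_samples:
        warnings.warn(
            f"recording {recording.subject_id!r} ({n} samples) is shorter than "
            f"one {config.W_minutes} min window ({n_samples} samples)",
            stacklevel=2,
        )
        return []
    windows = []
    for start in range(0, n - n_samples + 1, step):
        t0, t1 = start / rate, (start + n_samples) / rate
        windows.append(
            LabeledWindow(
                source=recording.subject_id,
                start_datum=start,
                n_samples=n_samples,
                label=label_window((t0, t1), meals, config.overlap_threshold),
                data=recording.data[start : start + n_samples],
            )
        )
    return windows


def balance_undersample(
    windows: list[LabeledWindow], seed: int
) -> list[LabeledWindow]:
    """Keep all eating windows; sample an equal number of non-eating ones.

    Sampling is uniform without replacement and deterministic given ``seed``;
    the result is deterministically shuffled.  If fewer non-eating windows
    exist than eating ones, all are kept (with a warning).
    """
    eating = [w for w in windows if w.label == 1]
    non_eating = [w for w in windows if w.label == 0]
    if not eating:
        raise BalanceError("no eating-labeled windows; cannot balance for training")
    rng = np.random.default_rng(seed)
    if len(non_eating) <= len(eating):
        if len(non_eating) < len(eating):
            warnings.warn(
                f"only {len(non_eating)} non-eating windows for "
                f"{len(eating)} eating windows; keeping all",
                stacklevel=2,
            )
        kept = non_eating
    else:
        idx = rng.choice(len(non_eating), size=len(eating), replace=False)
        kept = [non_eating[i] for i in idx]
    combined = eating + kept
    order = rng.permutation(len(combined))
    return [combined[i] for i in order]


def windows_to_arrays(windows: list[LabeledWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into ``(n, n_samples, 6)`` float32 inputs and a label vector."""
    if not windows:
        raise ValueError("no windows")
    x = np.stack([w.data for w in windows]).astype(np.float32)
    y = np.array([w.label for w in windows], dtype=np.float32)
    return x, y
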