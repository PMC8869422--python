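"""Whole-day probability-of-eating traces.

A window of W minutes is slid through the full day (default slide: 1 datum,
i.e. 1/15 s) and the classifier's probability is assigned to the window's
*center* datum, yielding a per-datum trace p(e).  The first and last W/2 of the
day, where no full window fits, are assigned p = 0 (the conservative,
non-eating class) so every day has a total trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cad_io import EpisodeList, MotionRecording


@dataclass
class ProbabilityTrace:
    """Per-datum eating probability aligned to window centers."""

    values: np.ndarray           # one value per datum of the source recording
    valid_range: tuple[int, int]  # [first, last] datum where a full window fits
    W_minutes: float
    stride: int
    sample_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")


def sliding_probability(
    classifier,
    recording: MotionRecording,
    W_minutes: float,
    infer_stride_data: int = 1,
    method: str = "auto",
) -> ProbabilityTrace:
    """Slide a W-minute window through the day and build the p(e) trace.

    Window starts are ``0, k, 2k, ...`` for stride ``k``; each probability is
    assigned to the window's center datum and intermediate data are filled by
    linear interpolation between evaluated centers.  ``method`` selects the
    evaluation path: ``"dense"`` (whole-day dilated convolution, exact and
    fast, requires a :class:`~eatseg.model.WindowClassifier`), ``"direct"``
    (per-window calls to ``classifier.predict``, works for any object with a
    ``predict(batch)`` method), or ``"auto"``.
    """
    rate = recording.sample_rate
    n = recording.n_samples
    m = int(round(W_minutes * 60.0 * rate))
    if n < m:
        raise ValueError(
            f"recording ({n} samples) shorter than one {W_minutes} min window"
        )
    if infer_stride_data < 1:
        raise ValueError("infer_stride_data must be >= 1")

    starts = np.arange(0, n - m + 1, infer_stride_data)
    use_dense = method == "dense" or (method == "auto" and hasattr(classifier, "predict_dense"))
    if use_dense:
        all_start_probs = classifier.predict_dense(recording.data)
        probs = all_start_probs[starts]
    else:
        probs = np.concatenate([
            np.asarray(classifier.predict(
                np.stack([recording.data[s : s + m] for s in batch])
            ), dtype=np.float64)
            for batch in np.array_split(starts, max(1, len(starts) // 256))
        ])

    centers = starts + m // 2
    values = np.zeros(n)
    lo, hi = m // 2, (n - m) + m // 2
    inside = np.arange(lo, hi + 1)
    values[inside] = np.interp(inside, centers, probs)
    return ProbabilityTrace(
        values=values,
        valid_range=(lo, hi),
        W_minutes=W_minutes,
        stride=infer_stride_data,
        sample_rate=rate,
    )


def trace_to_mask(episodes: EpisodeList, n: int, rate: float) -> np.ndarray:
    """Boolean per-datum mask: true exactly where the datum's time is in an episode.

    Episodes are closed-open ``[start_s, end_s)``; datum ``i`` has time
    ``i / rate``.
    """
    mask = np.zeros(n, dtype=bool)
    for e in episodes:
        if e.start_s < 0 or e.end_s > n / rate:
            raise ValueError(
                f"episode [{e.start_s}, {e.end_s}) outside recording [0, {n / rate})"
            )
        i0 = int(np.ceil(e.start_s * rate - 1e-9))
        i1 = int(np.ceil(e.end_s * rate - 1e-9))
        mask[i0:i1] = True
    return mask
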