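"""Per-axis smoothing and normalization applied before windowing.

Each of the six sensor axes is smoothed independently with a Gaussian filter
(sigma = 10 samples by default, i.e. 2/3 s at 15 Hz) to reduce sampling noise,
then z-normalized (mean 0, population standard deviation 1) so the network
trains on comparable scales regardless of sensor units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .cad_io import CHANNEL_NAMES, MotionRecording

# Kernel truncated at 4 sigma with reflect padding at the edges; fixed
# constants so results are reproducible across runs and platforms.
KERNEL_TRUNCATE_SIGMAS = 4.0


class DegenerateSignalError(ValueError):
    """Zero-variance axis: z-normalization is undefined (dead sensor channel)."""


@dataclass(frozen=True)
class PreprocessConfig:
    sigma_samples: float = 10.0
    normalize: bool = True
    stats_scope: str = "recording"  # or "dataset"

    def __post_init__(self) -> None:
        if self.sigma_samples <= 0:
            raise ValueError("sigma_samples must be positive")
        if self.stats_scope not in ("recording", "dataset"):
            raise ValueError("stats_scope must be 'recording' or 'dataset'")


def gaussian_smooth(signal: np.ndarray, sigma_samples: float = 10.0) -> np.ndarray:
    """Convolve with a unit-area Gaussian kernel (std in samples).

    Output length equals input length; the kernel is truncated at 4 sigma and
    the signal is reflect-padded at the edges, so constants are preserved
    exactly and the output range never exceeds the input range.
    """
    if sigma_samples <= 0:
        raise ValueError("sigma_samples must be positive")
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1 or signal.size < 1:
        raise ValueError("signal must be a non-empty 1D sequence")
    return ndimage.gaussian_filter1d(
        signal, sigma_samples, mode="reflect", truncate=KERNEL_TRUNCATE_SIGMAS
    )


def znorm(
    signal: np.ndarray, stats: tuple[float, float] | None = None
) -> np.ndarray:
    """Center and scale to mean 0, population standard deviation 1.

    ``stats=(mean, sd)`` substitutes externally computed statistics (used for
    dataset-scope normalization); otherwise they come from the signal itself.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size < 2:
        raise ValueError("znorm needs at least 2 samples")
    if stats is None:
        mean, sd = float(np.mean(signal)), float(np.std(signal))
    else:
        mean, sd = stats
    if sd == 0:
        raise DegenerateSignalError("zero-variance signal cannot be z-normalized")
    return (signal - mean) / sd


def dataset_channel_stats(
    recordings: list[MotionRecording], config: PreprocessConfig | None = None
) -> np.ndarray:
    """Per-channel (mean, sd) pooled over all recordings, after smoothing.

    Returns a ``(6, 2)`` array used for ``stats_scope='dataset'``.
    """
    config = config or PreprocessConfig()
    stats = np.empty((len(CHANNEL_NAMES), 2))
    for c in range(len(CHANNEL_NAMES)):
        pooled = np.concatenate(
            [gaussian_smooth(r.data[:, c], config.sigma_samples) for r in recordings]
        )
        stats[c] = np.mean(pooled), np.std(pooled)
    return stats


def preprocess_recording(
    recording: MotionRecording,
    config: PreprocessConfig | None = None,
    channel_stats: np.ndarray | None = None,
) -> MotionRecording:
    """Smooth then (optionally) z-normalize each of the 6 channels independently.

    With ``stats_scope='dataset'`` the caller supplies ``channel_stats`` from
    :func:`dataset_channel_stats`; the default normalizes each channel with its
    own per-recording statistics.
    """
    config = config or PreprocessConfig()
    if config.stats_scope == "dataset" and config.normalize and channel_stats is None:
        raise ValueError("stats_scope='dataset' requires channel_stats")
    out = np.empty_like(recording.data)
    for c, name in enumerate(CHANNEL_NAMES):
        try:
            smoothed = gaussian_smooth(recording.data[:, c], config.sigma_samples)
            if config.normalize:
                stats = None
                if config.stats_scope == "dataset":
                    stats = (channel_stats[c, 0], channel_stats[c, 1])
                smoothed = znorm(smoothed, stats=stats)
            out[:, c] = smoothed
        except (DegenerateSignalError, ValueError) as err:
            raise type(err)(f"channel {c} ({name}): {err}") from err
    return replace(recording, data=out)
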