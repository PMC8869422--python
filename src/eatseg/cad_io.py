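"""Reading and writing the flat-binary wrist-motion format and episode tables.

A day-long recording is stored as a headerless binary file of floating point
numbers in a flat sequence, six values per sample in the channel order
``a_x, a_y, a_z, omega_x, omega_y, omega_z`` (3-axis accelerometer followed by
3-axis gyroscope), sampled at a fixed rate (15 Hz for the all-day wrist-motion
data this package targets).  Episode annotations (self-reported meals, or
detections produced by this package) travel as small CSV tables with columns
``start_s,end_s,label`` in seconds from the start of the recording.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_CHANNELS = 6
CHANNEL_NAMES = ("a_x", "a_y", "a_z", "omega_x", "omega_y", "omega_z")
DEFAULT_SAMPLE_RATE = 15.0


class MalformedFileError(ValueError):
    """Raised when a binary recording file cannot be a whole number of samples."""


@dataclass
class MotionRecording:
    """One day of 6-axis wrist-motion samples at a fixed rate.

    ``data`` has shape ``(n, 6)``; datum index ``i`` maps to time
    ``i / sample_rate`` seconds.  Units are passed through untouched
    (acceleration in g or m/s^2, angular velocity in deg/s).
    """

    subject_id: str
    data: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    start_clock: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != N_CHANNELS:
            raise ValueError(
                f"recording data must have shape (n, {N_CHANNELS}); "
                f"got {self.data.shape}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.data.size and not np.all(np.isfinite(self.data)):
            bad = int(np.flatnonzero(~np.isfinite(self.data.ravel()))[0])
            raise ValueError(
                f"non-finite value at flat position {bad} "
                f"(sample {bad // N_CHANNELS}, channel {bad % N_CHANNELS})"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        """Time of each datum in seconds from the start of the recording."""
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True, order=True)
class Episode:
    """A closed-open labeled time interval ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float
    label: str = "meal"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EpisodeList:
    """Ordered, internally non-overlapping labeled intervals for one recording."""

    episodes: list[Episode] = field(default_factory=list)
    reference: str | None = None

    def __post_init__(self) -> None:
        eps = [e if isinstance(e, Episode) else Episode(*e) for e in self.episodes]
        for i, e in enumerate(eps):
            if not e.start_s < e.end_s:
                raise ValueError(
                    f"episode {i}: start_s ({e.start_s}) must be < end_s ({e.end_s})"
                )
        eps.sort(key=lambda e: (e.start_s, e.end_s))
        for a, b in zip(eps, eps[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"overlapping episodes: [{a.start_s}, {a.end_s}) and "
                    f"[{b.start_s}, {b.end_s})"
                )
        self.episodes = eps

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self):
        return iter(self.episodes)

    def __getitem__(self, i):
        return self.episodes[i]

    def intervals(self) -> np.ndarray:
        """``(k, 2)`` array of start/end seconds."""
        if not self.episodes:
            return np.empty((0, 2))
        return np.array([(e.start_s, e.end_s) for e in self.episodes])

    def durations_s(self) -> np.ndarray:
        return np.array([e.duration_s for e in self.episodes])


def _float_dtype(float_width: int) -> np.dtype:
    if float_width == 4:
        return np.dtype("<f4")
    if float_width == 8:
        return np.dtype("<f8")
    raise ValueError(f"float_width must be 4 or 8, got {float_width}")


def read_cad_recording(
    path: str | os.PathLike,
    subject_id: str | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    float_width: int = 4,
) -> MotionRecording:
    """Read a flat-binary 6-axis recording (little-endian floats, no header).

    Value ``j`` of sample ``i`` sits at flat position ``6*i + j``.  The file
    length must be a whole number of samples (a multiple of
    ``6 * float_width`` bytes).
    """
    dtype = _float_dtype(float_width)
    size = os.path.getsize(path)
    sample_bytes = N_CHANNELS * float_width
    if size % sample_bytes:
        raise MalformedFileError(
            f"{path}: {size} bytes is not a multiple of one sample "
            f"({sample_bytes} bytes); {size % sample_bytes} trailing bytes"
        )
    flat = np.fromfile(path, dtype=dtype)
    if flat.size and not np.all(np.isfinite(flat)):
        bad = int(np.flatnonzero(~np.isfinite(flat))[0])
        raise MalformedFileError(f"{path}: non-finite value at flat index {bad}")
    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(path))[0]
    return MotionRecording(
        subject_id=subject_id,
        data=flat.reshape(-1, N_CHANNELS),
        sample_rate=sample_rate,
    )


def write_cad_recording(
    recording: MotionRecording, path: str | os.PathLike, float_width: int = 4
) -> None:
    """Write a recording as a flat little-endian binary (inverse of the reader)."""
    dtype = _float_dtype(float_width)
    recording.data.astype(dtype).ravel().tofile(path)


def read_episode_list(path: str | os.PathLike) -> EpisodeList:
    """Read a ``start_s,end_s,label`` CSV into a sorted, validated EpisodeList."""
    table = pd.read_csv(path)
    required = {"start_s", "end_s", "label"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    episodes = []
    for row_number, row in enumerate(table.itertuples(index=False), start=2):
        if not row.start_s < row.end_s:
            raise ValueError(
                f"{path} row {row_number}: start_s ({row.start_s}) must be "
                f"< end_s ({row.end_s})"
            )
        episodes.append(Episode(float(row.start_s), float(row.end_s), str(row.label)))
    ref = os.path.splitext(os.path.basename(path))[0]
    return EpisodeList(episodes=episodes, reference=ref)


def write_episode_list(episodes: EpisodeList, path: str | os.PathLike) -> None:
    table = pd.DataFrame(
        [(e.start_s, e.end_s, e.label) for e in episodes],
        columns=["start_s", "end_s", "label"],
    )
    table.to_csv(path, index=False)


def read_probability_trace(path: str | os.PathLike) -> np.ndarray:
    """Read a per-datum probability trace (single-column CSV or flat float32)."""
    if str(path).endswith(".csv"):
        return pd.read_csv(path)["p_eat"].to_numpy(dtype=np.float64)
    return np.fromfile(path, dtype="<f4").astype(np.float64)


def write_probability_trace(values: np.ndarray, path: str | os.PathLike) -> None:
    values = np.asarray(values)
    if str(path).endswith(".csv"):
        pd.DataFrame({"p_eat": values}).to_csv(path, index=False)
    else:
        values.astype("<f4").tofile(path)
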