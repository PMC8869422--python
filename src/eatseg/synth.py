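"""Synthetic day-long 6-axis wrist-motion recordings with meal annotations.

The generator emulates the statistical structure the detector relies on, not
arm biomechanics.  A day (default 13 h at 15 Hz) is background activity —
rest, walking (cyclic ~1.5-2 Hz oscillation on the accelerometer axes), and
occasional isolated bite-like confounder gestures — into which 1-6 meals are
placed.  A meal is a sequence of bite gestures (3-5 s of large wrist rotation
with smaller linear motion) separated by rest and food-preparation gestures,
reflecting that a sizable fraction of a real meal is spent not ingesting.

Meal durations are log-normal with median 11 min and mean 14 min (right-skewed,
sd ~= 11 min), truncated at 1 min; with ~3 meals per 13 h day this puts roughly
5% of all samples inside meals, matching the eating/non-eating imbalance of
day-long free-living recordings.

All randomness flows through one seeded generator per day; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cad_io import Episode, EpisodeList, MotionRecording

GRAVITY = np.array([0.0, 0.0, 1.0])  # baseline accelerometer reading, in g


class PlacementError(RuntimeError):
    """Requested meals cannot fit in the day without overlapping."""


@dataclass(frozen=True)
class SynthParams:
    day_length_h: float = 13.0
    sample_rate: float = 15.0
    meals_per_day_mean: float = 3.0
    meals_per_day_min: int = 1
    meals_per_day_max: int = 6
    meal_duration_median_min: float = 11.0
    meal_duration_mean_min: float = 14.0
    meal_duration_floor_min: float = 1.0
    bite_interval_s: float = 20.0
    bite_duration_s: tuple[float, float] = (3.0, 5.0)
    prep_fraction: float = 0.18
    walk_fraction: float = 0.25  # share of background time spent walking
    confounders_per_h: float = 2.0
    noise_sd: float = 0.05
    edge_margin_s: float = 300.0
    meal_gap_s: float = 180.0

    def __post_init__(self) -> None:
        if self.meal_duration_mean_min < self.meal_duration_median_min:
            raise ValueError("mean meal duration must be >= median (right skew)")
        if not 0 <= self.prep_fraction < 1 or not 0 <= self.walk_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def lognormal_mu(self) -> float:
        return math.log(self.meal_duration_median_min)

    @property
    def lognormal_sigma(self) -> float:
        # exp(mu + s^2/2) = mean with exp(mu) = median fixes s exactly
        return math.sqrt(2.0 * math.log(
            self.meal_duration_mean_min / self.meal_duration_median_min
        ))


# --------------------------------------------------------------- gesture kernels

def _smooth_noise(n: int, rng: np.random.Generator, sigma: float = 8.0) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    return ndimage.gaussian_filter1d(rng.standard_normal(n), sigma, mode="reflect")


def rest_kernel(duration_s: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Low-amplitude drift: the wrist is nearly still."""
    n = max(1, int(round(duration_s * rate)))
    out = np.zeros((n, 6))
    for c in range(3):
        out[:, c] = GRAVITY[c] + 0.03 * _smooth_noise(n, rng, sigma=20)
    for c in range(3, 6):
        out[:, c] = 1.5 * _smooth_noise(n, rng, sigma=20)
    return out


def walk_kernel(duration_s: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Cyclic arm swing: dominant 1.5-2 Hz oscillation on the linear channels."""
    n = max(1, int(round(duration_s * rate)))
    t = np.arange(n) / rate
    freq = rng.uniform(1.5, 2.0)
    out = np.zeros((n, 6))
    for c in range(3):
        amp = rng.uniform(0.25, 0.5)
        out[:, c] = GRAVITY[c] + amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    for c in range(3, 6):
        amp = rng.uniform(5.0, 12.0)
        out[:, c] = amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return out


def bite_kernel(duration_s: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One hand-to-mouth gesture: large wrist rotation, small linear motion.

    The rotational channels carry a smooth raise-then-lower velocity profile
    (RMS far above the linear channels', the signature used for recognition).
    """
    n = max(2, int(round(duration_s * rate)))
    t = np.linspace(0, 1, n)
    profile = np.sin(2 * np.pi * t)  # rotate up, then back down
    out = np.zeros((n, 6))
    amp_rot = rng.uniform(60.0, 120.0)
    out[:, 3] = amp_rot * profile
    out[:, 4] = rng.uniform(20.0, 50.0) * np.sin(np.pi * t)
    out[:, 5] = rng.uniform(10.0, 30.0) * profile
    for c in range(3):
        out[:, c] = GRAVITY[c] + rng.uniform(0.05, 0.15) * np.sin(np.pi * t)
    return out


def prep_kernel(duration_s: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Food manipulation (cutting, stirring): irregular moderate motion."""
    n = max(1, int(round(duration_s * rate)))
    out = np.zeros((n, 6))
    for c in range(3):
        out[:, c] = GRAVITY[c] + 0.15 * _smooth_noise(n, rng, sigma=5)
    for c in range(3, 6):
        out[:, c] = 25.0 * _smooth_noise(n, rng, sigma=5)
    return out


def confounder_kernel(duration_s: float, rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    """An isolated bite-like gesture outside any meal (e.g. touching the face)."""
    return bite_kernel(duration_s, rate, rng)


GESTURE_KERNELS = {
    "rest": rest_kernel,
    "walk": walk_kernel,
    "bite": bite_kernel,
    "prep": prep_kernel,
    "confounder": confounder_kernel,
}


# ------------------------------------------------------------------- assembly

def _meal_signal(duration_s: float, rate: float,
                 params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """A meal: bites separated by rest/prep, trimmed to the exact duration."""
    n_target = int(round(duration_s * rate))
    lo, hi = params.bite_duration_s
    mean_bite = (lo + hi) / 2
    gap_mean = max(2.0, params.bite_interval_s - mean_bite)
    p_prep = min(1.0, params.prep_fraction * params.bite_interval_s / gap_mean)
    pieces = []
    n_done = 0
    while n_done < n_target:
        bite = bite_kernel(rng.uniform(lo, hi), rate, rng)
        pieces.append(bite)
        n_done += bite.shape[0]
        gap_s = float(np.clip(rng.exponential(gap_mean), 2.0, 60.0))
        kind = "prep" if rng.random() < p_prep else "rest"
        gap = GESTURE_KERNELS[kind](gap_s, rate, rng)
        pieces.append(gap)
        n_done += gap.shape[0]
    return np.concatenate(pieces)[:n_target]


def _background_signal(n_samples: int, rate: float,
                       params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    pieces = []
    n_done = 0
    while n_done < n_samples:
        if rng.random() < params.walk_fraction:
            seg = walk_kernel(rng.uniform(30, 300), rate, rng)
        else:
            seg = rest_kernel(rng.uniform(60, 600), rate, rng)
        pieces.append(seg)
        n_done += seg.shape[0]
    out = np.concatenate(pieces)[:n_samples]
    # sprinkle isolated confounder gestures over the background
    hours = n_samples / rate / 3600.0
    for _ in range(rng.poisson(params.confounders_per_h * hours)):
        snippet = confounder_kernel(rng.uniform(*params.bite_duration_s), rate, rng)
        k = snippet.shape[0]
        if k < n_samples:
            start = int(rng.integers(0, n_samples - k))
            out[start : start + k] = snippet
    return out


def _draw_meal_plan(params: SynthParams, rng: np.random.Generator,
                    day_s: float) -> list[tuple[float, float]]:
    """Meal (start_s, end_s) intervals: truncated-Poisson count, log-normal durations."""
    lo, hi = params.meals_per_day_min, params.meals_per_day_max
    count = int(np.clip(rng.poisson(params.meals_per_day_mean), lo, hi))
    if count == 0:
        return []
    durations = []
    for _ in range(count):
        d = float(rng.lognormal(params.lognormal_mu, params.lognormal_sigma))
        while d < params.meal_duration_floor_min:
            d = float(rng.lognormal(params.lognormal_mu, params.lognormal_sigma))
        durations.append(d * 60.0)
    usable = day_s - 2 * params.edge_margin_s
    if sum(durations) + (count - 1) * params.meal_gap_s > usable:
        raise PlacementError(
            f"{count} meals totalling {sum(durations) / 60:.0f} min cannot fit "
            f"in a {day_s / 3600:.1f} h day"
        )
    for _attempt in range(1000):
        starts = np.sort(rng.uniform(
            params.edge_margin_s,
            day_s - params.edge_margin_s - max(durations),
            size=count,
        ))
        intervals = sorted(
            (s, s + d) for s, d in zip(starts, rng.permutation(durations))
        )
        ok = all(
            b0 - a1 >= params.meal_gap_s
            for (_, a1), (b0, _) in zip(intervals, intervals[1:])
        ) and intervals[-1][1] <= day_s - params.edge_margin_s
        if ok:
            return intervals
    raise PlacementError("could not place meals without overlap after 1000 attempts")


def generate_day(
    params: SynthParams | None = None,
    seed: int = 0,
    subject_id: str = "synth",
) -> tuple[MotionRecording, EpisodeList]:
    """One annotated synthetic day; bit-identical for identical seeds.

    Annotations are the exact hulls of the generated meal gesture sequences.
    """
    params = params or SynthParams()
    rng = np.random.default_rng(seed)
    rate = params.sample_rate
    n = int(round(params.day_length_h * 3600 * rate))
    day_s = n / rate

    meal_plan = _draw_meal_plan(params, rng, day_s)
    data = _background_signal(n, rate, params, rng)
    episodes = []
    for start_s, end_s in meal_plan:
        i0 = int(round(start_s * rate))
        i1 = int(round(end_s * rate))
        data[i0:i1] = _meal_signal((i1 - i0) / rate, rate, params, rng)
        episodes.append(Episode(i0 / rate, i1 / rate, "meal"))

    noise = rng.standard_normal((n, 6))
    data[:, :3] += params.noise_sd * noise[:, :3]
    data[:, 3:] += 20.0 * params.noise_sd * noise[:, 3:]

    recording = MotionRecording(subject_id=subject_id, data=data, sample_rate=rate)
    return recording, EpisodeList(episodes=episodes, reference=subject_id)


def generate_dataset(
    n_days: int,
    params: SynthParams | None = None,
    seed: int = 0,
) -> list[tuple[MotionRecording, EpisodeList]]:
    """``n_days`` independent synthetic days, one subject per day.

    Per-day seeds are spawned deterministically from the master seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    params = params or SynthParams()
    children = np.random.SeedSequence(seed).spawn(n_days)
    dataset = []
    for i, child in enumerate(children):
        day_seed = int(child.generate_state(1)[0] % (2**31))
        dataset.append(
            generate_day(params, seed=day_seed, subject_id=f"S{i:04d}")
        )
    return dataset
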