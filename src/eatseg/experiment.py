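"""Subject-wise k-fold cross-testing and one-at-a-time hyperparameter sweeps.

Folds are assigned at the subject level so no individual contributes data to
both training and testing (free-living wrist motion is strongly
subject-specific; splitting by day would leak).  Each fold is held out once:
the model trains on the other folds' balanced windows, then whole-day traces
are inferred for the held-out days, segmented with the hysteresis detector,
and scored at the episode, boundary, datum and window level.

Threshold sweeps (TS, TE) reuse the trained model and cached traces per
(fold, W): thresholding a trace is cheap, so only sweeps over the window
length W retrain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cad_io import EpisodeList, MotionRecording
from .detector import DetectorConfig, detect_episodes
from .evaluation import (
    EpisodeConfusion,
    MetricsReport,
    boundary_errors,
    datum_metrics,
    episode_metrics,
    match_episodes,
)
from .inference import sliding_probability, trace_to_mask
from .model import ModelConfig, TrainConfig, WindowClassifier, build_model, train_model
from .windowing import WindowConfig, balance_undersample, cut_training_windows, label_window

logger = logging.getLogger(__name__)

Dataset = list[tuple[MotionRecording, EpisodeList]]


@dataclass(frozen=True)
class FoldSplit:
    """Assignment of every subject to exactly one of k folds."""

    k: int
    assignment: dict[str, int]
    seed: int

    def subjects_in(self, fold: int) -> set[str]:
        return {s for s, f in self.assignment.items() if f == fold}

    def fold_sizes(self) -> list[int]:
        return [len(self.subjects_in(f)) for f in range(self.k)]


def split_subjects(subject_ids: list[str], k: int = 5, seed: int = 0) -> FoldSplit:
    """Deterministic shuffled round-robin assignment; fold sizes differ by <= 1.

    Repeated ids are collapsed first, so all recordings of a subject share a
    fold.
    """
    unique = list(dict.fromkeys(subject_ids))
    if len(unique) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    assignment = {unique[j]: i % k for i, j in enumerate(order)}
    return FoldSplit(k=k, assignment=assignment, seed=seed)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one fold run needs besides the data and the split."""

    window: WindowConfig = field(default_factory=WindowConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    infer_stride: int = 1


def _evaluate_days(
    classifier: WindowClassifier,
    test_days: Dataset,
    config: ExperimentConfig,
    trace_cache: dict[str, "object"] | None = None,
) -> tuple[EpisodeConfusion, np.ndarray, np.ndarray]:
    """Detect episodes on each held-out day; pooled confusion and datum masks.

    ``trace_cache`` (subject_id -> ProbabilityTrace) lets threshold sweeps skip
    re-inferring the probability traces, which only depend on (model, W).
    """
    confusion = EpisodeConfusion()
    truth_masks, pred_masks = [], []
    for recording, meals in test_days:
        if trace_cache is not None and recording.subject_id in trace_cache:
            trace = trace_cache[recording.subject_id]
        else:
            trace = sliding_probability(
                classifier, recording, config.window.W_minutes,
                infer_stride_data=config.infer_stride,
            )
            if trace_cache is not None:
                trace_cache[recording.subject_id] = trace
        detections = detect_episodes(
            trace, config.detector, rate=recording.sample_rate,
            reference=recording.subject_id,
        )
        confusion = confusion.merge(match_episodes(meals, detections))
        n = recording.n_samples
        truth_masks.append(trace_to_mask(meals, n, recording.sample_rate))
        pred_masks.append(trace_to_mask(detections, n, recording.sample_rate))
    return confusion, np.concatenate(truth_masks), np.concatenate(pred_masks)


def _test_window_accuracy(
    classifier: WindowClassifier, test_days: Dataset, config: ExperimentConfig
) -> float:
    """Class-balanced accuracy over the held-out days' labeled windows.

    Windows are cut at the training slide and scored on all eating windows
    plus an equal-size deterministic sample of non-eating windows, so chance
    level is 0.5 regardless of the eating/non-eating imbalance.  Uses the
    dense whole-day evaluation indexed at window starts, equivalent to
    predicting each overlapping window separately.
    """
    probs_parts, label_parts = [], []
    for recording, meals in test_days:
        rate = recording.sample_rate
        m = config.window.n_samples(rate)
        step = int(round(config.window.train_slide_s * rate))
        if recording.n_samples < m:
            continue
        starts = np.arange(0, recording.n_samples - m + 1, step)
        probs_parts.append(classifier.predict_dense(recording.data)[starts])
        label_parts.append(np.array([
            label_window((s / rate, (s + m) / rate), meals,
                         config.window.overlap_threshold)
            for s in starts
        ]))
    if not probs_parts:
        raise ValueError("no held-out windows to score")
    probs = np.concatenate(probs_parts)
    labels = np.concatenate(label_parts)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("held-out windows contain a single class")
    rng = np.random.default_rng(0)
    if len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    idx = np.concatenate([pos, neg])
    return float(np.mean((probs[idx] >= 0.5) == (labels[idx] == 1)))


def train_fold_model(
    dataset: Dataset,
    split: FoldSplit,
    test_fold: int,
    config: ExperimentConfig,
    seed: int = 0,
) -> WindowClassifier:
    """Train the window classifier on all folds except ``test_fold``.

    One integer seed drives undersampling, weight initialization and batch
    shuffling for the fold.
    """
    test_subjects = split.subjects_in(test_fold)
    train_days = [(r, m) for r, m in dataset if r.subject_id not in test_subjects]
    # leakage guard: train and test subjects must be disjoint
    assert not {r.subject_id for r, _ in train_days} & test_subjects

    windows = []
    for recording, meals in train_days:
        windows.extend(cut_training_windows(recording, meals, config.window))
    balanced = balance_undersample(windows, seed=seed)
    logger.info(
        "fold %d: %d balanced training windows (%d eating)",
        test_fold, len(balanced), sum(w.label for w in balanced),
    )
    rate = train_days[0][0].sample_rate
    classifier = build_model(
        config.model, n_samples=config.window.n_samples(rate), seed=seed
    )
    train_model(classifier, balanced, replace(config.train, seed=seed))
    return classifier


def run_fold(
    dataset: Dataset,
    split: FoldSplit,
    test_fold: int,
    config: ExperimentConfig | None = None,
    seed: int = 0,
    classifier: WindowClassifier | None = None,
    trace_cache: dict[str, "object"] | None = None,
    window_acc: float | None = None,
) -> MetricsReport:
    """Train on k-1 folds, detect and score on the held-out fold.

    A pre-trained ``classifier`` (and a per-fold ``trace_cache``) may be
    supplied, as the threshold sweeps do; otherwise the model is trained from
    scratch.
    """
    config = config or ExperimentConfig()
    test_subjects = split.subjects_in(test_fold)
    test_days = [(r, m) for r, m in dataset if r.subject_id in test_subjects]
    if not test_days:
        raise ValueError(f"fold {test_fold} holds no recordings")
    if classifier is None:
        classifier = train_fold_model(dataset, split, test_fold, config, seed=seed)

    confusion, truth, pred = _evaluate_days(
        classifier, test_days, config, trace_cache=trace_cache
    )
    if window_acc is None:
        window_acc = _test_window_accuracy(classifier, test_days, config)
    report = MetricsReport(
        episode=episode_metrics(confusion, n_days=len(test_days)),
        boundary=boundary_errors(confusion) if confusion.tp else None,
        datum=datum_metrics(truth, pred),
        window_accuracy=window_acc,
        n_days=len(test_days),
    )
    logger.info("fold %d: %s", test_fold, report.to_dict())
    return report


def aggregate_reports(reports: list[MetricsReport]) -> pd.DataFrame:
    """Per-fold table plus mean/min/max rows (NaN-aware)."""
    table = pd.DataFrame([r.to_dict() for r in reports])
    summary = pd.DataFrame(
        [table.mean(numeric_only=True), table.min(numeric_only=True),
         table.max(numeric_only=True)],
        index=["mean", "min", "max"],
    )
    return pd.concat([table, summary])


def run_crossval(
    dataset: Dataset,
    k: int = 5,
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> tuple[list[MetricsReport], pd.DataFrame]:
    """Hold each fold out once; returns per-fold reports and the aggregate table."""
    config = config or ExperimentConfig()
    split = split_subjects([r.subject_id for r, _ in dataset], k=k, seed=seed)
    reports = [
        run_fold(dataset, split, fold, config, seed=seed + fold)
        for fold in range(k)
    ]
    return reports, aggregate_reports(reports)


@dataclass
class SweepResult:
    axis: str
    values: list[float]
    reports: dict[float, list[MetricsReport]]  # value -> per-fold reports

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.values:
            for fold, rep in enumerate(self.reports[v]):
                rows.append({self.axis: v, "fold": fold, **rep.to_dict()})
        return pd.DataFrame(rows)

    def mean_frame(self) -> pd.DataFrame:
        frame = self.to_frame().drop(columns="fold")
        return frame.groupby(self.axis, as_index=False).mean()


def sweep(
    axis: str,
    values: list[float],
    dataset: Dataset,
    k: int = 5,
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> SweepResult:
    """One-at-a-time sweep over W (retrains) or TS/TE (reuses trained models).

    For threshold axes the per-fold model is trained once at the fixed W and
    every value re-runs only detection + scoring, so sweep results are
    reproducible and independent of the order of ``values``.
    """
    if axis not in ("W", "TS", "TE"):
        raise ValueError("axis must be one of 'W', 'TS', 'TE'")
    if not values:
        raise ValueError("empty value list")
    config = config or ExperimentConfig()
    split = split_subjects([r.subject_id for r, _ in dataset], k=k, seed=seed)
    result = SweepResult(axis=axis, values=list(values), reports={})

    if axis == "W":
        for v in values:
            cfg = replace(config, window=replace(config.window, W_minutes=v))
            result.reports[v] = [
                run_fold(dataset, split, fold, cfg, seed=seed + fold)
                for fold in range(k)
            ]
        return result

    # thresholds: train each fold once, cache its traces, re-detect per value
    models = {
        fold: train_fold_model(dataset, split, fold, config, seed=seed + fold)
        for fold in range(k)
    }
    caches: dict[int, dict] = {fold: {} for fold in range(k)}
    accs = {}
    for fold in range(k):
        days = [(r, m) for r, m in dataset
                if r.subject_id in split.subjects_in(fold)]
        accs[fold] = _test_window_accuracy(models[fold], days, config)
    for v in values:
        if axis == "TS":
            det = replace(config.detector, TS=v)
        else:
            det = replace(config.detector, TE=v)
        cfg = replace(config, detector=det)
        result.reports[v] = [
            run_fold(dataset, split, fold, cfg, seed=seed + fold,
                     classifier=models[fold], trace_cache=caches[fold],
                     window_acc=accs[fold])
            for fold in range(k)
        ]
    return result
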