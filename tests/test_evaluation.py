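"""Episode matching, boundary errors, and per-datum metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eatseg.cad_io import Episode, EpisodeList
from eatseg.evaluation import (
    boundary_errors,
    datum_metrics,
    episode_metrics,
    match_episodes,
    percent_reduction,
)


def el(*intervals, label="meal"):
    return EpisodeList(episodes=[Episode(a, b, label) for a, b in intervals])


def overlap_oracle(a, b):
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


class TestMatchEpisodes:
    def test_one_meal_one_overlapping_detection(self):
        c = match_episodes(el((100, 700)), el((150, 650)))
        assert (c.tp, c.fp, c.miss) == (1, 0, 0)

    def test_meal_split_across_detections_single_tp(self):
        c = match_episodes(el((100, 700)), el((120, 300), (400, 800)))
        assert (c.tp, c.fp, c.miss) == (1, 0, 0)

    def test_two_meals_under_one_detection(self):
        """Each meal is evaluated for its own TP; the detection is no FP."""
        c = match_episodes(el((100, 400), (500, 900)), el((50, 950)))
        assert (c.tp, c.fp, c.miss) == (2, 0, 0)

    def test_disjoint_detection_is_fp_and_meal_missed(self):
        c = match_episodes(el((100, 400)), el((1000, 1300)))
        assert (c.tp, c.fp, c.miss) == (0, 1, 1)

    def test_touching_endpoints_do_not_overlap(self):
        c = match_episodes(el((100, 400)), el((400, 700)))
        assert (c.tp, c.fp, c.miss) == (0, 1, 1)

    def test_overlapping_ground_truth_rejected(self):
        meals = EpisodeList(episodes=[Episode(0, 100)])
        meals.episodes.append(Episode(50, 150))  # bypass constructor check
        with pytest.raises(ValueError):
            match_episodes(meals, el())

    def test_tpr_invariant_under_time_shift(self):
        meals, dets = el((100, 700), (2000, 2500)), el((600, 900), (4000, 4100))
        c0 = match_episodes(meals, dets)
        shift = 12345.0
        meals2 = el(*[(e.start_s + shift, e.end_s + shift) for e in meals])
        dets2 = el(*[(e.start_s + shift, e.end_s + shift) for e in dets])
        c1 = match_episodes(meals2, dets2)
        assert (c0.tp, c0.fp, c0.miss) == (c1.tp, c1.fp, c1.miss)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=300, deadline=None)
    def test_random_scenarios_vs_interval_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_meals = int(rng.integers(1, 6))
        n_dets = int(rng.integers(0, 8))
        meal_starts = np.cumsum(rng.uniform(200, 800, size=n_meals))
        meals = el(*[(s, s + rng.uniform(60, 150)) for s in meal_starts])
        det_starts = np.cumsum(rng.uniform(150, 900, size=n_dets))
        dets = el(*[(s, s + rng.uniform(30, 140)) for s in det_starts])

        c = match_episodes(meals, dets)
        # every meal classified exactly once
        assert c.tp + c.miss == len(meals)
        # detections partition into overlapping-some-meal and FP
        m_iv, d_iv = meals.intervals(), dets.intervals()
        fp_expected = sum(
            1 for d in d_iv if all(overlap_oracle(d, m) == 0 for m in m_iv)
        )
        tp_expected = sum(
            1 for m in m_iv if any(overlap_oracle(m, d) > 0 for d in d_iv)
        )
        assert c.fp == fp_expected
        assert c.tp == tp_expected


class TestEpisodeMetrics:
    def test_paper_scale_counts_round_to_printed_values(self):
        """944 TPs, 119 misses, 1650 FPs over 354 days."""
        from eatseg.evaluation import EpisodeConfusion

        c = EpisodeConfusion(
            tp_meals=[(None, None, None)] * 944,
            missed_meals=[None] * 119,
            fp_detections=[None] * 1650,
        )
        m = episode_metrics(c, n_days=354)
        assert round(m.tpr, 2) == 0.89
        assert round(m.fp_per_tp, 1) == 1.7
        assert round(m.fp_per_day, 1) == 4.7

    def test_zero_tp_flags_undefined_ratio(self):
        c = match_episodes(el((0, 100)), el((500, 700)))
        m = episode_metrics(c, n_days=1)
        assert m.tpr == 0.0
        assert math.isnan(m.fp_per_tp) and not m.fp_per_tp_defined

    def test_perfect_detector(self):
        c = match_episodes(el((0, 100), (200, 300)), el((0, 100), (200, 300)))
        m = episode_metrics(c, n_days=2)
        assert (m.tpr, m.fp_per_tp, m.fp_per_day) == (1.0, 0.0, 0.0)

    def test_nonpositive_days_rejected(self):
        c = match_episodes(el((0, 100)), el((0, 100)))
        with pytest.raises(ValueError):
            episode_metrics(c, n_days=0)


class TestBoundaryErrors:
    def test_exact_detection_zero_errors(self):
        c = match_episodes(el((600, 1200)), el((600, 1200)))
        b = boundary_errors(c)
        assert (b.start_mean_min, b.end_mean_min) == (0.0, 0.0)

    def test_signed_convention(self):
        """Detection starting early gives a negative start error."""
        c = match_episodes(el((600, 1200)), el((510, 1254)))
        b = boundary_errors(c)
        assert b.start_mean_min == pytest.approx(-1.5)
        assert b.end_mean_min == pytest.approx(0.9)

    def test_first_and_last_overlapping_detection_used(self):
        c = match_episodes(el((600, 1200)), el((580, 700), (800, 1300)))
        b = boundary_errors(c)
        assert b.start_mean_min == pytest.approx((580 - 600) / 60)
        assert b.end_mean_min == pytest.approx((1300 - 1200) / 60)

    def test_zero_tp_raises(self):
        c = match_episodes(el((0, 100)), el((500, 600)))
        with pytest.raises(ValueError):
            boundary_errors(c)


class TestDatumMetrics:
    def test_perfect_prediction(self):
        truth = np.array([True, False, True, False])
        m = datum_metrics(truth, truth)
        assert (m.precision, m.recall, m.tnr, m.f1, m.weighted_accuracy) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_hand_confusion_matrix(self):
        truth = np.zeros(10, dtype=bool)
        truth[:4] = True
        pred = np.zeros(10, dtype=bool)
        pred[1:6] = True  # 3 of 4 positives hit, 2 false alarms
        m = datum_metrics(truth, pred)
        assert m.precision == pytest.approx(0.6)
        assert m.recall == pytest.approx(0.75)
        assert m.tnr == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 * 0.6 * 0.75 / 1.35)

    def test_balanced_accuracy_matches_published_row(self):
        """recall 0.69 and TNR 0.93 give a weighted accuracy of 0.81."""
        n = 10000
        pos = 2000
        truth = np.arange(n) < pos
        pred = np.zeros(n, dtype=bool)
        pred[: int(0.69 * pos)] = True                     # recall 0.69
        pred[pos : pos + int(0.07 * (n - pos))] = True     # TNR 0.93
        m = datum_metrics(truth, pred)
        assert m.recall == pytest.approx(0.69, abs=1e-3)
        assert m.tnr == pytest.approx(0.93, abs=1e-3)
        assert m.weighted_accuracy == pytest.approx(0.81, abs=1e-3)

    def test_degenerate_denominators_are_nan(self):
        m = datum_metrics(np.zeros(5, bool), np.zeros(5, bool))
        assert math.isnan(m.precision) and math.isnan(m.recall)

    def test_empty_masks_rejected(self):
        with pytest.raises(ValueError):
            datum_metrics(np.array([], bool), np.array([], bool))


class TestPercentReduction:
    def test_boundary_error_reduction(self):
        assert round(percent_reduction(7.3, 0.9)) == 88
        assert round(percent_reduction(4.5, 1.5)) == 67
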