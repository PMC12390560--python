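"""Evaluation harness: scoring oracles, ROC properties, power and design."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tenssim.detector import DetectionEvent
from tenssim.emg import generate_benchmark
from tenssim.evaluate import (
    MATCH_TOLERANCE,
    PowerModel,
    StudyDesign,
    battery_runtime,
    implied_idle_current,
    normalize_to_baseline,
    rmssd,
    roc_auc,
    sample_size_paired,
    score_detections,
)


def _events(times):
    return [DetectionEvent(time=t, envelope_value=1.0) for t in times]


def _truth(onsets, offsets, duration):
    return (np.asarray(onsets), np.asarray(offsets), duration)


class TestScoreDetections:
    def test_perfect_detection(self):
        truth = _truth([1.0, 3.0, 5.0], [1.5, 3.5, 5.5], 7.0)
        sens, spec = score_detections([_events([1.0, 3.0, 5.0])], [truth])
        assert sens == 1.0
        assert spec == 1.0

    def test_no_detections(self):
        truth = _truth([1.0, 3.0], [1.5, 3.5], 5.0)
        sens, spec = score_detections([_events([])], [truth])
        assert sens == 0.0
        assert spec == 1.0

    def test_sensitivity_plus_miss_rate_is_one(self):
        truth = _truth([1.0, 3.0, 5.0, 7.0], [1.5, 3.5, 5.5, 7.5], 9.0)
        sens, _ = score_detections([_events([1.02, 6.0])], [truth])
        miss = 3 / 4  # 3 of 4 onsets unmatched
        assert sens + miss == 1.0

    def test_empty_truth_flagged(self):
        with pytest.raises(ValueError):
            score_detections([_events([1.0])], [_truth([], [], 5.0)])

    def test_agrees_with_exhaustive_matching_oracle(self):
        """Greedy nearest-first matching must agree with a brute-force
        oracle that enumerates candidate pairs on small sessions."""

        def oracle_counts(det, ons, tol):
            # exhaustive greedy: repeatedly take the globally closest pair
            det, ons = list(det), list(ons)
            tp = 0
            while det and ons:
                best = None
                for d in det:
                    for o in ons:
                        if abs(d - o) <= tol and (best is None or abs(d - o) < best[0]):
                            best = (abs(d - o), d, o)
                if best is None:
                    break
                det.remove(best[1])
                ons.remove(best[2])
                tp += 1
            return tp

        rng = np.random.default_rng(42)
        for _ in range(3):
            n_onsets = rng.integers(2, 6)
            onsets = np.sort(rng.uniform(1, 19, size=n_onsets))
            while np.any(np.diff(onsets) < 1.0):
                onsets = np.sort(rng.uniform(1, 19, size=n_onsets))
            offsets = onsets + 0.4
            det_times = np.sort(
                np.concatenate([onsets + rng.normal(0, 0.08, n_onsets), rng.uniform(0, 20, 2)])
            )
            sens, _ = score_detections([_events(det_times)], [_truth(onsets, offsets, 20.0)])
            tp_oracle = oracle_counts(det_times, onsets, MATCH_TOLERANCE)
            assert sens == tp_oracle / n_onsets


class TestRocAuc:
    def test_separable_benchmark_auc_one(self):
        recs = generate_benchmark(4, 1, "clean", seed=2)
        score = roc_auc(recs)
        assert score.auc == pytest.approx(1.0, abs=0.005)
        assert score.sensitivity >= 0.99
        assert score.specificity >= 0.99

    def test_coin_flip_detector_auc_half(self):
        """A detector replaced by a per-decision coin flip (fire with
        probability p at every onset and every baseline window) must trace
        the diagonal: AUC ~ 0.5 over seeded repetitions."""
        from tenssim.evaluate import _baseline_windows

        rng = np.random.default_rng(31)
        recs = generate_benchmark(2, 1, "paper-bench", seed=8)
        truths = [_truth(r.onsets, r.offsets, r.duration) for r in recs]
        windows = [
            _baseline_windows(r.onsets, r.offsets, r.duration, MATCH_TOLERANCE) for r in recs
        ]
        aucs = []
        for _ in range(20):
            fprs, tprs = [], []
            for p in np.linspace(0.05, 0.95, 12):
                evs = []
                for r, wins in zip(recs, windows):
                    times = [t for t in r.onsets if rng.random() < p]
                    times += [0.5 * (lo + hi) for lo, hi in wins if rng.random() < p]
                    evs.append(_events(sorted(times)))
                s, sp = score_detections(evs, truths)
                fprs.append(1 - sp)
                tprs.append(s)
            order = np.argsort(fprs)
            fx = np.concatenate(([0], np.asarray(fprs)[order], [1]))
            ty = np.concatenate(([0], np.asarray(tprs)[order], [1]))
            aucs.append(np.trapezoid(ty, fx))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_auc_invariant_to_monotone_envelope_rescale(self):
        """Scaling all recordings by a > 0 rescales the envelope and the
        default sweep with it: the ROC must not change."""
        recs = generate_benchmark(2, 1, "paper-bench", seed=3)
        base = roc_auc(recs)
        for rec in recs:
            rec.samples *= 3.0
        scaled = roc_auc(recs)
        # exact invariance is broken only by the fixed ADC quantization step
        assert scaled.auc == pytest.approx(base.auc, abs=0.005)
        assert scaled.optimal_threshold == pytest.approx(3 * base.optimal_threshold, rel=0.05)


class TestBattery:
    def test_worst_case_runtime_4p2_hours(self):
        assert battery_runtime(PowerModel()) == pytest.approx(400 / 95)
        assert round(battery_runtime(PowerModel()), 1) == 4.2

    def test_intermittent_duty_exceeds_8_hours(self):
        model = PowerModel(active_current=95.0, idle_current=11.6667, duty=0.4)
        hours = battery_runtime(model)
        assert hours == pytest.approx(400 / 45, rel=1e-3)
        assert hours > 8

    def test_zero_current_rejected(self):
        with pytest.raises(ValueError):
            battery_runtime(PowerModel(active_current=0.0, idle_current=0.0, duty=0.0))

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(min_value=0.5, max_value=4.0))
    def test_runtime_homogeneous_in_capacity(self, scale):
        base = PowerModel()
        scaled = PowerModel(battery_capacity=400.0 * scale)
        assert battery_runtime(scaled) == pytest.approx(scale * battery_runtime(base))

    def test_implied_idle_current(self):
        idle = implied_idle_current(95.0, 0.4, 45.0)
        assert idle == pytest.approx((45 - 0.4 * 95) / 0.6)
        assert idle == pytest.approx(11.67, abs=0.01)

    def test_implied_idle_degenerate_cases(self):
        assert implied_idle_current(95.0, 0.0, 10.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            implied_idle_current(95.0, 1.0, 95.0)
        with pytest.raises(ValueError):
            implied_idle_current(95.0, 0.9, 10.0)  # would need negative idle


class TestSampleSize:
    def test_one_tailed_paired_design_gives_18(self):
        assert sample_size_paired(StudyDesign()) == 18

    def test_two_tailed_gives_22(self):
        assert sample_size_paired(StudyDesign(tails="two")) == 22

    def test_huge_effect_needs_one_participant(self):
        assert sample_size_paired(StudyDesign(effect_size_d=10.0)) == 1

    def test_monotonicity_grid(self):
        for d1, d2 in [(0.4, 0.6), (0.6, 0.9)]:
            assert sample_size_paired(StudyDesign(effect_size_d=d1)) >= sample_size_paired(
                StudyDesign(effect_size_d=d2)
            )
        for a1, a2 in [(0.01, 0.05), (0.05, 0.1)]:
            assert sample_size_paired(StudyDesign(alpha=a1)) >= sample_size_paired(
                StudyDesign(alpha=a2)
            )
        for p1, p2 in [(0.8, 0.9), (0.9, 0.95)]:
            assert sample_size_paired(StudyDesign(power=p1)) <= sample_size_paired(
                StudyDesign(power=p2)
            )


class TestRmssd:
    def test_constant_rr_zero(self):
        assert rmssd([800.0] * 10) == 0.0

    def test_alternating_rr(self):
        assert rmssd([800.0, 810.0, 800.0, 810.0]) == pytest.approx(10.0)

    def test_agrees_with_direct_summation_oracle(self):
        rng = np.random.default_rng(6)
        rr = rng.normal(800, 50, size=120)
        acc = 0.0
        for i in range(1, len(rr)):
            acc += (rr[i] - rr[i - 1]) ** 2
        assert rmssd(rr) == pytest.approx(np.sqrt(acc / (len(rr) - 1)), rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rmssd([800.0])


class TestNormalizeToBaseline:
    def test_flat_signal_all_zero(self):
        x = np.full(100, 5.0)
        np.testing.assert_allclose(normalize_to_baseline(x, 1.0, 10.0), 0.0)

    def test_doubling_maps_to_one(self):
        x = np.concatenate([np.full(10, 5.0), np.full(10, 10.0)])
        out = normalize_to_baseline(x, 1.0, 10.0)
        np.testing.assert_allclose(out[10:], 1.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(1, 3, size=200)
        out = normalize_to_baseline(x, 2.0, 10.0)
        mean = x[:20].mean()
        np.testing.assert_allclose(out, (x - mean) / mean, rtol=1e-12)

    def test_zero_baseline_rejected(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        with pytest.raises(ValueError):
            normalize_to_baseline(x, 1.0, 10.0)
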