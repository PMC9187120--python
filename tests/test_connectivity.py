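"""Pairwise correlations, STTC, and jitter-corrected CCG detection."""

import math

import numpy as np
import pytest

from spikesight.connectivity import (BinnedTrialSpikes, CCGResult, ccg,
                                     detect_connection, jitter_correct,
                                     pairwise_pearson, population_pearson,
                                     sttc, trial_response_vector,
                                     passes_rate_floor)
from spikesight.core import AnalysisWindow, Unit
from spikesight.errors import AnalysisError
from spikesight.synth import inject_connection
from conftest import make_trials


def _poisson_trials(rate, n_trials, rng, window=(-0.5, 0.5)):
    dur = window[1] - window[0]
    return [np.sort(rng.uniform(window[0], window[1], rng.poisson(rate * dur)))
            for _ in range(n_trials)]


class TestTrialResponseVector:
    def test_single_spike_rate_arithmetic(self):
        tt = make_trials(n_stim=1, n_nostim=0)
        t0 = tt.trials[0].whisker_onset_s
        u = Unit(unit_id="u", area="wS1", spike_times=np.array([t0 + 0.02]))
        w = AnalysisWindow((0.005, 0.055), (-0.05, 0.0))
        np.testing.assert_allclose(trial_response_vector(u, tt, w), [20.0])

    def test_silent_unit_gives_zero_vector_below_floor(self):
        tt = make_trials(n_stim=5, n_nostim=0)
        u = Unit(unit_id="u", area="wS1")
        w = AnalysisWindow((0.005, 0.055), (-0.05, 0.0))
        vec = trial_response_vector(u, tt, w)
        np.testing.assert_allclose(vec, 0.0)
        assert not passes_rate_floor(vec)  # 2.5 Hz inclusion rule


class TestPairwisePearson:
    def test_identical_vectors_correlate_perfectly(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        assert pairwise_pearson(v, v) == pytest.approx(1.0)
        assert pairwise_pearson(v, -v) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # direct formula: cov/(sd_a*sd_b) = 0.9999009 for these vectors
        r = pairwise_pearson([1.0, 2.0, 3.0], [2.0, 4.0, 6.1])
        assert r == pytest.approx(0.9999009, abs=1e-6)

    def test_constant_vector_flagged_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            assert math.isnan(pairwise_pearson([1.0, 1.0, 1.0],
                                               [1.0, 2.0, 3.0]))


class TestPopulationPearson:
    def test_single_unit_per_area_reduces_to_pairwise(self):
        rng = np.random.default_rng(70)
        tt = make_trials(n_stim=30, n_nostim=0)
        w = AnalysisWindow((0.0, 0.1), (-0.1, 0.0))
        units = []
        for uid in ("a", "b"):
            spikes = np.sort(np.concatenate(
                [t.whisker_onset_s + rng.uniform(0, 0.1, rng.poisson(2))
                 for t in tt.trials]))
            units.append(Unit(unit_id=uid, area="wS1", spike_times=spikes))
        r_pop = population_pearson([units[0]], [units[1]], tt, w, w)
        r_pair = pairwise_pearson(trial_response_vector(units[0], tt, w),
                                  trial_response_vector(units[1], tt, w))
        assert r_pop == pytest.approx(r_pair)

    def test_shared_trial_gain_induces_positive_correlation(self):
        rng = np.random.default_rng(71)
        tt = make_trials(n_stim=60, n_nostim=0)
        w = AnalysisWindow((0.0, 0.1), (-0.1, 0.0))
        hits = 0
        for rep in range(20):
            gains = rng.uniform(0.5, 3.0, len(tt.trials))
            areas = []
            for area in ("wS1", "wM1"):
                us = []
                for j in range(4):
                    spikes = np.sort(np.concatenate(
                        [t.whisker_onset_s
                         + rng.uniform(0, 0.1, rng.poisson(4 * g))
                         for t, g in zip(tt.trials, gains)]))
                    us.append(Unit(unit_id=f"{area}{j}", area=area,
                                   spike_times=spikes))
                areas.append(us)
            hits += population_pearson(areas[0], areas[1], tt, w, w) > 0
        assert hits >= 19  # >= 95% of replicates


class TestSttc:
    def test_hand_computed_example(self):
        res = sttc([0.100, 0.500], [0.105], interval=(0.0, 1.0))
        assert res.value == pytest.approx(0.7424, abs=1e-4)
        assert res.p_a == pytest.approx(0.5)
        assert res.p_b == pytest.approx(1.0)
        assert res.t_a == pytest.approx(0.04)
        assert res.t_b == pytest.approx(0.02)

    def test_identical_trains_give_one(self):
        train = [0.1, 0.25, 0.4, 0.77]
        assert sttc(train, train).value == pytest.approx(1.0)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(72)
        for _ in range(50):
            a = np.sort(rng.uniform(0, 1, rng.poisson(8)))
            b = np.sort(rng.uniform(0, 1, rng.poisson(8)))
            if a.size == 0 or b.size == 0:
                continue
            ab, ba = sttc(a, b).value, sttc(b, a).value
            assert ab == pytest.approx(ba)
            assert -1.0 <= ab <= 1.0

    def test_independent_poisson_pairs_center_on_zero(self):
        rng = np.random.default_rng(73)
        vals = []
        for _ in range(1000):
            a = np.sort(rng.uniform(0, 1, rng.poisson(5)))
            b = np.sort(rng.uniform(0, 1, rng.poisson(5)))
            if a.size and b.size:
                vals.append(sttc(a, b).value)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_empty_train_flagged_undefined(self):
        with pytest.warns(UserWarning, match="empty"):
            assert math.isnan(sttc([], [0.5]).value)

    def test_edge_clipping_of_tiling_windows(self):
        # a spike at the interval edge tiles only half a neighbourhood
        res = sttc([0.0], [0.9], interval=(0.0, 1.0), dt=0.1)
        assert res.t_a == pytest.approx(0.1)


class TestCcg:
    def test_hand_computed_single_pair(self):
        ref = BinnedTrialSpikes(trial_index=np.array([0]),
                                bin_index=np.array([3]), n_trials=1,
                                n_bins=10)
        tgt = BinnedTrialSpikes(trial_index=np.array([0]),
                                bin_index=np.array([5]), n_trials=1,
                                n_bins=10)
        res = ccg(ref, tgt, max_lag=0.005, enforce_rate_min=False)
        at = dict(zip(np.round(res.lags_s * 1000).astype(int), res.ccg_raw))
        assert at[2] == pytest.approx(12.5)
        assert at[-2] == pytest.approx(0.0)

    def test_independent_poisson_normalizes_to_one(self):
        rng = np.random.default_rng(74)
        a = BinnedTrialSpikes.from_arrays(_poisson_trials(10, 200, rng))
        b = BinnedTrialSpikes.from_arrays(_poisson_trials(10, 200, rng))
        res = ccg(a, b)
        mc_se = res.ccg_raw.std() / np.sqrt(res.ccg_raw.size)
        assert abs(res.ccg_raw.mean() - 1.0) < 3 * mc_se + 0.02

    def test_shifted_copy_peaks_at_shift(self):
        rng = np.random.default_rng(75)
        pre = _poisson_trials(10, 100, rng)
        post = [tr + 0.003 for tr in pre]
        a = BinnedTrialSpikes.from_arrays(pre)
        b = BinnedTrialSpikes.from_arrays(post)
        res = ccg(a, b)
        assert res.lags_s[np.argmax(res.ccg_raw)] == pytest.approx(0.003)

    def test_rate_floor_enforced(self):
        rng = np.random.default_rng(76)
        a = BinnedTrialSpikes.from_arrays(_poisson_trials(0.5, 50, rng))
        b = BinnedTrialSpikes.from_arrays(_poisson_trials(10, 50, rng))
        with pytest.raises(AnalysisError, match="floor"):
            ccg(a, b)


class TestJitterCorrection:
    def test_stimulus_locked_comodulation_removed(self):
        # both units double their rate in the same 100-ms epoch on every
        # trial but are otherwise independent: raw CCG is inflated, the
        # corrected CCG is flat (no detections, mean ~ 0)
        rng = np.random.default_rng(77)
        detections = 0
        for rep in range(10):
            def comod_trials():
                out = []
                for _ in range(150):
                    base = rng.uniform(-0.5, 0.5, rng.poisson(8))
                    burst = rng.uniform(0.0, 0.1, rng.poisson(3.0))
                    out.append(np.sort(np.concatenate([base, burst])))
                return out
            a = BinnedTrialSpikes.from_arrays(comod_trials())
            b = BinnedTrialSpikes.from_arrays(comod_trials())
            res = jitter_correct(a, b, seed=rep)
            detected, _ = detect_connection(res)
            detections += detected
            n = res.ccg_corrected.size
            assert abs(res.ccg_corrected.mean()) < 3 * res.flank_sd / np.sqrt(n) + 0.01
        assert detections == 0

    def test_injected_synapse_survives_comodulation_removal(self):
        rng = np.random.default_rng(78)
        pre, post = [], []
        for _ in range(200):
            burst = rng.uniform(0.0, 0.1, rng.poisson(2.0))
            a = np.sort(np.concatenate(
                [rng.uniform(-0.5, 0.5, rng.poisson(10)), burst]))
            spawned = inject_connection(a, 0.2, 3.0, 0.3,
                                        seed=int(rng.integers(2 ** 31)))
            b = np.sort(np.concatenate(
                [rng.uniform(-0.5, 0.5, rng.poisson(5)),
                 rng.uniform(0.0, 0.1, rng.poisson(2.0)), spawned]))
            pre.append(a)
            post.append(b)
        res = jitter_correct(BinnedTrialSpikes.from_arrays(pre),
                             BinnedTrialSpikes.from_arrays(post), seed=0)
        detected, peak = detect_connection(res)
        assert detected
        assert peak == pytest.approx(0.003, abs=0.001)

    def test_single_trial_rejected(self):
        rng = np.random.default_rng(79)
        a = BinnedTrialSpikes.from_arrays(_poisson_trials(10, 1, rng))
        with pytest.raises(AnalysisError, match="2 trials"):
            jitter_correct(a, a)

    def test_corrected_equals_raw_minus_jittered(self):
        rng = np.random.default_rng(80)
        a = BinnedTrialSpikes.from_arrays(_poisson_trials(8, 60, rng))
        b = BinnedTrialSpikes.from_arrays(_poisson_trials(8, 60, rng))
        res = jitter_correct(a, b, n_resamples=20, seed=1)
        np.testing.assert_allclose(res.ccg_corrected,
                                   res.ccg_raw - res.ccg_jittered)


class TestDetectConnection:
    def _result(self, corrected, bin_width=0.001):
        L = (corrected.size - 1) // 2
        lags = np.arange(-L, L + 1) * bin_width
        return CCGResult(lags_s=lags, ccg_raw=corrected.copy(),
                         ccg_jittered=np.zeros_like(corrected),
                         ccg_corrected=corrected, bin_width_s=bin_width)

    def test_constructed_peak_detected_at_its_lag(self):
        rng = np.random.default_rng(81)
        corrected = rng.normal(0, 0.1, 201)
        corrected[100 + 3] = 10 * 0.1  # 10 flank SDs at +3 ms
        res = self._result(corrected)
        detected, peak = detect_connection(res)
        assert detected
        assert peak == pytest.approx(0.003)

    def test_mirrored_pair_peaks_at_negative_lag(self):
        rng = np.random.default_rng(82)
        corrected = rng.normal(0, 0.1, 201)
        corrected[100 + 3] = 1.5
        res_fwd = self._result(corrected)
        res_rev = self._result(corrected[::-1].copy())
        detect_connection(res_fwd)
        detected_rev, _ = detect_connection(res_rev)
        assert res_fwd.detected
        assert not detected_rev  # the mirrored peak sits at -3 ms
        assert res_rev.ccg_corrected[100 - 3] == pytest.approx(1.5)

    def test_null_false_positive_rate_below_one_percent(self):
        # 10,000 pairs of i.i.d. Gaussian corrected CCGs, 6-SD threshold
        rng = np.random.default_rng(83)
        corrected = rng.normal(0.0, 1.0, size=(10_000, 201))
        hits = 0
        for row in corrected:
            detected, _ = detect_connection(self._result(row))
            hits += detected
        assert hits / 10_000 < 0.01

    def test_zero_flank_variance_flagged_degenerate(self):
        res = self._result(np.zeros(201))
        detected, peak = detect_connection(res)
        assert not detected and res.degenerate
        assert math.isnan(peak)

    def test_zero_lag_excluded_from_detection_range(self):
        corrected = np.zeros(201)
        corrected[100] = 100.0  # huge peak exactly at zero lag
        corrected[150:201] = np.random.default_rng(84).normal(0, 0.01, 51)
        corrected[0:51] = np.random.default_rng(85).normal(0, 0.01, 51)
        detected, _ = detect_connection(self._result(corrected))
        assert not detected


class TestEndToEndRecovery:
    def test_sensitivity_and_false_positives_on_synthetic_cohort(self):
        # 30 pairs: 15 with an injected 3-ms synapse at efficacy 0.2 and
        # 15 independent; detection must be near-perfectly selective
        rng = np.random.default_rng(86)
        results = []
        for k in range(30):
            connected = k % 2 == 0
            pre, post = [], []
            for _ in range(200):
                a = np.sort(rng.uniform(-0.5, 0.5, rng.poisson(10)))
                extra = inject_connection(a, 0.2, 3.0, 0.3,
                                          seed=int(rng.integers(2 ** 31))) \
                    if connected else np.empty(0)
                b = np.sort(np.concatenate(
                    [rng.uniform(-0.5, 0.5, rng.poisson(5)), extra]))
                pre.append(a)
                post.append(b)
            res = jitter_correct(BinnedTrialSpikes.from_arrays(pre),
                                 BinnedTrialSpikes.from_arrays(post),
                                 seed=int(rng.integers(2 ** 31)))
            detected, _ = detect_connection(res)
            results.append((connected, detected))
        sens = np.mean([d for c, d in results if c])
        fp = np.mean([d for c, d in results if not c])
        assert sens >= 0.9
        assert fp == 0.0
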