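"""PSTHs, evoked responses, modulated fractions and group contrasts."""

import numpy as np
import pytest

from spikesight.core import AnalysisWindow, Trial, TrialTable, Unit
from spikesight.errors import AnalysisError
from spikesight.modulation import (EvokedResponse, compare_groups,
                                   compute_psth, evoked_response,
                                   modulated_fractions, outcome_contrast,
                                   smooth_rate)
from spikesight.stats import permutation_test_unpaired
from conftest import make_trials, poisson_unit


class TestComputePsth:
    def test_single_spike_unit_mass(self):
        tt = make_trials(n_stim=1, n_nostim=0)
        t0 = tt.trials[0].whisker_onset_s
        u = Unit(unit_id="u", area="wS1", spike_times=np.array([t0 + 0.0005]))
        psth = compute_psth(u, tt, "whisker", span=(-0.05, 0.05), sigma=0.0)
        event_bin = np.argmin(np.abs(psth.bin_centers_s - 0.0005))
        assert psth.rate_hz[event_bin] == pytest.approx(1000.0)
        assert psth.rate_hz.sum() == pytest.approx(1000.0)

    def test_homogeneous_poisson_is_flat(self):
        tt = make_trials(n_stim=300, n_nostim=200)
        span = tt.trials[-1].visual_onset_s + 5
        u = poisson_unit(10.0, span, np.random.default_rng(3))
        psth = compute_psth(u, tt, "visual", span=(-0.5, 0.5), sigma=0.01)
        assert np.all(np.abs(psth.rate_hz - 10.0) < 4.0)
        assert psth.rate_hz.mean() == pytest.approx(10.0, abs=0.5)

    def test_smoothing_preserves_interior_mass(self):
        # mass supported > 4 sigma from the edges is conserved exactly by
        # the unit-area kernel
        rng = np.random.default_rng(4)
        rate = np.zeros(400)
        rate[50:350] = rng.uniform(0, 50, 300)
        sm = smooth_rate(rate, 0.01, 0.001)
        assert abs(sm.sum() - rate.sum()) / rate.sum() < 1e-6

    def test_no_passing_trials_rejected(self):
        tt = make_trials(n_stim=0, n_nostim=4)
        u = Unit(unit_id="u", area="wS1")
        with pytest.raises(AnalysisError):
            compute_psth(u, tt, "whisker", span=(-0.1, 0.1))


class TestEvokedResponse:
    def _unit_with_counts(self, tt, resp_per_trial, base_per_trial):
        spikes = []
        for t in tt.select(require_event="whisker"):
            t0 = t.whisker_onset_s
            spikes.append(t0 + np.linspace(0.005, 0.095, resp_per_trial))
            spikes.append(t0 - 0.1 + np.linspace(0.005, 0.095, base_per_trial))
        return Unit(unit_id="u", area="wS1",
                    spike_times=np.sort(np.concatenate(spikes)))

    def test_arithmetic_of_window_deltas(self):
        # 5 spikes in 100-ms response vs 2 spikes in 100-ms baseline -> +30 Hz
        tt = make_trials(n_stim=10, n_nostim=0)
        u = self._unit_with_counts(tt, 5, 2)
        w = AnalysisWindow((0.0, 0.100), (-0.100, 0.0))
        r = evoked_response(u, tt, w, n_perm=2000, seed=0)
        assert r.delta_rate_hz == pytest.approx(30.0)
        assert r.direction == "positive"  # exhaustive one-sided p = 1/1024

    def test_silent_unit_has_zero_delta_no_direction(self):
        tt = make_trials(n_stim=8, n_nostim=0)
        u = Unit(unit_id="u", area="wS1")
        w = AnalysisWindow((0.0, 0.100), (-0.100, 0.0))
        r = evoked_response(u, tt, w, n_perm=100, seed=0)
        assert r.delta_rate_hz == 0.0
        assert r.direction == "none"

    def test_invariant_to_spikes_outside_windows(self):
        tt = make_trials(n_stim=10, n_nostim=0)
        u = self._unit_with_counts(tt, 4, 1)
        w = AnalysisWindow((0.0, 0.100), (-0.100, 0.0))
        r1 = evoked_response(u, tt, w, n_perm=500, seed=1)
        extra = np.array([t.whisker_onset_s + 0.7
                          for t in tt.select(require_event="whisker")])
        u2 = Unit(unit_id="u", area="wS1",
                  spike_times=np.sort(np.concatenate([u.spike_times, extra])))
        r2 = evoked_response(u2, tt, w, n_perm=500, seed=1)
        assert r1.delta_rate_hz == r2.delta_rate_hz
        assert r1.p_value == r2.p_value

    def test_missing_event_rejected(self):
        tt = make_trials(n_stim=0, n_nostim=5)
        w = AnalysisWindow((0.0, 0.1), (-0.1, 0.0))
        with pytest.raises(AnalysisError):
            evoked_response(Unit(unit_id="u", area="wS1"), tt, w)


class TestModulatedFractions:
    @staticmethod
    def _resp(uid, area, cls, direction):
        return EvokedResponse(unit_id=uid, window_name="w",
                              delta_rate_hz=0.0,
                              per_trial_deltas=np.empty(0), p_value=0.01,
                              direction=direction, area=area, cell_class=cls)

    def test_all_positive_gives_unit_fraction(self):
        rs = [self._resp(f"u{i}", "wS1", "RS", "positive") for i in range(8)]
        table = modulated_fractions(rs)
        row = table.iloc[0]
        assert row["frac_positive"] == 1.0
        assert row["frac_negative"] == 0.0
        assert not row["below_floor"]

    def test_small_group_flagged_below_reporting_floor(self):
        rs = [self._resp(f"u{i}", "wM2", "FS", "none") for i in range(4)]
        assert modulated_fractions(rs).iloc[0]["below_floor"]

    def test_null_units_match_test_level(self):
        # homogeneous Poisson units: each one-sided fraction ~ alpha = 0.025
        rng = np.random.default_rng(14)
        tt = make_trials(n_stim=30, n_nostim=10)
        span = tt.trials[-1].visual_onset_s + 5
        w = AnalysisWindow((0.0, 0.100), (-0.100, 0.0))
        responses = []
        n_units = 250
        for i in range(n_units):
            u = poisson_unit(8.0, span, rng, unit_id=f"u{i}")
            responses.append(evoked_response(u, tt, w, alpha=0.025,
                                             n_perm=400,
                                             seed=int(rng.integers(2 ** 31))))
        table = modulated_fractions(responses)
        row = table.iloc[0]
        # 99% binomial band around 0.025 with n = 250
        half = 2.576 * np.sqrt(0.025 * 0.975 / n_units)
        assert abs(row["frac_positive"] - 0.025) < half + 1e-9
        assert abs(row["frac_negative"] - 0.025) < half + 1e-9


class TestCompareGroups:
    @staticmethod
    def _simulated_responses(rng, n_units, amp_hz, base_hz=3.0, n_trials=40,
                             win=0.1):
        """Per-unit evoked deltas built from per-trial Poisson window
        counts, the sampling model evoked_response sees."""
        out = []
        for i in range(n_units):
            resp = rng.poisson((base_hz + amp_hz) * win, n_trials) / win
            base = rng.poisson(base_hz * win, n_trials) / win
            out.append(EvokedResponse(
                unit_id=f"u{i}", window_name="w",
                delta_rate_hz=float(np.mean(resp - base)),
                per_trial_deltas=resp - base, p_value=1.0, direction="none",
                area="wM1", cell_class="RS"))
        return out

    def test_null_groups_not_systematically_significant(self):
        rng = np.random.default_rng(31)
        ps = []
        for k in range(40):
            a = self._simulated_responses(rng, 30, 1.0)
            b = self._simulated_responses(rng, 30, 1.0)
            ps.append(compare_groups(a, b, n_perm=500,
                                     seed=int(rng.integers(2 ** 31))).p_value)
        assert np.mean(np.asarray(ps) < 0.05) < 0.2
        assert np.median(ps) > 0.2

    def test_power_on_learning_sized_effect(self):
        # Novice 1.8 Hz (150 units) vs Expert 0.9 Hz (450 units): the group
        # difference should be detected at alpha = 0.01 almost always
        rng = np.random.default_rng(33)
        detected = 0
        n_rep = 100
        for _ in range(n_rep):
            nov = self._simulated_responses(rng, 150, 1.8)
            exp = self._simulated_responses(rng, 450, 0.9)
            res = compare_groups(nov, exp, n_perm=1000,
                                 seed=int(rng.integers(2 ** 31)))
            detected += res.p_value < 0.01
        assert detected >= 95

    def test_swapping_groups_flips_statistic(self):
        rng = np.random.default_rng(35)
        a = self._simulated_responses(rng, 20, 2.0)
        b = self._simulated_responses(rng, 20, 0.5)
        r1 = compare_groups(a, b, n_perm=500, seed=1)
        r2 = compare_groups(b, a, n_perm=500, seed=1)
        assert r1.statistic == pytest.approx(-r2.statistic)


class TestOutcomeContrast:
    def _unit_with_outcome_rates(self, tt, rate_by_outcome, rng, win=0.8):
        spikes = []
        for t in tt.trials:
            lam = rate_by_outcome.get(t.outcome, 0.0) * win
            n = rng.poisson(lam)
            spikes.append(t.auditory_onset_s + rng.uniform(0, win, n))
        times = np.sort(np.concatenate(spikes))
        return Unit(unit_id="u", area="tjM1",
                    spike_times=times[np.concatenate(
                        [[True], np.diff(times) > 1e-6])])

    def test_identical_outcome_rates_give_large_p(self):
        rng = np.random.default_rng(41)
        tt = make_trials(n_stim=30, n_nostim=30)
        # whisker trials are "hit", no-stim are "CR"; same rate everywhere
        u = self._unit_with_outcome_rates(tt, {"hit": 6.0, "CR": 6.0}, rng)
        w = AnalysisWindow((0.0, 0.8), (-0.8, 0.0), reference="auditory")
        ps = [outcome_contrast(u, tt, ("hit",), ("CR",), w, n_perm=500,
                               seed=s).p_value for s in range(10)]
        assert np.median(ps) > 0.05

    def test_suppression_detected_in_most_replicate_units(self):
        # CR-specific rate drop of 2 Hz on a 5-Hz baseline
        rng = np.random.default_rng(43)
        tt = make_trials(n_stim=30, n_nostim=30)
        w = AnalysisWindow((0.0, 0.8), (-0.8, 0.0), reference="auditory")
        hits = 0
        n_rep = 100
        for k in range(n_rep):
            u = self._unit_with_outcome_rates(tt, {"hit": 5.0, "CR": 3.0}, rng)
            res = outcome_contrast(u, tt, ("CR",), ("hit",), w, n_perm=500,
                                   seed=int(rng.integers(2 ** 31)))
            hits += res.p_value < 0.05
        assert hits >= 90

    def test_single_trial_per_subset_warns_but_runs(self):
        tt = make_trials(n_stim=1, n_nostim=1)
        rng = np.random.default_rng(44)
        u = self._unit_with_outcome_rates(tt, {"hit": 10.0, "CR": 10.0}, rng)
        w = AnalysisWindow((0.0, 0.8), (-0.8, 0.0), reference="auditory")
        with pytest.warns(UserWarning, match="single trial"):
            res = outcome_contrast(u, tt, ("hit",), ("CR",), w)
        assert res.p_value >= 0.5

    def test_empty_subset_rejected(self):
        tt = make_trials(n_stim=3, n_nostim=0)
        u = Unit(unit_id="u", area="tjM1")
        w = AnalysisWindow((0.0, 0.8), (-0.8, 0.0), reference="auditory")
        with pytest.raises(AnalysisError):
            outcome_contrast(u, tt, ("hit",), ("CR",), w)
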