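"""Trial classification, regime probabilities, timing, Pearson, SPIKE-distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corrgate.measures import (
    RegimeProbabilities,
    TrialClassification,
    classify_blocking_trial,
    classify_erasing_trial,
    dms_outcome,
    estimate_probabilities,
    running_mean_pearson,
    spike_synchrony,
    timing_analysis,
)
from corrgate.spike_distance import (
    bivariate_spike_distance,
    multivariate_spike_distance,
)

from _spike_oracle import multivariate_spike_distance_oracle


def _trace(duration=1000.0, base=20.0):
    return np.full(int(duration // 10), float(base))


class TestClassification:
    def test_persistent_not_erased(self):
        out = classify_erasing_trial(_trace())
        assert out.persistent_at_check and out.erased is False

    def test_persistent_then_silent_is_erased(self):
        trace = _trace()
        trace[60:] = 0.0
        out = classify_erasing_trial(trace)
        assert out.persistent_at_check and out.erased

    def test_never_persistent_is_discarded(self):
        out = classify_erasing_trial(_trace(base=0.0))
        assert not out.persistent_at_check and out.erased is None

    def test_blocking_on_quiet_and_active_traces(self):
        assert classify_blocking_trial(_trace(500, 0.0)).blocked
        assert not classify_blocking_trial(_trace(500, 20.0)).blocked

    def test_transient_outside_window_still_blocked(self):
        trace = _trace(500, 0.0)
        trace[20] = 30.0  # excursion at 200 ms, outside [400, 500)
        assert classify_blocking_trial(trace).blocked

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            classify_erasing_trial(_trace(300))


class TestRegimeProbabilities:
    @pytest.mark.parametrize(
        "p_e,p_b,regime",
        [(0.0, 0.0, "gate-in"), (0.0, 1.0, "selective-gate"), (1.0, 1.0, "gate-out")],
    )
    def test_pure_regimes(self, p_e, p_b, regime):
        probs = RegimeProbabilities(p_e, p_b, 0.0, 0.0, 10, 10)
        assert probs.regime == regime
        assert max(probs.p_gi, probs.p_sg, probs.p_go) == pytest.approx(1.0)

    @settings(max_examples=200, derandomize=True)
    @given(p_e=st.floats(0, 1), p_b=st.floats(0, 1))
    def test_probability_identity(self, p_e, p_b):
        probs = RegimeProbabilities(p_e, p_b, 0.0, 0.0, 1, 1)
        total = probs.p_gi + probs.p_sg + probs.p_go + p_e * (1 - p_b)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_estimate_from_trials(self):
        trials = (
            [TrialClassification(persistent_at_check=True, erased=True)] * 3
            + [TrialClassification(persistent_at_check=True, erased=False)] * 5
            + [TrialClassification(persistent_at_check=False)] * 2
            + [TrialClassification(blocked=True)] * 4
            + [TrialClassification(blocked=False)] * 6
        )
        probs = estimate_probabilities(trials)
        assert probs.p_e == pytest.approx(3 / 8)
        assert probs.p_b == pytest.approx(0.4)
        assert probs.n_valid == 8
        assert probs.se_b == pytest.approx(np.sqrt(0.4 * 0.6 / 10))

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            estimate_probabilities([])
        with pytest.raises(ValueError):
            estimate_probabilities([TrialClassification(persistent_at_check=False)])


class TestTimingAnalysis:
    def test_hand_traced_fixture(self):
        # 20-Hz plateau, a 30-Hz peak bin at 850 ms, silence from 870 ms
        trace = _trace(1000.0, 20.0)
        trace[85] = 30.0
        trace[87:] = 0.0
        res = timing_analysis(trace, t_corr=800.0)
        assert res.t_stop == 870.0
        assert res.t_peak == 850.0
        assert res.dt_corr_peak == 50.0
        assert res.dt_peak_stop == 20.0

    def test_never_stopping_trace(self):
        res = timing_analysis(_trace(), t_corr=500.0)
        assert res.t_stop is None and res.t_peak is None

    def test_stop_without_qualifying_peak(self):
        trace = _trace(1000.0, 10.0)  # never exceeds 20 Hz
        trace[90:] = 0.0
        res = timing_analysis(trace, t_corr=800.0)
        assert res.t_stop == 900.0
        assert res.t_peak is None

    def test_plateau_tie_resolves_to_later_bin(self):
        trace = _trace(1000.0, 15.0)
        trace[82:85] = 25.0  # flat 30-ms plateau above 20 Hz
        trace[88:] = 0.0
        res = timing_analysis(trace, t_corr=800.0)
        assert res.t_peak == 840.0


class TestRunningMeanPearson:
    def test_identical_traces_give_one(self, rng):
        x = rng.normal(size=(200, 1))
        cur = np.repeat(x, 4, axis=1)
        assert running_mean_pearson(cur) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        cur = rng.normal(size=(5000, 6))
        assert running_mean_pearson(cur) == pytest.approx(0.0, abs=0.05)

    def test_zero_variance_trace_excluded(self, rng):
        cur = rng.normal(size=(300, 3))
        cur[:, 2] = 1.0
        with pytest.warns(UserWarning):
            rho = running_mean_pearson(cur)
        assert -1.0 <= rho <= 1.0


class TestSpikeDistance:
    def test_identical_trains_distance_zero_synchrony_one(self):
        t = np.array([10.0, 30.0, 55.0, 80.0])
        assert bivariate_spike_distance(t, t, 0.0, 100.0) == pytest.approx(0.0)
        assert spike_synchrony([t, t, t], (0.0, 100.0)) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_distance_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        trains = [np.sort(rng.uniform(0, 100, rng.integers(1, 20)))
                  for _ in range(3)]
        s = multivariate_spike_distance(trains, 0.0, 100.0)
        assert 0.0 <= s <= 1.0

    def test_antiphase_periodic_trains_match_oracle(self):
        a = np.arange(5.0, 100.0, 10.0)
        s = bivariate_spike_distance(a, a + 5.0, 0.0, 100.0)
        oracle = multivariate_spike_distance_oracle([a, a + 5.0], 0.0, 100.0)
        assert s == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_trains_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        trains = [np.sort(rng.uniform(0, 200, rng.integers(2, 30)))
                  for _ in range(4)]
        mine = multivariate_spike_distance(trains, 0.0, 200.0)
        oracle = multivariate_spike_distance_oracle(trains, 0.0, 200.0)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_spikeless_train_rejected(self):
        with pytest.raises(ValueError):
            bivariate_spike_distance(np.array([]), np.array([1.0]), 0.0, 10.0)


class TestDmsOutcome:
    def _traces(self, duration, b=20.0, r=0.0):
        n = int(duration // 10)
        return np.full(n, float(b)), np.full(n, float(r))

    def test_ideal_wta_trial(self):
        rate_b, rate_r = self._traces(1300.0)
        rate_b[100:] = 0.0  # B deactivates after the match window opens
        out = dms_outcome(rate_b, rate_r, family="wta")
        assert out == {"load": True, "protect": True, "clear": True}

    def test_distractor_ignition_fails_protect(self):
        rate_b, rate_r = self._traces(1300.0)
        rate_b[100:] = 0.0
        rate_r[50:] = 20.0  # R ignites at 500 ms and persists
        out = dms_outcome(rate_b, rate_r, family="wta")
        assert out["load"] and not out["protect"]

    def test_two_unit_maintain_block_split(self):
        rate_b, rate_r = self._traces(1200.0)
        rate_b[95:] = 0.0
        rate_r[45:55] = 15.0  # transient distractor response only
        out = dms_outcome(rate_b, rate_r, family="two_unit")
        assert out["maintain"] and out["block"] and out["protect"]
        assert out["load"] and out["clear"]

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            dms_outcome(np.zeros(200), np.zeros(200), family="ring")
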