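"""SDT behavior: rates, d'/criterion, psychometric curves, sliding state."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm, spearmanr

from perisacc import synth
from perisacc.behavior import (
    OutcomeCounts,
    count_outcomes,
    dprime_criterion,
    median_split,
    psychometric,
    rates,
    sdt_from_counts,
    sliding_sdt,
)
from perisacc.errors import DegenerateSplitError, UndefinedRateError


def _inv_phi(p):
    """Independent inverse-normal oracle: root-find the CDF."""
    return brentq(lambda x: norm.cdf(x) - p, -10, 10, xtol=1e-12)


class TestRates:
    def test_balanced_counts(self):
        assert rates(OutcomeCounts(10, 10, 10, 10)) == (0.5, 0.5)

    def test_perfect_observer(self):
        assert rates(OutcomeCounts(42, 0, 50, 0)) == (1.0, 0.0)

    def test_zero_denominator(self):
        with pytest.raises(UndefinedRateError):
            rates(OutcomeCounts(0, 0, 5, 5))


class TestDprimeCriterion:
    def test_chance_observer(self):
        m = dprime_criterion(0.5, 0.5)
        assert m.dprime == 0.0 and m.criterion == 0.0

    def test_symmetric_rates_match_quantile_oracle(self):
        m = dprime_criterion(0.84, 0.16)
        expected = _inv_phi(0.84) - _inv_phi(0.16)
        assert m.dprime == pytest.approx(expected, abs=1e-9)
        assert m.criterion == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("r", [0.2, 0.35, 0.5, 0.7])
    def test_equal_rates_give_zero_dprime(self, r):
        assert dprime_criterion(r, r).dprime == pytest.approx(0.0, abs=1e-12)

    def test_criterion_zero_whenever_hr_is_one_minus_fa(self):
        for fa in (0.05, 0.2, 0.4, 0.45):
            m = dprime_criterion(1 - fa, fa)
            assert m.criterion == pytest.approx(0.0, abs=1e-12)

    def test_monotonicity_grid(self):
        grid = np.linspace(0.05, 0.95, 10)
        for fa in grid:
            d = [dprime_criterion(h, fa).dprime for h in grid]
            assert np.all(np.diff(d) > 0)  # increasing in hit rate
        for h in grid:
            d = [dprime_criterion(h, fa).dprime for fa in grid]
            assert np.all(np.diff(d) < 0)  # decreasing in FA rate

    def test_edge_correction(self):
        m = dprime_criterion(1.0, 0.0, n_signal=50, n_noise=40)
        assert m.corrected
        assert m.hit_rate == 1 - 1 / 100 and m.fa_rate == 1 / 80
        assert np.isfinite(m.dprime)

    def test_parameter_recovery_grid(self):
        """Simulated observers over a (d', c) grid: mean estimate within
        0.1 of truth at n = 500 trials per run, 100 seeds."""
        task = synth.TaskParams(n_trials=500)
        trials = synth.gen_trials(task, 2024)
        for true_dp in (0.5, 1.0, 2.0):
            for true_c in (-0.5, 0.0, 0.5):
                obs = synth.ObserverParams.flat(true_dp, true_c)
                dps, cs = [], []
                for s in range(100):
                    done, _ = synth.gen_observer(trials, obs, 900 + s)
                    m = sdt_from_counts(count_outcomes(done))
                    dps.append(m.dprime)
                    cs.append(m.criterion)
                assert np.mean(dps) == pytest.approx(true_dp, abs=0.1)
                assert np.mean(cs) == pytest.approx(true_c, abs=0.1)


class TestPsychometric:
    def test_four_levels_in_four_points_out(self, small_session):
        session, _ = small_session
        psy = psychometric(session.completed_trials())
        assert len(psy) == 4

    def test_monotone_sensitivity_recovered(self):
        task = synth.TaskParams(n_trials=400)
        trials = synth.gen_trials(task, 5)
        obs = synth.ObserverParams()  # monotone-increasing d' map
        rhos = []
        for s in range(100):
            done, _ = synth.gen_observer(trials, obs, 3000 + s)
            psy = psychometric(done)
            amps = sorted(psy)
            rho = spearmanr(amps, [psy[a].dprime for a in amps]).statistic
            rhos.append(rho)
        assert np.mean(rhos) > 0.8

    def test_null_observer_flat(self):
        task = synth.TaskParams(n_trials=2000)
        trials = synth.gen_trials(task, 6)
        done, _ = synth.gen_observer(trials, synth.ObserverParams.flat(0.0, 0.0), 7)
        psy = psychometric(done)
        for m in psy.values():
            se = np.sqrt(2 * np.pi) * 2 / np.sqrt(m.n_signal)  # rough CI scale
            assert abs(m.dprime) < 3 * se


class TestSlidingState:
    def test_window_count(self):
        task = synth.TaskParams(n_trials=60)
        trials = synth.gen_trials(task, 8)
        done, _ = synth.gen_observer(trials, synth.ObserverParams(), 9)
        state = sliding_sdt(done, window=50)
        assert len(state.window_metrics) == 11  # n - w + 1

    def test_full_window_reproduces_session_estimate(self):
        task = synth.TaskParams(n_trials=80)
        trials = synth.gen_trials(task, 10)
        done, _ = synth.gen_observer(trials, synth.ObserverParams(), 11)
        state = sliding_sdt(done, window=len(done))
        whole = sdt_from_counts(count_outcomes(done))
        assert np.allclose(state.dprime_t, whole.dprime)
        assert np.allclose(state.criterion_t, whole.criterion)

    def test_stationary_observer_windowed_mean_near_session_value(self):
        task = synth.TaskParams(n_trials=200)
        trials = synth.gen_trials(task, 12)
        done, _ = synth.gen_observer(trials, synth.ObserverParams.flat(1.2, 0.2), 13)
        state = sliding_sdt(done, window=50)
        whole = sdt_from_counts(count_outcomes(done))
        assert abs(np.mean([m.dprime for m in state.window_metrics]) - whole.dprime) < 0.15

    def test_step_change_detected(self):
        n = 300
        task = synth.TaskParams(n_trials=n)
        trials = synth.gen_trials(task, 14)
        scale = np.r_[np.full(n // 2, 0.5), np.full(n // 2, 1.6)]
        obs = synth.ObserverParams.flat(1.4, 0.2, dprime_scale_t=scale)
        done, _ = synth.gen_observer(trials, obs, 15)
        state = sliding_sdt(done, window=50)
        third = n // 3
        assert state.dprime_t[:third].mean() < state.dprime_t[-third:].mean()


class TestMedianSplit:
    def test_even_values(self):
        assert median_split([1, 2, 3, 4]) == ["low", "low", "high", "high"]

    def test_all_identical_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            median_split([5, 5, 5])

    def test_group_sizes_balanced(self, rng):
        for _ in range(200):
            n = rng.integers(2, 40)
            v = rng.choice([0.0, 1.0, 2.0, 3.0], size=n)
            if np.all(v == v[0]):
                continue
            labels = median_split(v)
            n_low = labels.count("low")
            assert abs(n_low - (n - n_low)) <= 1
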