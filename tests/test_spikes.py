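"""PETHs, baseline standardization, and the pre/post-saccadic split."""

import numpy as np
import pytest

from perisacc import synth
from perisacc.errors import DegenerateBaselineError
from perisacc.session import SpikeTrain, align_events
from perisacc.spikes import (
    BaselineStats,
    baseline_stats,
    peth,
    population_peth,
    saccadic_decomposition,
    zscore,
)


def _train(times, span=(0.0, 100.0)):
    return SpikeTrain(neuron_id="t", times=np.asarray(times, float), span=span)


class TestBaseline:
    def test_poisson_baseline_within_ci(self, rng):
        task = synth.TaskParams(n_trials=600)
        trials = synth.gen_trials(task, 31)
        trials, _ = synth.gen_observer(trials, synth.ObserverParams(), 32)
        span = (0.0, max(t.t_targets_off for t in trials) + 1.0)
        st, _ = synth.gen_spikes(trials, synth.NeuronParams(baseline=4.62), 33, span)
        bs = baseline_stats(st, trials)
        # mean window length ~0.45 s -> SEM = sqrt(r/L)/sqrt(n)
        sem = np.sqrt(4.62 / 0.45) / np.sqrt(bs.n_trials)
        assert abs(bs.mean_rate - 4.62) < 2.5 * sem

    def test_constant_count_degenerates_in_zscore(self):
        from perisacc.session import TrialEvents

        # full 500 ms windows, one spike in each -> rate 2.0, SD 0
        trials = [
            TrialEvents(
                trial_id=i, t_fix_on=2.0 * i, t_grating1_on=2.0 * i + 0.6,
                change_present=False, choice="no", outcome="correct_reject",
                completed=True,
            )
            for i in range(20)
        ]
        st = _train([2.0 * i + 0.1 for i in range(20)])
        bs = baseline_stats(st, trials)
        assert bs.mean_rate == pytest.approx(2.0) and bs.sd_rate == 0.0
        with pytest.raises(DegenerateBaselineError):
            zscore(5.0, bs)
        with pytest.raises(DegenerateBaselineError):
            baseline_stats(st, trials, require_sd=True)

    def test_no_spikes_zero_mean(self, small_session):
        session, _ = small_session
        bs = baseline_stats(_train([], session.eye.span), session.completed_trials())
        assert bs.mean_rate == 0.0 and bs.sd_rate == 0.0


class TestZscore:
    BASE = BaselineStats(mean_rate=4.0, sd_rate=2.0, n_trials=100)

    def test_mean_maps_to_zero_and_sd_to_one(self):
        assert zscore(4.0, self.BASE) == 0.0
        assert zscore(6.0, self.BASE) == 1.0

    def test_inversion_recovers_rate(self, rng):
        r = rng.uniform(0, 30, 100)
        z = zscore(r, self.BASE)
        assert np.allclose(z * self.BASE.sd_rate + self.BASE.mean_rate, r)


class TestPETH:
    def test_spike_at_event_lands_in_first_nonnegative_bin(self):
        p = peth(_train([50.0]), [50.0], (-100.0, 100.0), 20.0)
        assert p.counts.sum() == 1
        assert p.counts[0, 5] == 1  # bin [0, 20) by the half-open rule

    def test_window_must_divide_into_bins(self):
        with pytest.raises(ValueError):
            peth(_train([1.0]), [1.0], (-100.0, 90.0), 20.0)

    def test_matches_bruteforce_counting(self, rng):
        for _ in range(100):
            spikes = np.sort(rng.uniform(0, 30, rng.integers(0, 400)))
            events = rng.uniform(1, 29, rng.integers(1, 15))
            bin_ms = float(rng.choice([10.0, 20.0, 25.0]))
            n_bins = int(rng.integers(2, 12))
            lo = float(rng.integers(-10, 0)) * bin_ms
            hi = lo + n_bins * bin_ms
            p = peth(_train(spikes, (0.0, 30.0)), events, (lo, hi), bin_ms)
            brute = np.zeros((events.size, n_bins), dtype=int)
            for i, e in enumerate(events):
                for s in spikes:
                    for b in range(n_bins):
                        b_lo = e + (lo + b * bin_ms) * 1e-3
                        b_hi = e + (lo + (b + 1) * bin_ms) * 1e-3
                        if b_lo <= s < b_hi:
                            brute[i, b] += 1
            assert np.array_equal(p.counts, brute)

    def test_bin_sums_conserve_aligned_counts(self, rng):
        spikes = np.sort(rng.uniform(0, 30, 500))
        events = rng.uniform(1, 29, 10)
        p = peth(_train(spikes, (0.0, 30.0)), events, (-200.0, 300.0), 20.0)
        aligned = align_events(spikes, events, (-0.2, 0.3))
        assert np.array_equal(p.counts.sum(axis=1), [a.size for a in aligned])

    def test_poisson_mean_rate_within_ci(self, rng):
        # homogeneous rate r: each 20 ms bin's mean rate estimates r
        r, n_ev = 20.0, 10_000
        spikes = np.sort(rng.uniform(0, 2000, int(r * 2000)))
        events = rng.uniform(10, 1990, n_ev)
        p = peth(_train(spikes, (0.0, 2000.0)), events, (-100.0, 100.0), 20.0)
        sem = np.sqrt(r / 0.02 / n_ev)
        assert np.all(np.abs(p.mean_rate - r) < 4 * sem)


class TestPopulationPETH:
    def test_identical_neurons_zero_sem(self, small_session):
        session, _ = small_session
        trials = session.completed_trials()
        st = session.spikes[0]
        bs = baseline_stats(st, trials)
        p = peth(st, [t.t_saccade for t in trials], (-300.0, 200.0), 20.0, baseline=bs)
        mean, sem = population_peth([p, p, p])
        assert np.allclose(mean, p.z)
        assert np.allclose(sem, 0.0)

    def test_mismatched_grids_rejected(self, small_session):
        session, _ = small_session
        trials = session.completed_trials()
        st = session.spikes[0]
        bs = baseline_stats(st, trials)
        ev = [t.t_saccade for t in trials]
        p1 = peth(st, ev, (-300.0, 200.0), 20.0, baseline=bs)
        p2 = peth(st, ev, (-200.0, 300.0), 20.0, baseline=bs)
        with pytest.raises(ValueError):
            population_peth([p1, p2])

    def test_null_population_mean_within_sem_bands(self):
        task = synth.TaskParams(n_trials=200)
        trials = synth.gen_trials(task, 41)
        trials, _ = synth.gen_observer(trials, synth.ObserverParams(), 42)
        span = (0.0, max(t.t_targets_off for t in trials) + 1.0)
        peths = []
        for i in range(12):
            st, _ = synth.gen_spikes(trials, synth.NeuronParams(baseline=5.0), 50 + i, span)
            bs = baseline_stats(st, trials)
            peths.append(
                peth(st, [t.t_saccade for t in trials], (-300.0, 200.0), 20.0, baseline=bs)
            )
        mean, sem = population_peth(peths)
        # stationary population: no bin should sit far outside its SEM band
        assert np.mean(np.abs(mean) < 3.5 * sem) > 0.95


class TestSaccadicDecomposition:
    def _session(self, pre, post, n_trials=300, seed=61):
        task = synth.TaskParams(n_trials=n_trials)
        trials = synth.gen_trials(task, seed)
        trials, _ = synth.gen_observer(trials, synth.ObserverParams(), seed + 1)
        span = (0.0, max(t.t_targets_off for t in trials) + 1.0)
        npar = synth.NeuronParams(baseline=4.62, pre_gain=pre, post_gain=post)
        st, _ = synth.gen_spikes(trials, npar, seed + 2, span)
        return st, trials

    def test_stationary_neuron_deltas_near_zero(self):
        st, trials = self._session(0.0, 0.0)
        d = saccadic_decomposition(st, trials, 1)
        se = np.sqrt(4.62 / 0.1 / len(trials))
        assert abs(d.pre_delta) < 4 * se and abs(d.post_delta) < 4 * se

    def test_planted_gains_recovered(self):
        pre_d, post_d = [], []
        for s in range(10):
            st, trials = self._session(6.0, 6.0, seed=100 + 3 * s)
            d = saccadic_decomposition(st, trials, 1)
            pre_d.append(d.pre_delta)
            post_d.append(d.post_delta)
        assert np.mean(pre_d) == pytest.approx(6.0, rel=0.2)
        assert np.mean(post_d) == pytest.approx(6.0, rel=0.2)

    def test_pre_only_kernel_never_swaps(self):
        for s in range(10):
            st, trials = self._session(8.0, 0.0, seed=300 + 3 * s)
            d = saccadic_decomposition(st, trials, 1)
            assert d.pre_delta > d.post_delta
            assert d.pre_delta > 2.0

    def test_task_version_selects_baseline_window(self):
        st, trials = self._session(0.0, 0.0)
        d1 = saccadic_decomposition(st, trials, 1)
        d2 = saccadic_decomposition(st, trials, 2)
        # same spikes, different baseline windows -> baselines generally differ
        assert not np.array_equal(d1.baseline_rates, d2.baseline_rates)
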