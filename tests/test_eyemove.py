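"""Microsaccade detection: velocity estimation, thresholds, filters."""

import numpy as np
import pytest

from perisacc import synth
from perisacc.errors import DegenerateThresholdError, NoSaccadeError
from perisacc.eyemove import (
    DetectionParams,
    compute_velocity,
    detect_choice_saccade,
    detect_microsaccades,
    estimate_threshold,
    label_epoch,
    trial_thresholds,
)
from perisacc.session import EyeTrace, TrialEvents
from perisacc.synth import _minjerk_profile

RATE = 1000.0


def _trace(x, y):
    return EyeTrace(t0=0.0, rate=RATE, x=x, y=y)


def _one_trial_trace(rng, n_s=4.0, noise_sd=0.005):
    """A single-trial session: quiet jittery fixation, one completed trial."""
    n = int(n_s * RATE)
    x = rng.normal(0, noise_sd, n).cumsum() * 0  # placeholder, replaced below
    from scipy.ndimage import gaussian_filter1d

    x = gaussian_filter1d(rng.standard_normal(n), 15.0)
    y = gaussian_filter1d(rng.standard_normal(n), 15.0)
    x *= noise_sd / x.std()
    y *= noise_sd / y.std()
    trial = TrialEvents(
        trial_id=0, t_fix_on=0.3, t_grating1_on=0.8, t_grating1_off=1.15,
        t_grating2_on=1.4, t_grating2_off=1.75, t_targets_on=2.3, t_go=2.3,
        t_saccade=2.5, t_targets_off=2.7, change_present=True,
        change_amplitude=2.0, choice="yes", outcome="hit", completed=True,
    )
    return x, y, trial


def _plant(x, y, t_on, amplitude, duration_s, axis="x"):
    prof = _minjerk_profile(max(int(round(duration_s * RATE)), 2)) * amplitude
    i0 = int(t_on * RATE)
    tgt = x if axis == "x" else y
    tgt[i0 : i0 + prof.size] += prof
    tgt[i0 + prof.size :] += amplitude


class TestVelocity:
    def test_constant_position_zero_velocity(self):
        v = compute_velocity(_trace(np.full(500, 2.0), np.full(500, -1.0)))
        assert np.nanmax(v.v_radial) == 0.0

    @pytest.mark.parametrize("axis", ["x", "y"])
    def test_linear_ramp_and_rotational_symmetry(self, axis):
        t = np.arange(2000) / RATE
        ramp = 3.0 * t
        flat = np.zeros_like(t)
        eye = _trace(ramp, flat) if axis == "x" else _trace(flat, ramp)
        v = compute_velocity(eye)
        core = v.v_radial[10:-10]
        assert np.allclose(core, 3.0)

    def test_too_short_trace_errors(self):
        with pytest.raises(ValueError):
            compute_velocity(_trace(np.zeros(3), np.zeros(3)), smooth_span=5)

    def test_blink_samples_masked(self):
        x = np.zeros(400)
        eye = EyeTrace(t0=0.0, rate=RATE, x=x, y=x.copy(),
                       blink_mask=np.r_[np.zeros(200, bool), np.ones(10, bool),
                                        np.zeros(190, bool)])
        v = compute_velocity(eye)
        assert np.isnan(v.v_radial[200:210]).all()
        assert np.isnan(v.v_radial[198])  # within half-span of the blink


class TestThreshold:
    def test_matches_sample_sd_oracle(self, rng):
        v = np.abs(rng.normal(0, 5.0, 5000))
        expected = 4.0 * np.std(v, ddof=1)
        assert estimate_threshold(v, 4.0) == pytest.approx(expected)

    def test_scaling_homogeneity(self, rng):
        v = np.abs(rng.normal(0, 2.0, 1000))
        assert estimate_threshold(3 * v) == pytest.approx(3 * estimate_threshold(v))

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateThresholdError):
            estimate_threshold(np.full(100, 7.0))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            estimate_threshold(np.arange(10.0))

    def test_per_trial_window_and_floor(self, rng):
        x, y, trial = _one_trial_trace(rng)
        vel = compute_velocity(_trace(x, y))
        thr = trial_thresholds(vel, [trial])
        # quiet trace: the SD multiple sinks below the floor, which binds
        assert thr[0] == DetectionParams().floor_dps


class TestDetectionFilters:
    """The three rejection rules, each probed with a targeted planted event."""

    def _detect(self, rng, amplitude, duration_s):
        x, y, trial = _one_trial_trace(rng)
        _plant(x, y, t_on=1.0, amplitude=amplitude, duration_s=duration_s)
        events = detect_microsaccades(_trace(x, y), [trial])
        return [e for e in events if abs(e.t_on - 1.0) < 0.05]

    def test_valid_event_detected(self, rng):
        hits = self._detect(rng, amplitude=0.5, duration_s=0.019)
        assert len(hits) == 1
        e = hits[0]
        assert e.amplitude_deg == pytest.approx(0.5, abs=0.05)
        assert e.threshold_dps <= e.peak_velocity_dps <= 100.0

    def test_amplitude_above_one_degree_rejected(self, rng):
        # slow enough (vpeak ~ 64 deg/s) that only the amplitude rule fires
        assert self._detect(rng, amplitude=1.2, duration_s=0.035) == []

    def test_duration_below_6ms_rejected(self, rng):
        # vpeak ~ 47 deg/s crosses threshold but only for < 6 ms
        assert self._detect(rng, amplitude=0.1, duration_s=0.004) == []

    def test_velocity_above_100dps_rejected(self, rng):
        # amplitude 0.9 deg passes, but vpeak = 1.875*0.9/0.0125 = 135 deg/s
        assert self._detect(rng, amplitude=0.9, duration_s=0.0125) == []

    def test_noise_only_trace_yields_nothing(self, rng):
        x, y, trial = _one_trial_trace(rng)
        assert detect_microsaccades(_trace(x, y), [trial]) == []

    def test_translation_invariance(self, rng):
        x, y, trial = _one_trial_trace(rng)
        _plant(x, y, t_on=1.0, amplitude=0.5, duration_s=0.019)
        ev1 = detect_microsaccades(_trace(x, y), [trial])
        ev2 = detect_microsaccades(_trace(x + 4.2, y - 1.7), [trial])
        assert [e.t_on for e in ev1] == [e.t_on for e in ev2]
        assert [e.amplitude_deg for e in ev1] == pytest.approx(
            [e.amplitude_deg for e in ev2]
        )


class TestDetectionSession:
    def test_events_sorted_disjoint_and_filtered(self, v2_trials, rng):
        eye, gt = synth.gen_eye(v2_trials[:60], synth.EyeGenParams(), seed=5)
        params = DetectionParams()
        events = detect_microsaccades(eye, v2_trials[:60], params)
        assert len(events) > 10
        for a, b in zip(events, events[1:]):
            assert a.t_on < b.t_on
            assert a.t_off <= b.t_on  # no overlap
        for e in events:
            assert e.duration_ms >= params.dur_min
            assert e.amplitude_deg <= params.amp_max
            assert e.threshold_dps <= e.peak_velocity_dps <= params.v_max

    def test_epoch_labels(self):
        tr = TrialEvents(trial_id=5, t_fix_on=1.0, t_grating1_on=1.5,
                         t_targets_on=3.0, t_go=3.4, t_saccade=3.6,
                         t_targets_off=3.8)
        assert label_epoch(3.1, tr) == "choice"
        assert label_epoch(1.6, tr) == "other"  # during grating 1
        assert label_epoch(4.5, tr) == "outside_trial"
        assert label_epoch(3.0, tr) == "choice"  # onset boundary inclusive
        assert label_epoch(3.8, tr) == "outside_trial"


class TestChoiceSaccade:
    def test_onset_recovered_within_5ms(self, rng):
        x, y, _ = _one_trial_trace(rng, n_s=5.0)
        t_go = 2.3
        _plant(x, y, t_on=t_go + 0.180, amplitude=8.0, duration_s=0.04, axis="y")
        t = detect_choice_saccade(_trace(x, y), t_go)
        assert t == pytest.approx(t_go + 0.180, abs=0.005)

    def test_stationary_trace_raises(self, rng):
        x, y, _ = _one_trial_trace(rng)
        with pytest.raises(NoSaccadeError):
            detect_choice_saccade(_trace(x, y), t_go=2.3)

    def test_sample_rate_invariance(self, rng):
        # doubling the sample rate moves the onset by < one original sample
        t_go, onset = 1.0, 1.2
        times = {}
        for rate in (1000.0, 2000.0):
            n = int(3.0 * rate)
            from scipy.ndimage import gaussian_filter1d

            g = np.random.default_rng(7)
            x = gaussian_filter1d(g.standard_normal(n), 0.015 * rate)
            x *= 0.005 / x.std()
            y = x.copy()
            prof = _minjerk_profile(int(0.04 * rate)) * 8.0
            i0 = int(onset * rate)
            y[i0 : i0 + prof.size] += prof
            y[i0 + prof.size :] += 8.0
            eye = EyeTrace(t0=0.0, rate=rate, x=x, y=y)
            times[rate] = detect_choice_saccade(eye, t_go)
        assert abs(times[1000.0] - times[2000.0]) <= 1.5e-3
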