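"""Synthetic session generator with full ground truth.

Emulates one recording session of the 2AFC orientation change-detection
task: trial event timing for both task versions, an equal-variance SDT
observer producing choices and reaction times, a 1 kHz fixational eye
trace with planted main-sequence microsaccades and choice saccades, and
low-rate spike trains (baseline calibrated around 4.6 sp/s) with
event-locked gain kernels sampled as an inhomogeneous Poisson process by
thinning.

Every planted quantity is returned in a :class:`GroundTruth` record so
that detection and estimation stages can be scored against it.  All
generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm

from .session import EyeTrace, Session, SpikeTrain, TrialEvents, classify_outcome

__all__ = [
    "TaskParams",
    "ObserverParams",
    "EyeGenParams",
    "NeuronParams",
    "GroundTruth",
    "gen_trials",
    "gen_observer",
    "gen_eye",
    "gen_spikes",
    "gen_session",
    "draw_neurons",
    "saccade_locked_neurons",
]


@dataclass(frozen=True)
class TaskParams:
    """Trial-timing and stimulus-statistics parameters.

    Delay ranges (seconds) follow the task protocol: initial fixation
    0.4-0.6, gratings shown for 0.35, inter-grating delay 0.2-0.4, and in
    task version 2 an extra 0.35-0.55 target-to-go delay.  The protocol
    leaves the delay between grating-2 offset and choice-target onset as
    "variable"; 0.4-0.6 is used.  Change-present probability is 0.5 over
    4 amplitude levels.
    """

    n_trials: int = 600
    fix_delay: tuple[float, float] = (0.4, 0.6)
    grating_dur: float = 0.35
    inter_grating: tuple[float, float] = (0.2, 0.4)
    pre_targets_delay: tuple[float, float] = (0.4, 0.6)
    target_go_delay: tuple[float, float] = (0.35, 0.55)
    p_change: float = 0.5
    amplitudes: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0)
    p_side: float = 0.5
    iti: float = 1.0
    task_version: int = 1
    #: time reserved after the go cue for the response + target fixation
    response_slot: float = 0.9
    t_start: float = 0.5

    def __post_init__(self) -> None:
        for lo, hi in (self.fix_delay, self.inter_grating, self.pre_targets_delay,
                       self.target_go_delay):
            if not (0 < lo <= hi):
                raise ValueError("delay ranges must be positive with lo <= hi")
        if not (0.0 <= self.p_change <= 1.0 and 0.0 <= self.p_side <= 1.0):
            raise ValueError("probabilities must lie in [0,1]")
        if self.task_version not in (1, 2):
            raise ValueError("task_version must be 1 or 2")


@dataclass(frozen=True)
class ObserverParams:
    """Equal-variance SDT observer with a shifted-lognormal RT model.

    On change trials P(yes) = Phi(d'/2 - c) with the amplitude's d'; on
    change-absent trials P(yes) = Phi(-d'/2 - c) with the mean d' of the
    map.  Optional per-trial courses modulate both parameters
    (``dprime_scale_t`` multiplies every d'; ``criterion_t`` replaces c).

    RT = rt_shift + LogNormal(rt_mu, rt_sigma) + difficulty + outcome
    effects; the difficulty effect adds ``rt_difficulty`` seconds for the
    hardest amplitude, shrinking linearly to 0 for the easiest, and
    incorrect outcomes add ``rt_error``.  Medians land near 0.17-0.22 s.
    These RT constants are generator choices, not protocol values.
    """

    dprime: dict[float, float] = field(
        default_factory=lambda: {2.0: 0.5, 4.0: 1.0, 8.0: 1.8, 16.0: 2.5}
    )
    criterion: float = 0.3
    dprime_scale_t: np.ndarray | None = None
    criterion_t: np.ndarray | None = None
    rt_shift: float = 0.1
    rt_mu: float = float(np.log(0.08))
    rt_sigma: float = 0.35
    rt_difficulty: float = 0.02
    rt_error: float = 0.01
    rt_max: float = 0.55

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.dprime.values()):
            raise ValueError("d-prime entries must be >= 0")
        if self.rt_shift <= 0:
            raise ValueError("RT shift must be positive")

    @staticmethod
    def flat(dprime: float, criterion: float, amplitudes=(2.0, 4.0, 8.0, 16.0),
             **kw) -> "ObserverParams":
        """Observer with one d' at every amplitude."""
        return ObserverParams(dprime={a: dprime for a in amplitudes},
                              criterion=criterion, **kw)


@dataclass(frozen=True)
class EyeGenParams:
    """Fixational eye-trace generator parameters.

    Fixation jitter is low-pass Gaussian noise (white noise smoothed with
    a Gaussian kernel of ``lp_sigma_ms``, rescaled to ``noise_sd`` degrees
    RMS per axis).  Microsaccades follow a minimum-jerk profile with the
    main-sequence law peak velocity = ``main_seq_slope`` * amplitude
    (hence a fixed duration of 1.875/slope seconds); amplitudes are drawn
    uniformly from ``ms_amp_range``.  Rates are per second of eligible
    epoch time.
    """

    rate: float = 1000.0
    noise_sd: float = 0.02
    lp_sigma_ms: float = 15.0
    ms_rate_other: float = 0.5
    ms_rate_choice: float = 1.0
    ms_amp_range: tuple[float, float] = (0.1, 0.9)
    main_seq_slope: float = 100.0
    saccade_amp: float = 8.0
    saccade_peak_vel: float = 400.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive (the detector needs finite thresholds)")


@dataclass(frozen=True)
class NeuronParams:
    """One synthetic neuron: baseline rate plus event-locked gain kernels.

    Kernels:

    * pre-saccadic linear ramp from -150 ms to saccade onset;
    * post-saccadic exponential decay, time constant 100 ms, support
      [0, 200) ms;
    * optional choice-target-onset Gaussian bump (latency 150 ms, SD
      40 ms, support [0, 300) ms);
    * optional target-offset bump (latency 100 ms, SD 40 ms, support
      [0, 200) ms).

    ``pre_gain`` and ``post_gain`` are calibrated as the *mean* rate
    increment (sp/s) the kernel adds in the canonical pre-saccadic
    [-100, 0) and post-saccadic [0, 100) ms windows, so a planted gain is
    directly comparable to what the response decomposition measures; the
    kernel peaks are scaled internally.  Bump gains are peak rates.
    """

    neuron_id: str = "n0"
    baseline: float = 4.62
    pre_gain: float = 0.0
    post_gain: float = 0.0
    target_on_gain: float = 0.0
    target_off_gain: float = 0.0
    pre_ramp_s: float = 0.150
    post_tau_s: float = 0.100
    post_support_s: float = 0.200

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline rate must be positive")
        for g in (self.pre_gain, self.post_gain, self.target_on_gain, self.target_off_gain):
            if self.baseline + g < 0:
                raise ValueError("a negative gain drives the rate below zero")


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring recovery."""

    #: per completed trial: (trial_id, d', c, p_yes) used by the observer
    observer: list[tuple[int, float, float, float]] = field(default_factory=list)
    #: planted microsaccades: dicts with t_on, duration_s, amplitude_deg,
    #: peak_vel_dps, epoch, trial_id
    microsaccades: list[dict] = field(default_factory=list)
    #: planted choice (and return) saccades, same keys
    saccades: list[dict] = field(default_factory=list)
    #: per-neuron NeuronParams
    neurons: list[NeuronParams] = field(default_factory=list)


# ---------------------------------------------------------------------------
# trials & observer


def gen_trials(params: TaskParams, seed: int) -> list[TrialEvents]:
    """Generate trial event tables (without saccade/target-off times).

    Trials are laid out sequentially on the session clock with a fixed
    response slot after the go cue and the 1 s inter-trial interval.
    """
    rng = np.random.default_rng(seed)
    trials = []
    t = params.t_start
    for i in range(params.n_trials):
        t_fix = t
        t_g1 = t_fix + rng.uniform(*params.fix_delay)
        t_g1off = t_g1 + params.grating_dur
        t_g2 = t_g1off + rng.uniform(*params.inter_grating)
        t_g2off = t_g2 + params.grating_dur
        t_ton = t_g2off + rng.uniform(*params.pre_targets_delay)
        if params.task_version == 1:
            t_go = t_ton
        else:
            t_go = t_ton + rng.uniform(*params.target_go_delay)
        change = bool(rng.random() < params.p_change)
        amp = float(rng.choice(params.amplitudes)) if change else 0.0
        side = "left" if rng.random() < params.p_side else "right"
        trials.append(
            TrialEvents(
                trial_id=i,
                t_fix_on=t_fix,
                t_grating1_on=t_g1,
                t_grating1_off=t_g1off,
                t_grating2_on=t_g2,
                t_grating2_off=t_g2off,
                t_targets_on=t_ton,
                t_go=t_go,
                change_present=change,
                change_amplitude=amp,
                change_side=side,
                task_version=params.task_version,
            )
        )
        t = t_go + params.response_slot + params.iti
    return trials


def gen_observer(
    trials: list[TrialEvents],
    params: ObserverParams,
    seed: int,
    target_dwell: float = 0.2,
) -> tuple[list[TrialEvents], GroundTruth]:
    """Simulate the observer: choices, outcomes, RTs, saccade times.

    Returns completed copies of the trials (t_saccade = t_go + RT,
    t_targets_off = t_saccade + ``target_dwell``) plus the per-trial
    observer ground truth.
    """
    rng = np.random.default_rng(seed)
    mean_dp = float(np.mean(list(params.dprime.values())))
    amps = sorted(params.dprime)
    out = []
    gt = GroundTruth()
    for k, tr in enumerate(trials):
        scale = 1.0 if params.dprime_scale_t is None else float(params.dprime_scale_t[k])
        c = params.criterion if params.criterion_t is None else float(params.criterion_t[k])
        if tr.change_present:
            dp = params.dprime[tr.change_amplitude] * scale
            p_yes = float(norm.cdf(dp / 2.0 - c))
        else:
            dp = mean_dp * scale
            p_yes = float(norm.cdf(-dp / 2.0 - c))
        choice = "yes" if rng.random() < p_yes else "no"
        outcome = classify_outcome(tr.change_present, choice)

        rt = params.rt_shift + float(rng.lognormal(params.rt_mu, params.rt_sigma))
        if tr.change_present and params.rt_difficulty:
            # hardest (smallest) amplitude slowest, easiest fastest
            rank = amps.index(tr.change_amplitude)
            rt += params.rt_difficulty * (1.0 - rank / max(len(amps) - 1, 1))
        if outcome in ("miss", "false_alarm"):
            rt += params.rt_error
        rt = min(rt, params.rt_max)

        t_sacc = tr.t_go + rt
        out.append(
            replace(
                tr,
                t_saccade=t_sacc,
                t_targets_off=t_sacc + target_dwell,
                choice=choice,
                outcome=outcome,
                completed=True,
            )
        )
        gt.observer.append((tr.trial_id, dp, c, p_yes))
    return out, gt


# ---------------------------------------------------------------------------
# eye traces


def _minjerk_profile(n: int) -> np.ndarray:
    """Minimum-jerk displacement profile on (0, 1], peak velocity 1.875/D."""
    tau = np.arange(1, n + 1) / n
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _plant_movement(disp_x, disp_y, step_x, step_y, i0, n_prof, amp, ux, uy, profile):
    n = disp_x.size
    i1 = min(i0 + n_prof, n)
    seg = profile[: i1 - i0]
    disp_x[i0:i1] += amp * ux * seg
    disp_y[i0:i1] += amp * uy * seg
    if i1 < n:
        step_x[i1] += amp * ux
        step_y[i1] += amp * uy


def gen_eye(
    trials: list[TrialEvents],
    params: EyeGenParams = EyeGenParams(),
    seed: int = 0,
    duration: float | None = None,
) -> tuple[EyeTrace, GroundTruth]:
    """Generate the session eye trace with planted eye movements.

    Microsaccades are planted as Poisson events within each completed
    trial's 'other' epoch ([t_fix_on + 50 ms, t_targets_on - 50 ms)) and
    pre-go choice epoch ([t_targets_on + 50 ms, t_go - 50 ms), task
    version 2 only), directed roughly back toward the fixation point so
    gaze stays bounded.  Choice saccades jump to the chosen target at
    t_saccade and a return saccade restores fixation after target offset.
    Overlapping placements are rejected and redrawn (error after 100
    tries).
    """
    rng = np.random.default_rng(seed)
    rate = params.rate
    if duration is None:
        ends = [tr.t_targets_off or tr.t_go or tr.t_fix_on for tr in trials]
        duration = max(e for e in ends if e is not None) + 1.0
    n = int(round(duration * rate))

    # low-pass Gaussian fixation jitter, rescaled to noise_sd per axis
    sig = params.lp_sigma_ms * 1e-3 * rate
    nx = gaussian_filter1d(rng.standard_normal(n), sig)
    ny = gaussian_filter1d(rng.standard_normal(n), sig)
    nx *= params.noise_sd / nx.std()
    ny *= params.noise_sd / ny.std()

    disp_x = np.zeros(n)
    disp_y = np.zeros(n)
    step_x = np.zeros(n)
    step_y = np.zeros(n)
    gt = GroundTruth()

    ms_dur = 1.875 / params.main_seq_slope
    n_ms = max(int(round(ms_dur * rate)), 2)
    ms_profile = _minjerk_profile(n_ms)

    # running endpoint of planted displacements (noise excluded)
    cx = cy = 0.0
    occupied: list[tuple[float, float]] = []

    def _epoch_windows(tr):
        wins = []
        if tr.t_fix_on is not None and tr.t_targets_on is not None:
            wins.append(("other", tr.t_fix_on + 0.05, tr.t_targets_on - 0.05,
                         params.ms_rate_other))
        if (
            tr.t_targets_on is not None
            and tr.t_go is not None
            and tr.t_go - tr.t_targets_on > 0.15
        ):
            wins.append(("choice", tr.t_targets_on + 0.05, tr.t_go - 0.05,
                         params.ms_rate_choice))
        return wins

    events = []  # (t_on, amp, epoch, trial_id)
    for tr in trials:
        for epoch, lo, hi, ms_rate in _epoch_windows(tr):
            if hi - lo <= ms_dur:
                continue
            n_ev = rng.poisson(ms_rate * (hi - lo))
            for _ in range(n_ev):
                for attempt in range(100):
                    t_on = rng.uniform(lo, hi - ms_dur)
                    if all(not (t_on < b and t_on + ms_dur > a) for a, b in occupied):
                        break
                else:
                    raise RuntimeError("could not place a microsaccade in 100 attempts")
                occupied.append((t_on, t_on + ms_dur))
                amp = rng.uniform(*params.ms_amp_range)
                events.append((t_on, amp, epoch, tr.trial_id))
    events.sort()

    for t_on, amp, epoch, tid in events:
        # direction biased back toward the fixation point
        if cx == 0.0 and cy == 0.0:
            base_ang = rng.uniform(0, 2 * np.pi)
        else:
            base_ang = np.arctan2(-cy, -cx)
        ang = base_ang + rng.uniform(-np.pi / 3, np.pi / 3)
        ux, uy = np.cos(ang), np.sin(ang)
        i0 = int(round((t_on) * rate))
        _plant_movement(disp_x, disp_y, step_x, step_y, i0, n_ms, amp, ux, uy, ms_profile)
        cx += amp * ux
        cy += amp * uy
        gt.microsaccades.append(
            {
                "t_on": t_on,
                "duration_s": ms_dur,
                "amplitude_deg": amp,
                "peak_vel_dps": params.main_seq_slope * amp,
                "epoch": epoch,
                "trial_id": tid,
            }
        )

    # choice + return saccades for completed trials
    sac_dur = 1.875 * params.saccade_amp / params.saccade_peak_vel
    n_sac = max(int(round(sac_dur * rate)), 2)
    sac_profile = _minjerk_profile(n_sac)
    for tr in trials:
        if not tr.completed or tr.t_saccade is None:
            continue
        uy_sign = 1.0 if tr.choice == "yes" else -1.0
        i0 = int(round(tr.t_saccade * rate))
        _plant_movement(disp_x, disp_y, step_x, step_y, i0, n_sac,
                        params.saccade_amp, 0.0, uy_sign, sac_profile)
        gt.saccades.append(
            {
                "t_on": tr.t_saccade,
                "duration_s": sac_dur,
                "amplitude_deg": params.saccade_amp,
                "peak_vel_dps": params.saccade_peak_vel,
                "epoch": "choice",
                "trial_id": tr.trial_id,
            }
        )
        # return to fixation after the targets disappear
        t_ret = (tr.t_targets_off or tr.t_saccade + 0.2) + 0.25
        i0r = int(round(t_ret * rate))
        if i0r < n:
            _plant_movement(disp_x, disp_y, step_x, step_y, i0r, n_sac,
                            params.saccade_amp, 0.0, -uy_sign, sac_profile)

    x = nx + disp_x + np.cumsum(step_x)
    y = ny + disp_y + np.cumsum(step_y)
    eye = EyeTrace(t0=0.0, rate=rate, x=x, y=y)
    return eye, gt


# ---------------------------------------------------------------------------
# spike trains


def _kernel_rate(t: np.ndarray, events: np.ndarray, contrib) -> np.ndarray:
    """Sum a causal/anticausal kernel over its nearest event occurrence.

    ``contrib(dt)`` maps signed offsets (t - event) to sp/s with compact
    support; events are assumed separated by more than that support.
    """
    out = np.zeros(t.size)
    if events.size == 0:
        return out
    idx = np.searchsorted(events, t)
    prev = np.clip(idx - 1, 0, events.size - 1)
    nxt = np.clip(idx, 0, events.size - 1)
    for j in (prev, nxt):
        out += contrib(t - events[j])
    # when prev == nxt the kernel would be counted twice
    dup = prev == nxt
    out[dup] -= contrib(t[dup] - events[prev[dup]])
    return out


def _pre_peak(gain: float, ramp_s: float, window_s: float = 0.1) -> float:
    """Ramp peak whose mean over the pre-saccadic window equals ``gain``."""
    return gain / (1.0 - window_s / (2.0 * ramp_s))


def _post_peak(gain: float, tau_s: float, window_s: float = 0.1) -> float:
    """Decay peak whose mean over the post-saccadic window equals ``gain``."""
    return gain / (tau_s / window_s * (1.0 - np.exp(-window_s / tau_s)))


def rate_function(nparams: NeuronParams, trials: list[TrialEvents]):
    """Vectorized session-time firing-rate function for one neuron."""
    sacc = np.sort([tr.t_saccade for tr in trials if tr.completed and tr.t_saccade])
    ton = np.sort([tr.t_targets_on for tr in trials if tr.completed and tr.t_targets_on])
    toff = np.sort([tr.t_targets_off for tr in trials if tr.completed and tr.t_targets_off])

    ramp = nparams.pre_ramp_s
    tau = nparams.post_tau_s
    supp = nparams.post_support_s
    pre_peak = _pre_peak(nparams.pre_gain, ramp)
    post_peak = _post_peak(nparams.post_gain, tau)

    def presacc(dt):
        return np.where((dt >= -ramp) & (dt < 0), pre_peak * (1.0 + dt / ramp), 0.0)

    def postsacc(dt):
        return np.where((dt >= 0) & (dt < supp), post_peak * np.exp(-dt / tau), 0.0)

    def ton_bump(dt):
        return np.where(
            (dt >= 0) & (dt < 0.3),
            nparams.target_on_gain * np.exp(-0.5 * ((dt - 0.15) / 0.04) ** 2),
            0.0,
        )

    def toff_bump(dt):
        return np.where(
            (dt >= 0) & (dt < 0.2),
            nparams.target_off_gain * np.exp(-0.5 * ((dt - 0.10) / 0.04) ** 2),
            0.0,
        )

    def rate(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r = np.full(t.shape, nparams.baseline)
        if nparams.pre_gain:
            r += _kernel_rate(t, sacc, presacc)
        if nparams.post_gain:
            r += _kernel_rate(t, sacc, postsacc)
        if nparams.target_on_gain:
            r += _kernel_rate(t, ton, ton_bump)
        if nparams.target_off_gain:
            r += _kernel_rate(t, toff, toff_bump)
        return r

    return rate


def gen_spikes(
    trials: list[TrialEvents],
    nparams: NeuronParams,
    seed: int,
    span: tuple[float, float],
) -> tuple[SpikeTrain, "callable"]:
    """Sample one neuron's spike train by Poisson thinning.

    Homogeneous candidates at the kernel-summed maximum rate are thinned
    against the true rate function, which is returned alongside the train
    as ground truth.
    """
    rng = np.random.default_rng(seed)
    rate = rate_function(nparams, trials)
    rmax = (
        nparams.baseline
        + max(_pre_peak(nparams.pre_gain, nparams.pre_ramp_s), 0.0)
        + max(_post_peak(nparams.post_gain, nparams.post_tau_s), 0.0)
        + max(nparams.target_on_gain, 0.0)
        + max(nparams.target_off_gain, 0.0)
    )
    lo, hi = span
    n_cand = rng.poisson(rmax * (hi - lo))
    cand = np.sort(rng.uniform(lo, hi, size=n_cand))
    keep = rng.uniform(0.0, rmax, size=n_cand) < rate(cand)
    return SpikeTrain(neuron_id=nparams.neuron_id, times=cand[keep], span=span), rate


def draw_neurons(
    n: int,
    seed: int,
    pre_gain: float = 0.0,
    post_gain: float = 0.0,
    target_on_gain: float = 0.0,
    target_off_gain: float = 0.0,
    baseline_mean: float = 4.62,
    baseline_sd: float = 2.93,
) -> list[NeuronParams]:
    """Draw a population with gamma-distributed baselines (mean 4.62,
    SD 2.93 sp/s, floored at 0.5) and identical kernel gains."""
    rng = np.random.default_rng(seed)
    shape = (baseline_mean / baseline_sd) ** 2
    scale = baseline_sd**2 / baseline_mean
    bases = np.maximum(rng.gamma(shape, scale, size=n), 0.5)
    return [
        NeuronParams(
            neuron_id=f"n{i:03d}",
            baseline=float(b),
            pre_gain=pre_gain,
            post_gain=post_gain,
            target_on_gain=target_on_gain,
            target_off_gain=target_off_gain,
        )
        for i, b in enumerate(bases)
    ]


def saccade_locked_neurons(n: int = 59, seed: int = 0, frac_saccadic: float = 0.88,
                      sacc_gain: float = 8.0) -> list[NeuronParams]:
    """A population in which most neurons carry saccade-locked kernels
    (gains outcome-independent) and the rest are purely tonic."""
    rng = np.random.default_rng(seed)
    neurons = draw_neurons(n, seed=rng.integers(2**31))
    n_sacc = int(round(frac_saccadic * n))
    saccadic = rng.choice(n, size=n_sacc, replace=False)
    out = []
    for i, np_ in enumerate(neurons):
        if i in saccadic:
            g = float(rng.uniform(0.6, 1.4)) * sacc_gain
            np_ = replace(np_, pre_gain=g, post_gain=g)
        out.append(np_)
    return out


def gen_session(
    task: TaskParams = TaskParams(),
    observer: ObserverParams = ObserverParams(),
    eye_params: EyeGenParams = EyeGenParams(),
    neurons: list[NeuronParams] | None = None,
    seed: int = 0,
    subject: str = "synth",
) -> tuple[Session, GroundTruth]:
    """Generate a complete synthetic session with ground truth."""
    rng = np.random.default_rng(seed)
    s_trials, s_obs, s_eye, s_spk = rng.integers(2**31, size=4)
    trials = gen_trials(task, int(s_trials))
    trials, gt = gen_observer(trials, observer, int(s_obs))
    eye, eye_gt = gen_eye(trials, eye_params, int(s_eye))
    gt.microsaccades = eye_gt.microsaccades
    gt.saccades = eye_gt.saccades

    if neurons is None:
        neurons = draw_neurons(5, int(s_spk))
    span = eye.span
    spikes = []
    for i, np_ in enumerate(neurons):
        st, _ = gen_spikes(trials, np_, int(s_spk) + i + 1, span)
        spikes.append(st)
    gt.neurons = list(neurons)

    session = Session(
        trials=trials,
        spikes=spikes,
        eye=eye,
        metadata={
            "subject": subject,
            "task_version": task.task_version,
            "amplitude_levels": list(task.amplitudes),
            "eye_rate_hz": eye_params.rate,
            "seed": seed,
        },
    )
    session.validate()
    return session, gt
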