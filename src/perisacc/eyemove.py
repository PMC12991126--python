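"""Velocity-threshold (micro)saccade detection on 2D eye traces.

The detector follows the classical 2D-velocity approach: gaze velocity is
estimated with a centered moving-window finite difference, a per-trial
velocity threshold is set at a multiple (default 4) of the standard
deviation of radial speed over that trial's fixation epochs, and candidate
events are maximal above-threshold runs.  Events are then filtered by three
rules: amplitude must not exceed 1 deg, duration must be at least 6 ms, and
peak velocity must not exceed 100 deg/s (larger movements are choice
saccades, not microsaccades).

Epoch labels tie each event to the trial structure: *choice* events fall
between choice-target onset and offset, *other* events inside a trial but
before target onset, and everything else is *outside_trial*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateThresholdError, NoSaccadeError
from .session import EyeTrace, TrialEvents

__all__ = [
    "DetectionParams",
    "EyeEvent",
    "VelocityTrace",
    "compute_velocity",
    "estimate_threshold",
    "trial_thresholds",
    "detect_microsaccades",
    "label_epoch",
    "detect_choice_saccade",
    "events_frame",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable constants of the microsaccade detector.

    lambda_sd : threshold multiplier on the radial-speed SD (default 4).
    v_max : upper peak-velocity bound, deg/s (default 100).
    amp_max : upper amplitude bound, degrees (default 1).
    dur_min : minimum event duration, ms (default 6).
    smooth_span : samples in the centered finite-difference window (odd,
        default 5).
    merge_gap : runs separated by less than this many ms are fused
        (default 20; shorter than the physiologic inter-saccade interval).
    floor_dps : lower bound on the threshold, deg/s (default 6).  On very
        quiet traces the SD-multiple threshold sinks into the drift-noise
        bulk, where slow excursions masquerade as events; the floor keeps
        the detector out of that regime (and is the remedy the degenerate
        zero-SD error points at).
    robust_sd : if True use a median-based (MAD) scale estimate instead of
        the plain sample SD.  Off by default; the plain SD is the primary
        definition.
    """

    lambda_sd: float = 4.0
    v_max: float = 100.0
    amp_max: float = 1.0
    dur_min: float = 6.0
    smooth_span: int = 5
    merge_gap: float = 20.0
    floor_dps: float = 6.0
    robust_sd: bool = False

    def __post_init__(self) -> None:
        if self.lambda_sd <= 0 or self.v_max <= 0 or self.dur_min <= 0:
            raise ValueError("lambda_sd, v_max and dur_min must be positive")
        if self.smooth_span < 3 or self.smooth_span % 2 == 0:
            raise ValueError("smooth_span must be odd and >= 3")


@dataclass
class EyeEvent:
    """One detected (micro)saccade."""

    t_on: float
    t_off: float
    duration_ms: float
    amplitude_deg: float
    peak_velocity_dps: float
    trial_id: int | None = None
    epoch: str = "outside_trial"
    threshold_dps: float = float("nan")


@dataclass
class VelocityTrace:
    """Gaze velocity on the same timebase as its source eye trace."""

    t0: float
    rate: float
    vx: np.ndarray
    vy: np.ndarray
    v_radial: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.vx.size) / self.rate


def compute_velocity(eye: EyeTrace, smooth_span: int = 5) -> VelocityTrace:
    """Centered moving-window finite-difference velocity estimate.

    For window half-width ``k`` the estimate at sample ``n`` is

        v_n = sum_{j=1..k} (x_{n+j} - x_{n-j}) / (2 * sum_{j=1..k} j) * rate

    which at the default span of 5 is the classical 5-point scheme.  The
    first/last ``k`` samples, blink samples, and samples within ``k`` of a
    blink are NaN-masked.
    """
    if smooth_span < 3 or smooth_span % 2 == 0:
        raise ValueError("smooth_span must be odd and >= 3")
    if eye.n < smooth_span:
        raise ValueError(f"trace of {eye.n} samples shorter than smooth_span {smooth_span}")
    k = smooth_span // 2
    # correlation kernel: +1 at leads, -1 at lags, 0 at center
    w = np.zeros(smooth_span)
    w[k + 1 :] = 1.0
    w[:k] = -1.0
    norm = eye.rate / (2.0 * (k * (k + 1) / 2.0))
    x = np.where(eye.blink_mask, 0.0, eye.x)
    y = np.where(eye.blink_mask, 0.0, eye.y)
    vx = np.convolve(x, w[::-1], mode="same") * norm
    vy = np.convolve(y, w[::-1], mode="same") * norm

    bad = np.zeros(eye.n, dtype=bool)
    bad[:k] = True
    bad[-k:] = True
    if eye.blink_mask.any():
        dil = np.convolve(eye.blink_mask.astype(float), np.ones(smooth_span), mode="same") > 0
        bad |= dil
    vx[bad] = np.nan
    vy[bad] = np.nan
    vr = np.hypot(vx, vy)
    return VelocityTrace(t0=eye.t0, rate=eye.rate, vx=vx, vy=vy, v_radial=vr)


def estimate_threshold(
    v_radial: np.ndarray, lambda_sd: float = 4.0, robust: bool = False
) -> float:
    """Velocity threshold: ``lambda_sd`` times the SD of radial speed.

    ``v_radial`` is the pooled window of valid radial-speed samples (NaNs
    are ignored).  With ``robust=True``, 1.4826*MAD replaces the SD.

    Raises
    ------
    ValueError if fewer than 50 valid samples are supplied.
    DegenerateThresholdError if the SD is zero (noiseless trace); the
    caller should set a velocity floor.
    """
    v = np.asarray(v_radial, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 50:
        raise ValueError(f"threshold window has only {v.size} valid samples (need >= 50)")
    if robust:
        sd = 1.4826 * np.median(np.abs(v - np.median(v)))
    else:
        sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise DegenerateThresholdError(
            "radial-speed SD is zero; add measurement noise or set a threshold floor"
        )
    return float(lambda_sd * sd)


def trial_thresholds(
    vel: VelocityTrace,
    trials: list[TrialEvents],
    params: DetectionParams = DetectionParams(),
) -> dict[int, float]:
    """Per-completed-trial detection thresholds.

    The threshold window runs from 300 ms before grating-1 onset to the go
    cue (fixation-point offset) of each completed trial.  Trials whose
    window lacks 50 valid samples are skipped.
    """
    out: dict[int, float] = {}
    n = vel.v_radial.size
    for tr in trials:
        if not tr.completed or tr.t_grating1_on is None or tr.t_go is None:
            continue
        i0 = max(0, int(np.floor((tr.t_grating1_on - 0.3 - vel.t0) * vel.rate)))
        i1 = min(n, int(np.floor((tr.t_go - vel.t0) * vel.rate)))
        if i1 <= i0:
            continue
        try:
            thr = estimate_threshold(
                vel.v_radial[i0:i1], params.lambda_sd, robust=params.robust_sd
            )
        except ValueError:
            continue
        out[tr.trial_id] = max(thr, params.floor_dps)
    return out


def label_epoch(t_on: float, trial: TrialEvents | None) -> str:
    """Epoch of an eye event: choice, other, or outside_trial."""
    if trial is None:
        return "outside_trial"
    if (
        trial.t_targets_on is not None
        and trial.t_targets_off is not None
        and trial.t_targets_on <= t_on < trial.t_targets_off
    ):
        return "choice"
    if trial.t_fix_on is not None and trial.t_targets_on is not None:
        if trial.t_fix_on <= t_on < trial.t_targets_on:
            return "other"
    return "outside_trial"


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open (start, stop)."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_microsaccades(
    eye: EyeTrace,
    trials: list[TrialEvents],
    params: DetectionParams = DetectionParams(),
    vel: VelocityTrace | None = None,
) -> list[EyeEvent]:
    """Detect microsaccades over the whole session.

    Candidate events are maximal runs of samples whose radial speed exceeds
    the threshold of the trial they fall in (the session-median threshold
    outside completed trials).  Runs separated by less than ``merge_gap``
    are fused, then the three filters (duration >= dur_min, amplitude <=
    amp_max, peak velocity <= v_max) are applied.  Returned sorted by onset
    with trial and epoch labels attached; zero events is a valid result.
    """
    if vel is None:
        vel = compute_velocity(eye, params.smooth_span)
    thr_by_trial = trial_thresholds(vel, trials, params)
    if not thr_by_trial:
        raise DegenerateThresholdError("no trial yielded a valid velocity threshold")
    default_thr = float(np.median(list(thr_by_trial.values())))

    # threshold per sample: trial threshold inside [t_fix_on, t_targets_off)
    thr = np.full(eye.n, default_thr)
    tstarts, tstops, tids = [], [], []
    for tr in trials:
        if tr.trial_id not in thr_by_trial or tr.t_fix_on is None:
            continue
        stop = tr.t_targets_off if tr.t_targets_off is not None else tr.t_go
        if stop is None:
            continue
        i0 = max(0, int(np.floor((tr.t_fix_on - eye.t0) * eye.rate)))
        i1 = min(eye.n, int(np.floor((stop - eye.t0) * eye.rate)))
        thr[i0:i1] = thr_by_trial[tr.trial_id]
        tstarts.append(tr.t_fix_on)
        tstops.append(stop)
        tids.append(tr.trial_id)

    with np.errstate(invalid="ignore"):
        above = vel.v_radial > thr
    if not above.any():
        return []
    runs = _runs(above)

    # fuse runs separated by less than merge_gap
    gap_samples = params.merge_gap * 1e-3 * eye.rate
    merged: list[list[int]] = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < gap_samples:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    # trial lookup by onset time
    order = np.argsort(tstarts) if tstarts else np.array([], dtype=int)
    tstarts_a = np.asarray(tstarts, dtype=float)[order] if tstarts else np.array([])
    tstops_a = np.asarray(tstops, dtype=float)[order] if tstarts else np.array([])
    tids_a = np.asarray(tids)[order] if tstarts else np.array([])
    trial_by_id = {tr.trial_id: tr for tr in trials}

    events: list[EyeEvent] = []
    for a, b in merged:
        dur_ms = (b - a) / eye.rate * 1e3
        if dur_ms < params.dur_min:
            continue
        seg_v = vel.v_radial[a:b]
        peak = float(np.nanmax(seg_v)) if np.isfinite(seg_v).any() else float("nan")
        if not np.isfinite(peak) or peak > params.v_max:
            continue
        xs, ys = eye.x[a:b], eye.y[a:b]
        amp = float(np.hypot(np.nanmax(xs) - np.nanmin(xs), np.nanmax(ys) - np.nanmin(ys)))
        if amp > params.amp_max:
            continue
        t_on = eye.t0 + a / eye.rate
        t_off = eye.t0 + b / eye.rate
        trial = None
        if tstarts_a.size:
            j = int(np.searchsorted(tstarts_a, t_on, side="right")) - 1
            if j >= 0 and t_on < tstops_a[j]:
                trial = trial_by_id[tids_a[j]]
        events.append(
            EyeEvent(
                t_on=t_on,
                t_off=t_off,
                duration_ms=dur_ms,
                amplitude_deg=amp,
                peak_velocity_dps=peak,
                trial_id=None if trial is None else trial.trial_id,
                epoch=label_epoch(t_on, trial),
                threshold_dps=float(thr[a]),
            )
        )
    events.sort(key=lambda e: e.t_on)
    return events


def detect_choice_saccade(
    eye: EyeTrace,
    t_go: float,
    onset_vel: float = 30.0,
    sustain_samples: int = 5,
    search_s: float = 1.0,
    min_amplitude: float = 1.0,
    vel: VelocityTrace | None = None,
) -> float:
    """Onset of the choice saccade: first sustained velocity crossing after
    the go cue.

    The onset is the first time after ``t_go`` at which radial speed
    crosses ``onset_vel`` and stays above it for at least
    ``sustain_samples`` samples, with the ensuing movement displacing gaze
    by more than ``min_amplitude`` degrees.

    Raises :class:`NoSaccadeError` if no such crossing occurs within
    ``search_s`` seconds of the go cue.
    """
    if vel is None:
        vel = compute_velocity(eye)
    i0 = max(0, int(np.ceil((t_go - eye.t0) * eye.rate)))
    i1 = min(eye.n, int(np.ceil((t_go + search_s - eye.t0) * eye.rate)))
    if i1 <= i0:
        raise NoSaccadeError(f"no eye data after go cue at {t_go} s")
    with np.errstate(invalid="ignore"):
        above = vel.v_radial[i0:i1] > onset_vel
    if above.any():
        for a, b in _runs(above):
            if b - a < sustain_samples:
                continue
            # displacement over the movement (run extended to speed minimum)
            stop = min(i0 + b + sustain_samples, eye.n)
            xs = eye.x[i0 + a : stop]
            ys = eye.y[i0 + a : stop]
            amp = float(
                np.hypot(np.nanmax(xs) - np.nanmin(xs), np.nanmax(ys) - np.nanmin(ys))
            )
            if amp > min_amplitude:
                return eye.t0 + (i0 + a) / eye.rate
    raise NoSaccadeError(f"no choice saccade within {search_s} s of go cue at {t_go} s")


def events_frame(events: list[EyeEvent]) -> pd.DataFrame:
    """Detected events as a tidy table (the events.csv schema)."""
    return pd.DataFrame(
        {
            "trial_id": [e.trial_id if e.trial_id is not None else -1 for e in events],
            "t_on": [e.t_on for e in events],
            "t_off": [e.t_off for e in events],
            "duration_ms": [e.duration_ms for e in events],
            "amplitude_deg": [e.amplitude_deg for e in events],
            "peak_vel_dps": [e.peak_velocity_dps for e in events],
            "epoch": [e.epoch for e in events],
        }
    )
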