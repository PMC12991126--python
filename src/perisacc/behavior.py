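"""Signal-detection-theoretic quantification of 2AFC change-detection
behavior.

Sensitivity and bias follow the equal-variance Gaussian model:

    d' = invPhi(HR) - invPhi(FAR)
    c  = -0.5 * (invPhi(HR) + invPhi(FAR))

where invPhi is the standard normal inverse CDF, HR the hit rate over
change-present trials and FAR the false-alarm rate over change-absent
trials.  c > 0 biases the observer toward reporting "no change".

Rates of exactly 0 or 1 are edge-corrected to 1/(2n) and 1 - 1/(2n)
before the quantile transform (the ``corrected`` flag records this).

The sliding-window estimator recomputes (d', c) in windows of 50 trials
stepped by 1 trial, assigns each trial the estimate of the window centered
on it (edge trials take the nearest window), and median-splits trials into
low/high perceptual-state groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DegenerateSplitError, UndefinedRateError
from .session import TrialEvents

__all__ = [
    "OutcomeCounts",
    "SDTMetrics",
    "SlidingState",
    "count_outcomes",
    "rates",
    "dprime_criterion",
    "psychometric",
    "sliding_sdt",
    "median_split",
]


@dataclass(frozen=True)
class OutcomeCounts:
    n_hit: int = 0
    n_miss: int = 0
    n_cr: int = 0
    n_fa: int = 0

    @property
    def n_signal(self) -> int:
        return self.n_hit + self.n_miss

    @property
    def n_noise(self) -> int:
        return self.n_cr + self.n_fa

    @property
    def n(self) -> int:
        return self.n_signal + self.n_noise


@dataclass(frozen=True)
class SDTMetrics:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    corrected: bool = False
    n_signal: int = 0
    n_noise: int = 0


def count_outcomes(trials: list[TrialEvents]) -> OutcomeCounts:
    """Tally the four outcomes over completed trials."""
    tally = {"hit": 0, "miss": 0, "correct_reject": 0, "false_alarm": 0}
    for tr in trials:
        if tr.completed:
            tally[tr.outcome] += 1
    return OutcomeCounts(
        n_hit=tally["hit"],
        n_miss=tally["miss"],
        n_cr=tally["correct_reject"],
        n_fa=tally["false_alarm"],
    )


def rates(counts: OutcomeCounts) -> tuple[float, float]:
    """(hit rate, false-alarm rate) from outcome counts.

    Raises :class:`UndefinedRateError` when either trial class is empty.
    """
    if counts.n_signal == 0 or counts.n_noise == 0:
        raise UndefinedRateError(
            f"undefined rate: {counts.n_signal} change-present and "
            f"{counts.n_noise} change-absent trials"
        )
    return counts.n_hit / counts.n_signal, counts.n_fa / counts.n_noise


def _edge_correct(rate: float, n: int) -> tuple[float, bool]:
    if rate == 0.0:
        if n < 1:
            raise UndefinedRateError("edge correction needs at least 1 trial")
        return 1.0 / (2 * n), True
    if rate == 1.0:
        if n < 1:
            raise UndefinedRateError("edge correction needs at least 1 trial")
        return 1.0 - 1.0 / (2 * n), True
    return rate, False


def dprime_criterion(
    hit_rate: float, fa_rate: float, n_signal: int = 0, n_noise: int = 0
) -> SDTMetrics:
    """Edge-corrected sensitivity and criterion from raw rates.

    ``n_signal``/``n_noise`` are the class sizes used for the 1/(2n) edge
    correction when a rate is exactly 0 or 1.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError(f"rates must lie in [0,1], got ({hit_rate}, {fa_rate})")
    hr, c1 = _edge_correct(hit_rate, n_signal)
    fr, c2 = _edge_correct(fa_rate, n_noise)
    zh = norm.ppf(hr)
    zf = norm.ppf(fr)
    return SDTMetrics(
        hit_rate=hr,
        fa_rate=fr,
        dprime=float(zh - zf),
        criterion=float(-0.5 * (zh + zf)),
        corrected=c1 or c2,
        n_signal=n_signal,
        n_noise=n_noise,
    )


def sdt_from_counts(counts: OutcomeCounts) -> SDTMetrics:
    """Convenience: counts -> rates -> edge-corrected (d', c)."""
    hr, fr = rates(counts)
    return dprime_criterion(hr, fr, counts.n_signal, counts.n_noise)


def psychometric(trials: list[TrialEvents]) -> dict[float, SDTMetrics]:
    """Per-amplitude psychometric points.

    Each change amplitude contributes a hit rate; change-absent trials
    carry no amplitude, so every point shares the session-wide false-alarm
    rate.  Amplitude levels with zero trials are omitted.
    """
    done = [t for t in trials if t.completed]
    noise = [t for t in done if not t.change_present]
    n_noise = len(noise)
    if n_noise == 0:
        raise UndefinedRateError("no change-absent trials: FA rate undefined")
    n_fa = sum(t.outcome == "false_alarm" for t in noise)
    fa_rate = n_fa / n_noise

    out: dict[float, SDTMetrics] = {}
    amps = sorted({t.change_amplitude for t in done if t.change_present})
    for amp in amps:
        sub = [t for t in done if t.change_present and t.change_amplitude == amp]
        n_sig = len(sub)
        hr = sum(t.outcome == "hit" for t in sub) / n_sig
        out[amp] = dprime_criterion(hr, fa_rate, n_sig, n_noise)
    return out


@dataclass
class SlidingState:
    """Per-trial perceptual-state estimates from a sliding SDT window."""

    window: int
    step: int
    #: one estimate per window position (n_completed - window + 1 of them)
    window_metrics: list[SDTMetrics]
    #: per-trial estimates (window centered on the trial, clipped at edges)
    dprime_t: np.ndarray
    criterion_t: np.ndarray
    #: per-trial {"low","high"} labels from median splits of the estimates
    #: (None when the estimates are constant and no split exists)
    dprime_label: list[str] | None
    criterion_label: list[str] | None
    trial_ids: list[int]


def _window_metrics(outcomes: list[str], window: int) -> list[SDTMetrics]:
    mets = []
    for start in range(0, len(outcomes) - window + 1):
        sub = outcomes[start : start + window]
        cnt = OutcomeCounts(
            n_hit=sub.count("hit"),
            n_miss=sub.count("miss"),
            n_cr=sub.count("correct_reject"),
            n_fa=sub.count("false_alarm"),
        )
        # a window may lack one trial class entirely; substitute an
        # uninformative 0.5 for the missing rate and flag the estimate
        if cnt.n_signal == 0 or cnt.n_noise == 0:
            hr = 0.5 if cnt.n_signal == 0 else cnt.n_hit / cnt.n_signal
            fr = 0.5 if cnt.n_noise == 0 else cnt.n_fa / cnt.n_noise
            m = dprime_criterion(hr, fr, max(cnt.n_signal, 1), max(cnt.n_noise, 1))
            m = SDTMetrics(
                hit_rate=m.hit_rate,
                fa_rate=m.fa_rate,
                dprime=m.dprime,
                criterion=m.criterion,
                corrected=True,
                n_signal=cnt.n_signal,
                n_noise=cnt.n_noise,
            )
        else:
            m = sdt_from_counts(cnt)
        mets.append(m)
    return mets


def sliding_sdt(
    trials: list[TrialEvents], window: int = 50, step: int = 1
) -> SlidingState:
    """Sliding-window perceptual-state estimate (window of 50 trials,
    stepped by 1 trial), with per-trial low/high median-split labels for
    both d' and criterion."""
    done = [t for t in trials if t.completed]
    n = len(done)
    if n < window:
        raise ValueError(f"{n} completed trials < window {window}")
    if step != 1:
        raise NotImplementedError("only step=1 windows are supported")
    mets = _window_metrics([t.outcome for t in done], window)
    n_win = len(mets)
    # trial i takes the window centered on it; edge trials take the nearest
    centers = np.arange(n) - (window - 1) // 2
    idx = np.clip(centers, 0, n_win - 1)
    dp = np.array([mets[j].dprime for j in idx])
    cr = np.array([mets[j].criterion for j in idx])
    def _labels(v):
        try:
            return median_split(v)
        except DegenerateSplitError:
            # constant estimates (e.g. window == n): no split exists
            return None

    return SlidingState(
        window=window,
        step=step,
        window_metrics=mets,
        dprime_t=dp,
        criterion_t=cr,
        dprime_label=_labels(dp),
        criterion_label=_labels(cr),
        trial_ids=[t.trial_id for t in done],
    )


def median_split(values) -> list[str]:
    """Label each value "low" or "high" relative to the median.

    Values strictly below the median are low, strictly above are high;
    values equal to the median alternate low/high so the groups differ in
    size by at most one.  All-identical input is a degenerate split.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or not np.isfinite(v).all():
        raise ValueError("median split needs >= 2 finite values")
    if np.all(v == v[0]):
        raise DegenerateSplitError("all values identical; no median split exists")
    med = float(np.median(v))
    labels = [""] * v.size
    n_low = n_high = 0
    ties = []
    for i, x in enumerate(v):
        if x < med:
            labels[i] = "low"
            n_low += 1
        elif x > med:
            labels[i] = "high"
            n_high += 1
        else:
            ties.append(i)
    for i in ties:
        if n_low <= n_high:
            labels[i] = "low"
            n_low += 1
        else:
            labels[i] = "high"
            n_high += 1
    return labels
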