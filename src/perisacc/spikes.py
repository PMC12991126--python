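"""Event-aligned firing-rate analysis: epoch rates, 20 ms-binned PETHs,
baseline z-scoring, population averages, and the pre/post-saccadic
decomposition.

Standardization follows the baseline-distribution convention: each
neuron's per-trial firing rate in a 500 ms window at the start of the
initial fixation period is collected across all completed trials; the mean
and SD of that distribution convert any epoch rate into a z-score ("number
of SDs above baseline").  Rates, not counts, are standardized so that
windows of different lengths remain comparable.

Analysis windows (ms, relative to their alignment event):

====================  ==================
epoch rate windows
====================  ==================
grating1 / grating2    [0, 350)
targets_on             [0, 300)
saccade                [-100, +100)
targets_off            [-100, +100)
====================  ==================

PETH windows: fixation [200, 700) after fixation-point onset; gratings
[-200, 500); choice-target onset [-200, 300); saccade [-300, 200);
choice-target offset [-300, 300); all binned at 20 ms.

The saccadic decomposition splits the peri-saccadic response into a
pre-saccadic [-100, 0) and post-saccadic [0, 100) rate and subtracts a
pre-choice baseline measured saccade-aligned at [-350, -250) (task
version 1) or [-650, -550) (task version 2, whose choice targets appear
earlier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateBaselineError
from .session import SpikeTrain, TrialEvents, align_events

__all__ = [
    "EPOCH_WINDOWS_MS",
    "PETH_WINDOWS_MS",
    "BaselineStats",
    "PETH",
    "baseline_stats",
    "epoch_rates",
    "peth",
    "zscore",
    "population_peth",
    "SaccadicDecomposition",
    "saccadic_decomposition",
]

#: epoch -> (alignment event, window in ms relative to the event)
EPOCH_WINDOWS_MS: dict[str, tuple[str, tuple[float, float]]] = {
    "grating1": ("t_grating1_on", (0.0, 350.0)),
    "grating2": ("t_grating2_on", (0.0, 350.0)),
    "targets_on": ("t_targets_on", (0.0, 300.0)),
    "saccade": ("t_saccade", (-100.0, 100.0)),
    "targets_off": ("t_targets_off", (-100.0, 100.0)),
}

#: PETH alignment -> (event, window in ms)
PETH_WINDOWS_MS: dict[str, tuple[str, tuple[float, float]]] = {
    "fixation": ("t_fix_on", (200.0, 700.0)),
    "grating1": ("t_grating1_on", (-200.0, 500.0)),
    "grating2": ("t_grating2_on", (-200.0, 500.0)),
    "targets_on": ("t_targets_on", (-200.0, 300.0)),
    "saccade": ("t_saccade", (-300.0, 200.0)),
    "targets_off": ("t_targets_off", (-300.0, 300.0)),
}

BASELINE_WINDOW_S = 0.5


@dataclass(frozen=True)
class BaselineStats:
    """Across-trial distribution of fixation-period firing rates."""

    mean_rate: float
    sd_rate: float
    n_trials: int
    window_s: float = BASELINE_WINDOW_S


def baseline_stats(
    spikes: SpikeTrain, trials: list[TrialEvents], require_sd: bool = False
) -> BaselineStats:
    """Baseline mean/SD of one neuron's fixation firing rates.

    The window is [0, 500) ms after fixation-point onset on every completed
    trial; if the fixation period ends (grating 1 appears) sooner, the
    window is truncated there and the rate rescaled by the actual length.

    With ``require_sd=True`` a zero SD raises
    :class:`DegenerateBaselineError` immediately (it always does at
    z-scoring time).
    """
    rates = []
    for tr in trials:
        if not tr.completed or tr.t_fix_on is None:
            continue
        end = tr.t_fix_on + BASELINE_WINDOW_S
        if tr.t_grating1_on is not None:
            end = min(end, tr.t_grating1_on)
        length = end - tr.t_fix_on
        if length <= 0:
            continue
        (rel,) = align_events(spikes.times, [tr.t_fix_on], (0.0, length))
        rates.append(rel.size / length)
    if len(rates) < 2:
        raise DataError(f"neuron {spikes.neuron_id}: < 2 completed trials for baseline")
    arr = np.asarray(rates)
    sd = float(arr.std(ddof=1))
    if require_sd and sd == 0.0:
        raise DegenerateBaselineError(
            f"neuron {spikes.neuron_id}: zero baseline SD; z-scoring impossible"
        )
    return BaselineStats(mean_rate=float(arr.mean()), sd_rate=sd, n_trials=arr.size)


def zscore(rate, baseline: BaselineStats):
    """Standardize a rate (sp/s) against the baseline distribution."""
    if baseline.sd_rate == 0.0:
        raise DegenerateBaselineError("zero baseline SD; z-scoring impossible")
    return (np.asarray(rate, dtype=float) - baseline.mean_rate) / baseline.sd_rate


def epoch_rates(
    spikes: SpikeTrain, trials: list[TrialEvents], epoch: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial firing rates (sp/s) in one epoch's window.

    Returns (trial_ids, rates) over completed trials that carry the
    epoch's alignment event.
    """
    event, (lo_ms, hi_ms) = EPOCH_WINDOWS_MS[epoch]
    ids, evs = [], []
    for tr in trials:
        if not tr.completed:
            continue
        t = getattr(tr, event)
        if t is None:
            raise DataError(f"trial {tr.trial_id}: completed trial missing {event}")
        ids.append(tr.trial_id)
        evs.append(t)
    window = (lo_ms * 1e-3, hi_ms * 1e-3)
    length = window[1] - window[0]
    aligned = align_events(spikes.times, evs, window)
    rates = np.array([a.size / length for a in aligned])
    return np.asarray(ids), rates


@dataclass
class PETH:
    """Binned event-aligned firing for one neuron.

    ``counts`` is (n_trials, n_bins) spike counts in half-open 20 ms bins;
    ``mean_rate`` the across-trial mean rate per bin (sp/s); ``z`` that
    rate standardized against the neuron's baseline distribution (absent
    until :func:`peth` is given baseline stats).
    """

    alignment: str
    bin_edges_ms: np.ndarray
    counts: np.ndarray
    neuron_id: str
    baseline: BaselineStats | None = None

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])

    @property
    def mean_rate(self) -> np.ndarray:
        return self.counts.mean(axis=0) / (self.bin_width_ms * 1e-3)

    @property
    def z(self) -> np.ndarray:
        if self.baseline is None:
            raise DegenerateBaselineError("PETH has no baseline stats attached")
        return zscore(self.mean_rate, self.baseline)


def peth(
    spikes: SpikeTrain,
    event_times,
    window_ms: tuple[float, float],
    bin_ms: float = 20.0,
    baseline: BaselineStats | None = None,
    alignment: str = "event",
    neuron_id: str | None = None,
) -> PETH:
    """Peri-event time histogram in uniform half-open bins.

    ``window_ms`` must be an integer multiple of ``bin_ms`` long.
    """
    lo, hi = window_ms
    n_bins_f = (hi - lo) / bin_ms
    n_bins = round(n_bins_f)
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(f"window {window_ms} ms not divisible by bin {bin_ms} ms")
    edges = lo + bin_ms * np.arange(n_bins + 1)
    aligned = align_events(spikes.times, event_times, (lo * 1e-3, hi * 1e-3))
    counts = np.empty((len(aligned), n_bins), dtype=int)
    for i, rel in enumerate(aligned):
        # half-open [edge_b, edge_{b+1}) bins via floor indexing
        idx = np.floor((rel * 1e3 - lo) / bin_ms).astype(int)
        counts[i] = np.bincount(idx, minlength=n_bins)[:n_bins]
    return PETH(
        alignment=alignment,
        bin_edges_ms=edges,
        counts=counts,
        neuron_id=neuron_id or spikes.neuron_id,
        baseline=baseline,
    )


def population_peth(peths: list[PETH]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SEM across neurons of z-scored PETHs.

    All PETHs must share one bin grid; SEM is SD over neurons divided by
    sqrt(n_neurons).
    """
    if len(peths) < 2:
        raise ValueError("population PETH needs >= 2 neurons")
    edges = peths[0].bin_edges_ms
    for p in peths[1:]:
        if p.bin_edges_ms.shape != edges.shape or not np.allclose(p.bin_edges_ms, edges):
            raise ValueError("PETH bin grids differ across neurons")
    zmat = np.vstack([p.z for p in peths])
    mean = zmat.mean(axis=0)
    sem = zmat.std(axis=0, ddof=1) / np.sqrt(zmat.shape[0])
    return mean, sem


#: saccade-aligned pre-choice baseline window (ms) per task version
PRECHOICE_BASELINE_MS = {1: (-350.0, -250.0), 2: (-650.0, -550.0)}


@dataclass
class SaccadicDecomposition:
    """Pre/post-saccadic response split for one neuron.

    Per-trial rates are retained for paired significance testing; the
    deltas are baseline-subtracted means (sp/s).
    """

    pre_rates: np.ndarray  # [-100, 0) ms, per trial
    post_rates: np.ndarray  # [0, 100) ms, per trial
    baseline_rates: np.ndarray  # pre-choice window, per trial
    trial_ids: np.ndarray

    @property
    def pre_rate(self) -> float:
        return float(self.pre_rates.mean())

    @property
    def post_rate(self) -> float:
        return float(self.post_rates.mean())

    @property
    def prechoice_baseline(self) -> float:
        return float(self.baseline_rates.mean())

    @property
    def pre_delta(self) -> float:
        return self.pre_rate - self.prechoice_baseline

    @property
    def post_delta(self) -> float:
        return self.post_rate - self.prechoice_baseline


def saccadic_decomposition(
    spikes: SpikeTrain, trials: list[TrialEvents], task_version: int | None = None
) -> SaccadicDecomposition:
    """Split the peri-saccadic response into pre/post components.

    Rates are computed saccade-aligned in [-100, 0) and [0, 100) ms, and a
    pre-choice baseline in the task-version-specific window just before
    choice-target onset.
    """
    ids, evs = [], []
    for tr in trials:
        if not tr.completed:
            continue
        if tr.t_saccade is None:
            raise DataError(f"trial {tr.trial_id}: completed trial missing t_saccade")
        ids.append(tr.trial_id)
        evs.append(tr.t_saccade)
        if task_version is None:
            task_version = tr.task_version
    if not ids:
        raise DataError("no completed trials for saccadic decomposition")
    blo, bhi = PRECHOICE_BASELINE_MS[task_version]

    def _rates(win_ms):
        lo, hi = win_ms
        length = (hi - lo) * 1e-3
        aligned = align_events(spikes.times, evs, (lo * 1e-3, hi * 1e-3))
        return np.array([a.size / length for a in aligned])

    return SaccadicDecomposition(
        pre_rates=_rates((-100.0, 0.0)),
        post_rates=_rates((0.0, 100.0)),
        baseline_rates=_rates((blo, bhi)),
        trial_ids=np.asarray(ids),
    )


def peth_frame(peths: list[PETH]) -> pd.DataFrame:
    """Long-form PETH table (the peth.csv schema)."""
    rows = []
    for p in peths:
        z = p.z if p.baseline is not None else np.full(p.mean_rate.size, np.nan)
        for b0, mr, zz in zip(p.bin_edges_ms[:-1], p.mean_rate, z):
            rows.append(
                {
                    "neuron_id": p.neuron_id,
                    "alignment": p.alignment,
                    "bin_start_ms": b0,
                    "mean_rate": mr,
                    "z": zz,
                }
            )
    return pd.DataFrame(rows, columns=["neuron_id", "alignment", "bin_start_ms", "mean_rate", "z"])
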