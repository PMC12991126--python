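"""Session data model: trials, spike trains, eye traces, and their CSV I/O.

A *session* is one recording day: a table of trial events on a common clock
(seconds), one or more sorted spike trains, and a uniformly sampled 2D eye
trace in degrees of visual angle.  All downstream stages (microsaccade
detection, SDT behavior, PETHs) consume this model.

Conventions
-----------
* All times are seconds on the session clock; analysis windows are given in
  milliseconds relative to an event and converted internally.
* Intervals are half-open ``[lo, hi)`` everywhere: event alignment, PETH
  bins, and epoch membership.
* Aborted/incomplete trials may carry partial timestamps and are excluded
  from every analysis.
* Reaction time is ``t_saccade - t_go`` (the go cue is fixation-point
  offset).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AbortedTrialError, SchemaError

__all__ = [
    "EVENT_FIELDS",
    "OUTCOMES",
    "TrialEvents",
    "EyeTrace",
    "SpikeTrain",
    "Session",
    "classify_outcome",
    "reaction_time",
    "align_events",
    "read_session",
    "write_session",
]

#: Trial event timestamps in their required temporal order.
EVENT_FIELDS = (
    "t_fix_on",
    "t_grating1_on",
    "t_grating1_off",
    "t_grating2_on",
    "t_grating2_off",
    "t_targets_on",
    "t_go",
    "t_saccade",
    "t_targets_off",
)

OUTCOMES = ("hit", "miss", "correct_reject", "false_alarm", "aborted")


def classify_outcome(change_present: bool, choice: str) -> str:
    """Map a (stimulus, report) pair to its 2AFC change-detection outcome.

    ``hit``/``miss`` when a change occurred and the subject reported
    yes/no; ``correct_reject``/``false_alarm`` when no change occurred and
    the subject reported no/yes.

    Raises
    ------
    AbortedTrialError
        If ``choice`` is ``"none"`` (the trial was aborted before a report).
    """
    if choice == "none":
        raise AbortedTrialError("cannot classify an aborted trial (choice='none')")
    if choice not in ("yes", "no"):
        raise ValueError(f"choice must be 'yes', 'no' or 'none', got {choice!r}")
    if change_present:
        return "hit" if choice == "yes" else "miss"
    return "false_alarm" if choice == "yes" else "correct_reject"


@dataclass
class TrialEvents:
    """Event timestamps and behavioral labels for one trial.

    Any event time may be ``None`` on aborted trials.  ``task_version`` 1
    shows the choice targets at the go cue (``t_targets_on == t_go``);
    version 2 shows them earlier (``t_targets_on < t_go``).
    """

    trial_id: int
    t_fix_on: float | None = None
    t_grating1_on: float | None = None
    t_grating1_off: float | None = None
    t_grating2_on: float | None = None
    t_grating2_off: float | None = None
    t_targets_on: float | None = None
    t_go: float | None = None
    t_saccade: float | None = None
    t_targets_off: float | None = None
    change_present: bool = False
    change_amplitude: float = 0.0
    change_side: str = "left"
    choice: str = "none"
    outcome: str = "aborted"
    completed: bool = False
    task_version: int = 1

    def event_time(self, name: str) -> float | None:
        if name not in EVENT_FIELDS:
            raise ValueError(f"unknown event {name!r}")
        return getattr(self, name)

    def validate(self) -> None:
        """Check the per-trial invariants; raise SchemaError on violation."""
        times = [(n, getattr(self, n)) for n in EVENT_FIELDS if getattr(self, n) is not None]
        for (na, ta), (nb, tb) in zip(times, times[1:]):
            # targets may appear exactly at the go cue in task version 1
            if na == "t_targets_on" and nb == "t_go":
                ok = ta <= tb if self.task_version == 1 else ta < tb
            else:
                ok = ta < tb
            if not ok:
                raise SchemaError(
                    f"trial {self.trial_id}: event times out of order ({na}={ta} !< {nb}={tb})"
                )
        if self.change_present != (self.change_amplitude > 0):
            raise SchemaError(
                f"trial {self.trial_id}: change_amplitude {self.change_amplitude} "
                f"inconsistent with change_present={self.change_present}"
            )
        if self.completed:
            if self.choice == "none":
                raise SchemaError(f"trial {self.trial_id}: completed trial with choice 'none'")
            expected = classify_outcome(self.change_present, self.choice)
            if self.outcome != expected:
                raise SchemaError(
                    f"trial {self.trial_id}: outcome {self.outcome!r} inconsistent with "
                    f"(change_present={self.change_present}, choice={self.choice!r}); "
                    f"expected {expected!r}"
                )
        elif self.outcome != "aborted":
            raise SchemaError(f"trial {self.trial_id}: incomplete trial must be 'aborted'")
        if self.task_version not in (1, 2):
            raise SchemaError(f"trial {self.trial_id}: task_version must be 1 or 2")
        if (
            self.task_version == 2
            and self.t_targets_on is not None
            and self.t_go is not None
            and not self.t_targets_on < self.t_go
        ):
            raise SchemaError(
                f"trial {self.trial_id}: task version 2 requires t_targets_on < t_go"
            )


def reaction_time(trial: TrialEvents) -> float:
    """Saccade latency from the go cue (fixation-point offset), seconds."""
    if trial.t_saccade is None or trial.t_go is None:
        raise AbortedTrialError(f"trial {trial.trial_id}: no saccade/go time for RT")
    return trial.t_saccade - trial.t_go


@dataclass
class EyeTrace:
    """Uniformly sampled 2D gaze position in degrees of visual angle."""

    t0: float
    rate: float
    x: np.ndarray
    y: np.ndarray
    blink_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.blink_mask is None:
            self.blink_mask = np.zeros(self.x.shape, dtype=bool)
        self.blink_mask = np.asarray(self.blink_mask, dtype=bool)
        if not (self.x.shape == self.y.shape == self.blink_mask.shape):
            raise SchemaError("eye trace x, y, blink_mask lengths differ")
        if self.rate <= 0:
            raise SchemaError("eye trace sample rate must be positive")
        ok = ~self.blink_mask
        if not (np.isfinite(self.x[ok]).all() and np.isfinite(self.y[ok]).all()):
            raise SchemaError("non-finite eye position outside blinks")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    @property
    def span(self) -> tuple[float, float]:
        return (self.t0, self.t0 + self.n / self.rate)

    def index_of(self, t: float) -> int:
        """Sample index containing time ``t`` (floor)."""
        return int(math.floor((t - self.t0) * self.rate))


@dataclass
class SpikeTrain:
    """Sorted spike times (seconds) of one neuron over a session."""

    neuron_id: str
    times: np.ndarray
    span: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise SchemaError(f"neuron {self.neuron_id}: spike times not sorted")
        if self.times.size:
            lo, hi = self.span
            if self.times[0] < lo or self.times[-1] > hi:
                bad = self.times[0] if self.times[0] < lo else self.times[-1]
                raise SchemaError(
                    f"neuron {self.neuron_id}: spike at {bad} s outside span {self.span}"
                )

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class Session:
    """One recording session: trials + spike trains + eye trace + metadata."""

    trials: list[TrialEvents]
    spikes: list[SpikeTrain]
    eye: EyeTrace
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for tr in self.trials:
            tr.validate()
        lo, hi = self.eye.span
        spans = [(lo, hi)] + [st.span for st in self.spikes]
        for tr in self.trials:
            for name in EVENT_FIELDS:
                t = getattr(tr, name)
                if t is None:
                    continue
                for slo, shi in spans:
                    if not (slo <= t <= shi):
                        raise SchemaError(
                            f"trial {tr.trial_id}: {name}={t} s outside data span "
                            f"({slo}, {shi})"
                        )

    def completed_trials(self) -> list[TrialEvents]:
        return [t for t in self.trials if t.completed]

    @property
    def task_version(self) -> int:
        return int(self.metadata.get("task_version", self.trials[0].task_version))


def align_events(
    spike_times: np.ndarray,
    event_times: Sequence[float],
    window: tuple[float, float],
) -> list[np.ndarray]:
    """Align spikes to events: per event, spikes with ``lo <= s - e < hi``.

    Parameters
    ----------
    spike_times : sorted array of seconds.
    event_times : event timestamps, seconds (need not be sorted).
    window : (lo, hi) in seconds relative to the event, half-open on the
        right.

    Returns
    -------
    One array per event with the contained spike times expressed relative
    to that event.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window lo must be < hi, got {window}")
    ev = np.asarray(event_times, dtype=float)
    if ev.size and not np.isfinite(ev).all():
        raise ValueError("event times must be finite")
    st = np.asarray(spike_times, dtype=float)
    left = np.searchsorted(st, ev + lo, side="left")
    right = np.searchsorted(st, ev + hi, side="left")
    return [st[a:b] - e for a, b, e in zip(left, right, ev)]


# ---------------------------------------------------------------------------
# CSV I/O

TRIALS_COLUMNS = (
    ("trial_id",)
    + EVENT_FIELDS
    + (
        "change_present",
        "change_amplitude",
        "change_side",
        "choice",
        "outcome",
        "completed",
        "task_version",
    )
)


def _trials_frame(trials: Iterable[TrialEvents]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        row = {f.name: getattr(tr, f.name) for f in dc_fields(tr)}
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(TRIALS_COLUMNS))
    df["change_present"] = df["change_present"].astype(int)
    df["completed"] = df["completed"].astype(int)
    return df


def _parse_trials(df: pd.DataFrame) -> list[TrialEvents]:
    missing = set(TRIALS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"trials file missing columns: {sorted(missing)}")
    trials = []
    for _, row in df.iterrows():
        kw: dict = {"trial_id": int(row["trial_id"])}
        for name in EVENT_FIELDS:
            v = row[name]
            kw[name] = None if pd.isna(v) else float(v)
        kw["change_present"] = bool(int(row["change_present"]))
        kw["change_amplitude"] = float(row["change_amplitude"])
        kw["change_side"] = str(row["change_side"])
        kw["choice"] = str(row["choice"])
        kw["outcome"] = str(row["outcome"])
        kw["completed"] = bool(int(row["completed"]))
        kw["task_version"] = int(row["task_version"])
        trials.append(TrialEvents(**kw))
    return trials


def read_session(
    trials_csv: str | Path,
    spikes_csv: str | Path,
    eye_csv: str | Path,
    meta_json: str | Path | None = None,
) -> Session:
    """Read a session from its three CSV files (plus optional JSON metadata).

    Validates every schema invariant and raises :class:`SchemaError` naming
    the offending row on failure.
    """
    trials = _parse_trials(pd.read_csv(Path(trials_csv), float_precision="round_trip"))

    sp = pd.read_csv(Path(spikes_csv), float_precision="round_trip")
    for col in ("neuron_id", "time_s"):
        if col not in sp.columns:
            raise SchemaError(f"spikes file missing column {col!r}")

    ey = pd.read_csv(Path(eye_csv), float_precision="round_trip")
    for col in ("time_s", "x_deg", "y_deg", "blink"):
        if col not in ey.columns:
            raise SchemaError(f"eye file missing column {col!r}")
    t = ey["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise SchemaError("eye trace must have at least 2 samples")
    metadata: dict = {}
    if meta_json is not None:
        metadata = json.loads(Path(meta_json).read_text())
    rate = float(metadata.get("eye_rate_hz", 1.0 / np.median(np.diff(t))))
    eye = EyeTrace(
        t0=float(t[0]),
        rate=rate,
        x=ey["x_deg"].to_numpy(dtype=float),
        y=ey["y_deg"].to_numpy(dtype=float),
        blink_mask=ey["blink"].to_numpy(dtype=int).astype(bool),
    )

    span = eye.span
    spikes = []
    for nid, grp in sp.groupby("neuron_id", sort=True):
        times = np.sort(grp["time_s"].to_numpy(dtype=float))
        spikes.append(SpikeTrain(neuron_id=str(nid), times=times, span=span))

    session = Session(trials=trials, spikes=spikes, eye=eye, metadata=metadata)
    session.validate()
    return session


def write_session(session: Session, out_dir: str | Path) -> dict[str, Path]:
    """Write trials.csv, spikes.csv, eye.csv and session_meta.json.

    Floats are written with 17 significant digits, so a write-then-read
    cycle is lossless.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "spikes": out / "spikes.csv",
        "eye": out / "eye.csv",
        "meta": out / "session_meta.json",
    }
    _trials_frame(session.trials).to_csv(paths["trials"], index=False, float_format="%.17g")

    sp = pd.DataFrame(
        {
            "neuron_id": np.concatenate(
                [np.repeat(st.neuron_id, st.n_spikes) for st in session.spikes]
            )
            if session.spikes
            else np.array([], dtype=str),
            "time_s": np.concatenate([st.times for st in session.spikes])
            if session.spikes
            else np.array([], dtype=float),
        }
    )
    sp.to_csv(paths["spikes"], index=False, float_format="%.17g")

    eye = session.eye
    pd.DataFrame(
        {
            "time_s": eye.times,
            "x_deg": eye.x,
            "y_deg": eye.y,
            "blink": eye.blink_mask.astype(int),
        }
    ).to_csv(paths["eye"], index=False, float_format="%.17g")

    meta = dict(session.metadata)
    meta.setdefault("eye_rate_hz", eye.rate)
    paths["meta"].write_text(json.dumps(meta, indent=2, default=float))
    return paths
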