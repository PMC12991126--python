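"""End-to-end analysis pipeline.

``run`` drives one session through every stage — microsaccade detection,
SDT behavior with sliding-window state estimates, per-neuron PETHs and
epoch responses, responsiveness classification, the pre/post-saccadic
decomposition, and condition-split group tests — and writes the full
table set (events.csv, behavior.csv, psychometric.csv, peth.csv,
responsiveness.csv, splits.csv, report.json) to an output directory.
Identical config + seed give identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import eyemove, spikes as spk, stats, synth
from .errors import ConfigError, PerisaccError
from .session import Session, align_events, reaction_time, read_session

__all__ = ["RunConfig", "RunReport", "run", "compare_splits", "run_from_yaml"]

log = logging.getLogger("perisacc")

KNOWN_SPLITS = ("outcome", "amplitude", "rt_median", "dprime_median",
                "criterion_median", "microsaccade_epoch")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    input_dir: str | None = None
    simulate: dict | None = None  # kwargs understood by synth presets
    seed: int = 0
    detection: eyemove.DetectionParams = field(default_factory=eyemove.DetectionParams)
    sliding_window: int = 50
    bin_ms: float = 20.0
    splits: tuple[str, ...] = KNOWN_SPLITS
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = set(self.splits) - set(KNOWN_SPLITS)
        if unknown:
            raise ConfigError(f"unknown split name(s): {sorted(unknown)}")
        if (self.input_dir is None) == (self.simulate is None):
            raise ConfigError("exactly one of input_dir / simulate must be given")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ConfigError(f"input_dir {self.input_dir!r} does not exist")


@dataclass
class RunReport:
    files: dict[str, str]
    n_trials: int
    n_completed: int
    n_neurons: int
    n_events: int
    params: dict
    wall_time_s: float


def _load_session(cfg: RunConfig) -> Session:
    if cfg.input_dir is not None:
        d = Path(cfg.input_dir)
        return read_session(
            d / "trials.csv", d / "spikes.csv", d / "eye.csv",
            d / "session_meta.json" if (d / "session_meta.json").exists() else None,
        )
    sim = dict(cfg.simulate or {})
    n_neurons = int(sim.pop("n_neurons", 10))
    preset = sim.pop("preset", "saccade_locked")
    task = synth.TaskParams(**sim.pop("task", {}))
    observer = synth.ObserverParams(**sim.pop("observer", {}))
    if sim:
        raise ConfigError(f"unknown simulate options: {sorted(sim)}")
    if preset == "saccade_locked":
        neurons = synth.saccade_locked_neurons(n_neurons, seed=cfg.seed + 1)
    elif preset == "null":
        neurons = synth.draw_neurons(n_neurons, seed=cfg.seed + 1)
    else:
        raise ConfigError(f"unknown simulate preset {preset!r}")
    session, _ = synth.gen_session(task=task, observer=observer,
                                   neurons=neurons, seed=cfg.seed)
    return session


def compare_splits(rates: np.ndarray, labels) -> tuple:
    """Group test on per-trial rates under a labeling.

    Dispatches to Welch's t for two groups or one-way ANOVA with
    Tukey-Kramer post hocs for three or more.  Returns (omnibus
    TestResult, pairwise list, ordered group names, group means); a
    single-group labeling returns ``None`` (skipped).
    """
    labels = np.asarray(labels)
    names = [g for g in sorted(set(labels.tolist())) if (labels == g).sum() >= 2]
    groups = [rates[labels == g] for g in names]
    if len(groups) < 2:
        return None
    means = {g: float(v.mean()) for g, v in zip(names, groups)}
    if len(groups) == 2:
        res = stats.welch_t(groups[0], groups[1])
        return res, [], names, means
    omni, pw = stats.anova_tukey(groups)
    return omni, pw, names, means


def run(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline; abort (removing partial outputs) on any
    stage error."""
    t_start = time.monotonic()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, df: pd.DataFrame) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)
        return p

    try:
        log.info("loading session")
        session = _load_session(cfg)
        trials = session.completed_trials()
        tv = session.task_version

        # --- eye events ------------------------------------------------
        log.info("detecting microsaccades")
        events = eyemove.detect_microsaccades(session.eye, session.trials, cfg.detection)
        _write("events.csv", eyemove.events_frame(events))

        # --- behavior ---------------------------------------------------
        log.info("behavioral quantification")
        state = bhv.sliding_sdt(trials, window=cfg.sliding_window)
        rts = {tr.trial_id: reaction_time(tr) for tr in trials}
        rt_labels = bhv.median_split([rts[t] for t in state.trial_ids])
        behavior_df = pd.DataFrame(
            {
                "trial_id": state.trial_ids,
                "outcome": [tr.outcome for tr in trials],
                "rt_s": [rts[t] for t in state.trial_ids],
                "window_dprime": state.dprime_t,
                "window_criterion": state.criterion_t,
                "dprime_label": state.dprime_label,
                "criterion_label": state.criterion_label,
                "rt_label": rt_labels,
            }
        )
        _write("behavior.csv", behavior_df)

        psy = bhv.psychometric(trials)
        _write(
            "psychometric.csv",
            pd.DataFrame(
                {
                    "amplitude": list(psy),
                    "hit_rate": [m.hit_rate for m in psy.values()],
                    "dprime": [m.dprime for m in psy.values()],
                    "criterion": [m.criterion for m in psy.values()],
                }
            ),
        )

        # --- spikes -----------------------------------------------------
        log.info("PETHs and epoch responses for %d neurons", len(session.spikes))
        peth_rows, resp_rows, split_rows = [], [], []
        baselines, epoch_rate_cache, decomp = {}, {}, {}
        for st in session.spikes:
            baselines[st.neuron_id] = spk.baseline_stats(st, trials)
            for name, (ev, win) in spk.PETH_WINDOWS_MS.items():
                times = [getattr(tr, ev) for tr in trials]
                p = spk.peth(st, times, win, cfg.bin_ms,
                             baseline=baselines[st.neuron_id], alignment=name)
                peth_rows.append(p)
            for epoch in spk.EPOCH_WINDOWS_MS:
                ids, rr = spk.epoch_rates(st, trials, epoch)
                epoch_rate_cache[(st.neuron_id, epoch)] = (ids, rr)
            decomp[st.neuron_id] = spk.saccadic_decomposition(st, trials, tv)
        _write("peth.csv", spk.peth_frame(peth_rows))

        # --- responsiveness --------------------------------------------
        log.info("responsiveness classification")
        fix_rates = {}
        for st in session.spikes:
            # per-trial baseline (fixation) rates, matched to trial order
            bl = []
            for tr in trials:
                end = min(tr.t_fix_on + spk.BASELINE_WINDOW_S, tr.t_grating1_on)
                (rel,) = align_events(st.times, [tr.t_fix_on], (0.0, end - tr.t_fix_on))
                bl.append(rel.size / (end - tr.t_fix_on))
            fix_rates[st.neuron_id] = np.asarray(bl)
        for st in session.spikes:
            for epoch in spk.EPOCH_WINDOWS_MS:
                _, rr = epoch_rate_cache[(st.neuron_id, epoch)]
                row = stats.classify_responsive(rr, fix_rates[st.neuron_id],
                                                st.neuron_id, epoch)
                resp_rows.append(
                    {
                        "neuron_id": row.neuron_id,
                        "epoch": row.epoch,
                        "n": len(trials),
                        "statistic": row.result.statistic if row.testable else np.nan,
                        "df": row.result.df if row.testable else np.nan,
                        "p": row.result.p if row.testable else np.nan,
                        "significant": row.significant,
                        "direction": row.direction,
                    }
                )
            d = decomp[st.neuron_id]
            for tag, rr in (("pre_saccadic", d.pre_rates), ("post_saccadic", d.post_rates)):
                row = stats.classify_responsive(rr, d.baseline_rates, st.neuron_id, tag)
                resp_rows.append(
                    {
                        "neuron_id": st.neuron_id,
                        "epoch": tag,
                        "n": len(trials),
                        "statistic": row.result.statistic if row.testable else np.nan,
                        "df": row.result.df if row.testable else np.nan,
                        "p": row.result.p if row.testable else np.nan,
                        "significant": row.significant,
                        "direction": row.direction,
                    }
                )
        _write("responsiveness.csv", pd.DataFrame(resp_rows))

        # --- condition splits on saccade-epoch rates --------------------
        log.info("condition splits")
        state_by_id = dict(zip(state.trial_ids, range(len(state.trial_ids))))
        for split in cfg.splits:
            for st in session.spikes:
                ids, rr = epoch_rate_cache[(st.neuron_id, "saccade")]
                if split == "outcome":
                    labels = [tr.outcome for tr in trials]
                elif split == "amplitude":
                    keep = [i for i, tr in enumerate(trials)
                            if tr.outcome == "hit"]
                    labels = [f"amp{trials[i].change_amplitude:g}" for i in keep]
                    rr = rr[keep]
                elif split == "rt_median":
                    labels = rt_labels
                elif split == "dprime_median":
                    labels = state.dprime_label
                elif split == "criterion_median":
                    labels = state.criterion_label
                elif split == "microsaccade_epoch":
                    labels, rr = _microsaccade_rates(st, events)
                    if labels is None:
                        continue
                res = compare_splits(np.asarray(rr), labels)
                if res is None:
                    log.warning("split %s skipped for %s (one usable group)",
                                split, st.neuron_id)
                    continue
                omni, pw, names, means = res
                bl = baselines[st.neuron_id]
                split_rows.append(
                    {
                        "split": split,
                        "neuron_id": st.neuron_id,
                        "test": omni.test_name,
                        "groups": "|".join(str(g) for g in names),
                        "group_mean_z": "|".join(
                            f"{float(spk.zscore(means[g], bl)):.4f}" for g in names
                        ),
                        "statistic": omni.statistic,
                        "p": omni.p,
                        "significant": omni.significant,
                        "n_pairs_significant": sum(x.significant for x in pw),
                    }
                )
        _write("splits.csv", pd.DataFrame(split_rows))

        report = RunReport(
            files={p.name: str(p) for p in written},
            n_trials=len(session.trials),
            n_completed=len(trials),
            n_neurons=len(session.spikes),
            n_events=len(events),
            params={
                "seed": cfg.seed,
                "detection": {k: getattr(cfg.detection, k)
                              for k in cfg.detection.__dataclass_fields__},
                "sliding_window": cfg.sliding_window,
                "bin_ms": cfg.bin_ms,
                "splits": list(cfg.splits),
            },
            wall_time_s=time.monotonic() - t_start,
        )
        rp = out / "report.json"
        rp.write_text(json.dumps(vars(report), indent=2, default=str))
        written.append(rp)
        return report
    except PerisaccError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PerisaccError(f"pipeline aborted: {exc}") from exc


def _microsaccade_rates(st, events, win_ms=(-100.0, 100.0)):
    """Spike rates around microsaccade onsets grouped choice vs other."""
    groups = {"choice": [], "other": []}
    for e in events:
        if e.epoch in groups:
            groups[e.epoch].append(e.t_on)
    if len(groups["choice"]) < 2 or len(groups["other"]) < 2:
        return None, None
    labels, rates = [], []
    length = (win_ms[1] - win_ms[0]) * 1e-3
    for g, times in groups.items():
        aligned = align_events(st.times, times, (win_ms[0] * 1e-3, win_ms[1] * 1e-3))
        for a in aligned:
            labels.append(g)
            rates.append(a.size / length)
    return labels, np.asarray(rates)


def run_from_yaml(path: str | Path) -> RunReport:
    """Build a RunConfig from a YAML file and run the pipeline."""
    raw = yaml.safe_load(Path(path).read_text())
    det = eyemove.DetectionParams(**raw.pop("detection", {}))
    cfg = RunConfig(detection=det, **raw)
    return run(cfg)
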