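"""Shared fixtures: small synthetic sessions and deterministic settings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from perisacc import synth

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_session():
    """A compact task-v1 session (6 neurons, 120 trials) with ground truth."""
    task = synth.TaskParams(n_trials=120)
    neurons = synth.draw_neurons(4, seed=3, pre_gain=6.0, post_gain=6.0)
    neurons += synth.draw_neurons(2, seed=4)
    for i, n in enumerate(neurons):
        object.__setattr__(n, "neuron_id", f"n{i:03d}")
    session, gt = synth.gen_session(task=task, neurons=neurons, seed=11)
    return session, gt


@pytest.fixture(scope="session")
def v2_trials():
    """Completed task-v2 trials (choice epoch precedes the go cue)."""
    task = synth.TaskParams(n_trials=150, task_version=2)
    trials = synth.gen_trials(task, 21)
    trials, _ = synth.gen_observer(trials, synth.ObserverParams(), 22)
    return trials


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
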