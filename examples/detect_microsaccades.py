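"""Detect microsaccades with the velocity-threshold algorithm and score
the result against the generator's planted ground truth.

The detector estimates gaze velocity with a 5-point centered difference,
sets a per-trial threshold at 4x the SD of radial speed over the trial's
fixation epochs, and filters candidate events by amplitude (<= 1 deg),
duration (>= 6 ms) and peak velocity (<= 100 deg/s).
"""

import numpy as np

from perisacc import eyemove, synth

task = synth.TaskParams(n_trials=120, task_version=2)
trials = synth.gen_trials(task, 1)
trials, _ = synth.gen_observer(trials, synth.ObserverParams(), 2)
eye, truth = synth.gen_eye(trials, synth.EyeGenParams(), seed=3)

events = eyemove.detect_microsaccades(eye, trials)

planted = np.sort([m["t_on"] for m in truth.microsaccades])
detected = np.array([e.t_on for e in events])
used = np.zeros(detected.size, bool)
hits = 0
for t in planted:
    d = np.abs(detected - t)
    d[used] = np.inf
    j = d.argmin()
    if d[j] <= 0.010:
        used[j] = True
        hits += 1

by_epoch = {}
for e in events:
    by_epoch[e.epoch] = by_epoch.get(e.epoch, 0) + 1

print(f"planted {planted.size} microsaccades, detected {detected.size}")
print(f"recall {hits / planted.size:.2f}, precision {hits / detected.size:.2f} "
      "(onsets matched within +-10 ms)")
print(f"median threshold {np.median([e.threshold_dps for e in events]):.1f} deg/s")
print(f"events by epoch: {by_epoch}")
# 'choice' events fall between choice-target onset and offset; 'other'
# events during fixation/gratings; recall and precision near 1 show the
# detector recovering the planted events at their true onsets.
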