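"""Event-aligned firing: z-scored PETHs, population averages, and the
pre/post-saccadic decomposition.

Each neuron's firing is counted in 20 ms bins around the choice saccade,
standardized against the mean and SD of its fixation-period (baseline)
rates across trials, and averaged over the population.  The peri-saccadic
response is then split into pre- ([-100, 0) ms) and post- ([0, 100) ms)
saccadic components against a pre-choice baseline window.
"""

import numpy as np

from perisacc import synth
from perisacc.spikes import (
    baseline_stats,
    peth,
    population_peth,
    saccadic_decomposition,
)
from perisacc.stats import classify_responsive

task = synth.TaskParams(n_trials=300)
trials = synth.gen_trials(task, 8)
trials, _ = synth.gen_observer(trials, synth.ObserverParams(), 9)
span = (0.0, max(t.t_targets_off for t in trials) + 1.0)
ev = [t.t_saccade for t in trials]

peths = []
for i in range(12):
    npar = synth.NeuronParams(neuron_id=f"n{i}", baseline=4.62,
                              pre_gain=5.0, post_gain=7.0)
    st, _ = synth.gen_spikes(trials, npar, 40 + i, span)
    bs = baseline_stats(st, trials)
    peths.append(peth(st, ev, (-300.0, 200.0), 20.0, baseline=bs))

mean_z, sem = population_peth(peths)
edges = peths[0].bin_edges_ms[:-1]
peak = int(np.argmax(mean_z))
print(f"population PETH peak: z = {mean_z[peak]:.1f} in bin "
      f"[{edges[peak]:.0f}, {edges[peak] + 20:.0f}) ms around the saccade")
pre_bins = (edges >= -100) & (edges < 0)
print(f"mean z in the pre-saccadic 100 ms: {mean_z[pre_bins].mean():.1f}")

st, _ = synth.gen_spikes(trials, synth.NeuronParams(
    neuron_id="demo", baseline=4.62, pre_gain=5.0, post_gain=7.0), 99, span)
d = saccadic_decomposition(st, trials, task_version=1)
row = classify_responsive(d.post_rates, d.baseline_rates, "demo", "post")
print(f"decomposition: pre {d.pre_delta:+.1f} sp/s, post {d.post_delta:+.1f} sp/s "
      f"above the pre-choice baseline ({d.prechoice_baseline:.1f} sp/s)")
print(f"post-saccadic response significant: {row.significant} "
      f"(paired t, p = {row.result.p:.2g})")
# The recovered deltas sit near the planted +5/+7 sp/s gains, and the
# z-scored population PETH shows the buildup beginning ~100 ms before
# saccade onset.
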