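# perisacc

Analysis tooling for studying how brainstem spiking — in particular the
low-rate, burst-prone firing typical of locus coeruleus (LC) neurons —
relates to eye movements and perceptual decisions in a two-alternative
forced-choice (2AFC) change-detection task with a saccadic report.

The package is aimed at systems-neuroscience labs that record sorted
spike trains, trial event tables, and high-rate eye-position traces in
such tasks and want a tested, reproducible path from raw session tables
to the standard figures-grade quantities:

- **Event-aligned firing.** Peri-event time histograms (PETHs) in 20 ms
  bins around fixation, grating, choice-target and saccade events;
  baseline standardization against the across-trial distribution of
  fixation-period rates, so each bin's z-score reads "SDs above
  baseline"; population means ± SEM across neurons; and a pre/post
  decomposition of the peri-saccadic response against a pre-choice
  baseline window.
- **Microsaccade detection.** A 2D velocity-threshold detector: radial
  gaze speed from a 5-point centered difference, a per-trial threshold at
  4× the SD of radial speed over the trial's fixation epochs, and the
  three classical filters (amplitude ≤ 1°, duration ≥ 6 ms, peak velocity
  ≤ 100°/s), with choice/other/outside-trial epoch labels.
- **Behavior via signal detection theory.** Hit and false-alarm rates,
  edge-corrected sensitivity and bias

      d' = Φ⁻¹(HR) − Φ⁻¹(FAR),   c = −½ (Φ⁻¹(HR) + Φ⁻¹(FAR)),

  per-amplitude psychometric curves, 50-trial sliding-window estimates of
  the perceptual state, and median-split trial labels (RT, d', c).
- **Statistics.** Paired t, Welch t, one-way ANOVA with Tukey-Kramer
  post hocs, and per-neuron responsiveness classification at p < 0.05.
- **Synthetic sessions.** A first-class generator producing complete
  sessions — task timing for both protocol versions, an equal-variance
  SDT observer with a shifted-lognormal RT model, fixational eye traces
  with planted main-sequence microsaccades, and inhomogeneous-Poisson
  spike trains with saccade-locked gain kernels — returning ground truth
  for every planted quantity so recovery can be scored.

## Worked example

```python
from perisacc import synth
from perisacc.behavior import count_outcomes, sdt_from_counts

task = synth.TaskParams(n_trials=300, task_version=1)
neurons = synth.draw_neurons(8, seed=2, pre_gain=6.0, post_gain=6.0)
session, truth = synth.gen_session(task=task, neurons=neurons, seed=17)

m = sdt_from_counts(count_outcomes(session.completed_trials()))
print(f"hit rate {m.hit_rate:.2f}, FA rate {m.fa_rate:.2f} "
      f"-> d' = {m.dprime:.2f}, c = {m.criterion:.2f}")
```

prints

```
hit rate 0.64, FA rate 0.15 -> d' = 1.39, c = 0.33
```

i.e. the simulated observer detects 64% of changes with a 15% false-alarm
rate, a sensitivity of 1.39 and a conservative bias (c > 0, toward
reporting "no change").  Running the detector on the same session's eye
trace (`examples/detect_microsaccades.py`) reports

```
planted 144 microsaccades, detected 137
recall 0.95, precision 1.00 (onsets matched within +-10 ms)
```

showing the velocity-threshold algorithm recovering the planted
fixational eye movements at their true onsets.  Each script in
`examples/` demonstrates one capability end to end and explains what its
numbers mean; `examples/full_pipeline.py` drives a whole session through
every stage and writes the complete table set (events, behavior,
psychometric, PETH, responsiveness, splits and a JSON run report).

A thin CLI wraps the same library calls:

```bash
perisacc simulate --seed 17 --n-neurons 10 --out session_dir
perisacc detect-ms --session session_dir --out events.csv
perisacc behavior --session session_dir --out behavior.csv
perisacc run --config run.yaml
```

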