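# Methods

This note documents the models, conventions and numerical choices behind
`perisacc`, and what the synthetic-data generator does and does not
emulate.

## Session model and conventions

All times are seconds on a single session clock. Analysis windows are
specified in milliseconds relative to an event and converted internally.
Every interval — event alignment, PETH bins, epoch membership — is
half-open `[lo, hi)`, which prevents double counting at bin edges.
Aborted trials may carry partial timestamps and are excluded from every
analysis; "trials" below always means completed trials. Reaction time is
`t_saccade − t_go`, the saccade latency from the go cue (fixation-point
offset), the standard convention for a go-cued saccade task.

In task version 1 the choice targets appear exactly at the go cue
(`t_targets_on == t_go`); version 2 inserts a randomized 350–550 ms
target-to-go delay, creating a pre-go choice epoch in which fixational
eye movements can be observed with the targets visible.

CSV I/O writes floats with 17 significant digits and reads them with
round-trip parsing, so a write–read cycle is lossless.

## Microsaccade detection

Velocity is a centered moving-window finite difference over
`smooth_span` samples (default 5, the classical 5-point scheme):
`v_n = Σ_{j=1..k} (x_{n+j} − x_{n−j}) / (2 Σ j) · rate`. Radial speed is
`√(vx² + vy²)`. Samples inside a blink, within half a span of one, or at
the trace edges are NaN-masked.

The per-trial threshold is `λ · SD(radial speed)` (λ = 4) over the window
from 300 ms before grating-1 onset to the go cue, pooled per completed
trial. The plain sample SD is the primary definition; a median-based
(1.4826·MAD) estimator is available behind `robust_sd` but is not the
default. Candidate events are maximal above-threshold runs; runs closer
than `merge_gap` (20 ms, below the physiologic inter-saccade interval)
are fused; events must then satisfy duration ≥ 6 ms, amplitude ≤ 1°, and
peak velocity ≤ 100°/s. Amplitude is the Euclidean combination of the
per-axis extrema displacements within the event.

**Threshold floor.** The SD-multiple rule alone is scale-invariant: for
Gaussian drift of *any* amplitude, 4× the SD of a Rayleigh-distributed
radial speed sits near its 97th percentile, so an event-free trace
triggers spurious detections at a rate set purely by the noise bandwidth
(order 1/s), independent of how quiet the trace is. The detector
therefore applies a lower bound `floor_dps` (default 6°/s) to every
per-trial threshold. On traces that contain real saccadic events the SD
is inflated well above the floor and the rule behaves exactly as the
plain λ·SD prescription; the floor only prevents the detector from
chasing drift on near-noiseless data, and is the remedy the degenerate
zero-SD error message points to.

Epoch labels: *choice* if the onset falls in `[t_targets_on,
t_targets_off)`, *other* in `[t_fix_on, t_targets_on)`, otherwise
*outside_trial*. Outside completed trials the session-median threshold
applies.

Choice-saccade onset detection (used when a saccade time must be derived
from the trace rather than supplied) takes the first time after the go
cue at which radial speed exceeds 30°/s for ≥ 5 consecutive samples with
an ensuing displacement > 1°, and errors if none occurs within 1 s.

## Behavior

Sensitivity and bias follow the equal-variance Gaussian model,
`d' = Φ⁻¹(HR) − Φ⁻¹(FAR)` and `c = −½(Φ⁻¹(HR) + Φ⁻¹(FAR))`; positive c
biases toward "no". Rates of exactly 0 or 1 are corrected to `1/(2n)` /
`1 − 1/(2n)` before the quantile transform and flagged; this is the
standard convention for finite samples, chosen because the measurement
procedure does not otherwise define behavior at the edges.

Psychometric curves compute one (d', c) per change amplitude using that
amplitude's hit rate against the session-wide false-alarm rate — forced
by the design, since change-absent trials carry no amplitude.

The sliding state estimator recomputes (d', c) in 50-trial windows
stepped by one trial. Each trial receives the estimate of the window
centered on it (edge trials take the nearest window); centering is a
choice — trailing or leading assignments are equally defensible — and is
configurable in principle via the mapping used. A window lacking one
trial class entirely gets an uninformative 0.5 for the missing rate and
a `corrected` flag rather than an exception, so long runs of one
stimulus class cannot abort a session analysis. Median splits label
trials strictly below/above the median and alternate ties so group sizes
differ by at most one; all-identical values raise a degenerate-split
error (with window = n the sliding estimates are constant, and the
labels are `None`).

## Spike analysis

Baseline statistics are per-trial firing rates in a 500 ms window at the
start of the initial fixation period, across all completed trials. The
fixation delay is 400–600 ms, so when grating 1 appears before the
window closes the window is truncated at grating onset and the rate
rescaled by the actual length — the window must not leak stimulus-driven
spikes. Rates (not counts) are standardized, so windows of different
lengths are comparable: `z = (rate − baseline mean)/baseline SD`. A zero
baseline SD makes z-scoring impossible and raises a degenerate-baseline
error.

Epoch rates use fixed windows: gratings `[0, 350)` ms from onset, choice
targets `[0, 300)` ms from onset, saccade and target-offset `[−100,
+100)` ms around the event. PETHs use 20 ms bins over fixation
`[200, 700)`, gratings `[−200, 500)`, target onset `[−200, 300)`,
saccade `[−300, 200)` and target offset `[−300, 300)` ms. Population
PETHs average z-scored single-neuron PETHs; SEM is across neurons.

The saccadic decomposition computes per-trial rates in `[−100, 0)` and
`[0, 100)` ms around saccade onset and subtracts a pre-choice baseline
measured saccade-aligned at `[−350, −250)` ms (task version 1) or
`[−650, −550)` ms (version 2, whose targets appear earlier); per-trial
rates are retained for paired significance tests.

## Statistics

All tests are two-sided; direction (above/below baseline) is reported
separately. Paired and Welch t tests and the one-way ANOVA are the
scipy.stats implementations behind a thin result layer; Tukey-Kramer
pairwise comparisons use the studentized-range distribution with the
Kramer unequal-n adjustment (`scipy.stats.tukey_hsd`), cross-checked in
the test suite against statsmodels. No correction is applied across
neurons; Tukey-Kramer operates only within an ANOVA family. Degenerate
inputs (zero-variance differences) become "untestable" rows rather than
exceptions so a population sweep continues.

## Synthetic sessions

The generator's defaults are the study conditions the analyses are
validated under.

**Task timing.** Fixation delay U(400, 600) ms; gratings 350 ms;
inter-grating delay U(200, 400) ms; delay from grating-2 offset to
choice-target onset U(400, 600) ms (the protocol calls this period
"variable" without a range; this value was fixed once); version-2
target-to-go delay U(350, 550) ms; inter-trial interval 1 s; change
probability 0.5 over 4 amplitude levels.

**Observer.** Equal-variance SDT with the signal at +d'/2 and noise at
−d'/2 — the unique generative model consistent with the d'/c formulas:
P(yes) = Φ(d'/2 − c) on change trials and Φ(−d'/2 − c) otherwise. On
change-absent trials the mean of the per-amplitude d' map places the
criterion. Optional per-trial courses scale d' and replace c, enabling
step-change and drifting-state scenarios. RT = 100 ms shift +
LogNormal(log 0.08, 0.35) + 20 ms for the hardest amplitude (shrinking
linearly to 0 for the easiest) + 10 ms on errors, capped at 550 ms;
medians land near 180–220 ms. The RT constants are generator choices
made once to exercise the RT-split analyses, not measured values.

**Eye traces.** Fixation jitter is low-pass Gaussian noise (white noise
smoothed with a 15 ms Gaussian kernel, 0.02° RMS per axis — realistic
for a 1 kHz video tracker). Microsaccades are planted as Poisson events
(0.5/s in the 'other' epoch, 1.0/s in the pre-go choice epoch) with
minimum-jerk displacement profiles, amplitudes U(0.1, 0.9)°, directions
biased back toward fixation so gaze stays bounded, and the main-sequence
law `vpeak = k · amplitude` with k = 100 s⁻¹ — i.e. 19 ms duration and
0.5° → 50°/s, on the empirical microsaccade main sequence. (A slope
near 55 would force 34 ms events whose threshold crossings lag true
onset by more than the ±10 ms matching tolerance used in validation;
k = 100 keeps the kinematics physiologic and the benchmark meaningful.)
Choice saccades of 8° jump to the chosen target at `t_go + RT`, with a
return saccade after target offset.

**Spike trains.** Each neuron is an inhomogeneous Poisson process
sampled by thinning against a rate function: a gamma-distributed
baseline (population mean 4.62, SD 2.93 sp/s, floored at 0.5) plus
event-locked kernels — a pre-saccadic linear ramp (onset −150 ms,
peaking at saccade onset), a post-saccadic exponential decay (τ =
100 ms, support 200 ms), and optional target-onset/-offset Gaussian
bumps. Pre/post gains are calibrated as the *mean* rate increment in the
canonical `[−100, 0)` / `[0, 100)` ms windows (kernel peaks are scaled
internally), so a planted gain is directly comparable to what the
decomposition measures. The "saccade_locked" population preset gives 88% of
neurons saccade-locked kernels with outcome-independent gains.

**What the generator does not emulate.** Drift/tremor microstructure of
fixation beyond low-pass jitter, blinks, binocular disparity, spike-count
correlations between neurons, microsaccade-locked spiking kernels, and
any dependence of neural gain on behavioral state. Passing recovery
tests therefore demonstrates that the analysis chain measures what it
claims on data matching its assumptions — not that real recordings meet
those assumptions.

## Validation problem sizes

The shipped validation uses: a 160-trial version-2 session (~200+
planted microsaccades) for the detector benchmark; 50 neurons × 300
trials for kernel-gain recovery; 2 000 trials × 100 seeds for observer
recovery; 2 000 null replicates per test for type-I calibration; and one
59-neuron, 600-trial version-1 session for the end-to-end run. These
sizes give the recovery estimates sampling errors comfortably inside the
tolerances being checked while keeping a full validation run to a few
minutes on one CPU.

## Known limitations

- The detector reports threshold-crossing onsets; for events whose peak
  velocity barely clears the threshold, detected onsets lag true
  movement onset by several milliseconds.
- Sliding-window d' is biased slightly upward relative to the
  whole-session estimate at small windows (nonlinear quantile transform
  of noisy rates); window = 50 keeps the bias well under 0.1 for typical
  performance levels.
- The sliding-window criterion/d' labels treat the window estimate as
  the trial's state; no latent-state smoothing is attempted.
- `align_events` and the PETH assume sorted spike times; the session
  reader enforces this.
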