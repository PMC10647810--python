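# Methods

This note documents the models implemented in `neurorace`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## The decision chain

The package models a minimal embodied decision: a robot arm grasps an
object and, by default, moves it to the right. Grasping emits a *start*
signal that begins externally driving a subset of neurons in a simulated
cell assembly. If the assembly *ignites* — its population firing crosses a
threshold — a *go* signal is emitted, and if that signal arrives strictly
before the default action's deadline, the robot moves left instead. This
is an independent horse race between two processes: the ignition-driven go
signal and the default-action timer. The ignition time depends on how many
neurons are driven, so the stimulation count selects the action.

## Assembly topology

`topology.generate_topology(n_neurons=500, k_out=30)` grows a directed
graph by sequential preferential attachment: neurons emit their 30
outgoing synapses in a seeded random order, and each target is drawn with
probability proportional to its current in-degree plus one, with
self-edges and duplicate pairs redrawn. Every neuron therefore has
out-degree exactly 30 (15,000 edges in total) while in-degrees are
heavy-tailed: hub neurons collect 100+ incoming synapses, the median
neuron fewer than 30, and the log in-degree vs log rank slope over the top
half of ranks is reliably below −0.1. The `+1` baseline keeps
zero-in-degree neurons reachable; freezing the attachment probabilities
during each neuron's emission turn keeps the generator order-independent
within a turn. All edges carry one scalar efficacy; weight heterogeneity
and plasticity are out of scope (the assembly is static, as if already
formed by prior learning).

No rewiring/clustering parameter is exposed: "small world" here is the
hub-dominated, short-path structure that preferential attachment produces,
not a Watts–Strogatz construction.

## Leaky integrate-and-fire simulation

`lif.simulate` advances the network on a fixed 1 ms grid. Each neuron
obeys the current-based LIF equations

    tau_m dV/dt = (v_rest − V) + R·I(t),      R = tau_m / c_m
    tau_syn dI_syn/dt = −I_syn,

with parameter defaults of the conventional current-based LIF cell:
v_rest = v_reset = −65 mV, v_thresh = −50 mV, tau_m = 20 ms, c_m = 1 nF,
tau_syn = 5 ms, absolute refractory period 0.1 ms, no offset current.
Both ODEs are linear, so each step applies their exact exponential
solution with the input current frozen at its start-of-step value — 
unconditionally stable at the coarse grid, and exact for a constant
current. A spike (V ≥ v_thresh, right at threshold counts) resets the
neuron and delivers `weight` nA to each of its 30 targets at the start of
the **next** step (one-step axonal delay, the minimum causal delay on the
grid). With the default 0.1 ms refractory period a neuron may fire in
consecutive steps; longer refractory periods hold the neuron at reset for
the corresponding whole steps.

The external activation is a constant DC current (`drive`) injected into
the k stimulated neurons from the start signal onward. A single neuron
from rest under constant current I crosses threshold at

    t* = tau_m · ln( IR / (IR − (v_thresh − v_rest)) ),

which is `single_neuron_first_spike`, the analytic oracle the simulator is
tested against (simulated first spike = ceil(t*) within one step).

## Ignition and calibration

Ignition is declared at the first millisecond t at which the number of
spikes in the trailing right-closed window (t−10, t] reaches 1100
(`decision.detect_ignition`; the incremental running-sum detector is
tested against a brute-force per-ms recount). The two free scalars of the
network — the uniform synaptic weight and the DC drive — are set by
`lif.calibrate_weight`, a grid search minimising the summed squared error
of median ignition times (over five seeded assemblies) against the
reference operating points: ignition at 56 ms with 100 neurons stimulated
and at 102 ms with 50. The search is joint in (weight, drive) because the
median ignition time is a step function of the weight — the cascade locks
onto the synchronized volley of the identically-driven stimulated neurons —
so a one-dimensional root find can stall on a plateau.

The shipped result is **weight = 0.30 nA, drive = 0.85 nA**. At this
point the dynamics are: the stimulated neurons, all identical, first fire
together near t* ≈ 43 ms; their volley recruits hub neurons, whose spikes
recruit further neurons within a few milliseconds. With k = 100 the first
volley's cascade reaches threshold (median 58 ms over assembly seeds
1–10); with k = 50 the first cascade stalls and ignition waits for the
second volley (median 101 ms). The default race deadline of 80 ms lies
between the two operating points — the value is a model parameter, since
the physical robot's own right-movement onset in simulation-time units is
not part of the model — so 100 stimulated neurons produce a left action
and 50 a right action on all ten seeded assemblies.

Simulation state after ignition is discarded (recording and simulation
stop); nothing downstream consumes post-ignition activity.

## Sweep experiment

`experiments.sweep_ignition` measures ignition time at k = 50..100 (step 5,
11 points) for 10 independently generated assemblies, re-using the same
topology across k within an assembly so the stimulation effect is
within-assembly; the stimulated subset is redrawn per (assembly, k).
Ignition time falls monotonically in trend with k (Spearman ρ = −1 for
the average curve at the shipped defaults), each assembly ignites strictly
earlier at k = 100 than k = 50, and the across-assembly average curve has
lower total variation than the mean individual curve. Runs reaching t_max
(400 ms default in the acceptance script, 300 ms in the sweep) without
ignition are recorded as failures, reported in an `n_failed` column and
excluded from means rather than silently censored.

## LRP pipeline

The lateralized readiness potential is derived from two-channel (C3/C4)
epochs spanning −1500..+200 ms around response onset at 1000 Hz. Per
trial the lateralized difference is C3 − C4 for right-hand responses and
C4 − C3 for left-hand responses (contralateral minus ipsilateral over
motor cortex); the condition waveform is the across-trial mean and the
summary statistic is the waveform's time-average over the half-open
window [−400, 0) ms. The task mapping is fixed: *remembered* items are
answered yes with the right hand, *new* items no with the left hand.
Trials whose absolute voltage exceeds ±100 µV on any channel are rejected
before averaging.

Filtering. `bandpass_zero_phase` applies a second-order Butterworth
band-pass (0.1–40 Hz) forward and backward, cancelling the phase shift.
Two edge-handling modes are provided because the low cut-off's impulse
response (~1/0.1 Hz = 10 s) is long relative to a 1.7 s epoch:

* `"pad"` (odd-extension padding, `scipy.signal.sosfiltfilt`): exact DC
  removal and the textbook behaviour for continuous recordings, where the
  start-up transient only touches the recording's ends;
* `"gust"` (Gustafsson's method, initial conditions chosen to minimise
  the forward/backward edge discrepancy): the mode `filter_dataset` uses
  on epochs. On a bare 1.7 s epoch, padding-based filtering inverts the
  slow build-up and roughly doubles the window-mean noise, while the
  Gustafsson mode preserves the build-up's window mean within 2% and
  leaves the window-mean noise at its theoretical value.

An optional 0.5 Hz zero-phase high-pass (`highpass_zero_phase`) is
provided for drifting synthetic noise in place of baseline correction.

Only C3 and C4 are modelled. Average re-referencing, ocular ICA and bad
channel interpolation are preprocessing steps for raw 64-channel
recordings and have no synthetic counterpart here: the generator emits
clean channel-level epochs.

## Synthetic data generators

ERP trials (`synth_erp`). Each trial carries a shared background-noise
component on both channels plus an independent noise component per
channel (both white, sd 10 µV by default; a pink-noise option shapes the
spectrum as 1/√f). The shared component cancels exactly in the double
subtraction; the independent components set the recovery variance, which
scales as noise_sd/√(trials). The contralateral channel for the trial's
hand additionally carries a negative build-up ramp rising linearly from
−400 ms to response onset and held after it; the ramp is normalised so
that the window mean of the derived LRP equals the condition's target
amplitude **exactly** — defaults −1.13 µV (remembered) and −0.49 µV (new) — 
making the noiseless single-trial case an identity and the noisy
pipeline an unbiased estimator (verified over 20 replicates of 100
trials, recovered means within ±0.15 µV). A convex (`"quadratic"`) ramp
option models a build-up that steepens toward the response; the linear
default keeps amplitude control analytic.

Response times (`synth_rt`). Shifted lognormal: RT = floor + X with
floor = 150 ms and X lognormal, its two moments matched to the
condition's (mean − floor, sd) — defaults 852 ± 577 ms (remembered) and
957 ± 649 ms (new). The lognormal gives strict positivity above the floor
and the right skew characteristic of response times; matching is feasible
for any sd > 0 provided mean > floor, which is the validated condition.

Force-sensor traces (`synth_fsr`). Two channels (outer finger: object
contact during the sweep; inner finger: grasp) of baseline plus white
noise with step changes at scripted contact indices; scenarios are
validated to keep the step above 3× the noise sd so detection succeeds by
construction. The first half of the schedule is sweep 1, the second half
sweep 2 (entered after a forward step only when sweep 1 finds nothing).

What passing these tests shows — and does not. The generators reproduce
the statistical structure the pipeline assumes (condition-dependent ramp
amplitudes, RT moments, detectable sensor steps), so the tests establish
correctness of the computations, calibration and recovery machinery. They
do not establish performance on real recordings: real EEG has correlated
multi-channel noise, ocular and movement artifacts, drifting baselines
and trial-to-trial latency jitter, none of which are emulated; real FSR
traces have drift and contact bounce.

## Numerical and bookkeeping conventions

* Time grid: spikes are stamped at the end of the integrating step; step t
  covers (t−1, t]; `counts_per_ms[0]` is always 0.
* Threshold tie: V = v_thresh counts as a spike; go_time = deadline goes
  to the default action (strict precedence for the override).
* Windows: spike window trailing right-closed (t−w, t]; ERP analysis
  window half-open [start, end) ms.
* Degenerate inputs: regular graphs return rank slope 0 with a flag;
  empty datasets raise on derivation (after a warning at rejection);
  non-finite membrane potentials abort with a calibration diagnostic;
  non-ignition is a recorded outcome, not an error.
* Problem sizes: tests and the acceptance script use 10 assemblies × 11
  stimulation levels (sweep), 20 ERP replicates × 100 trials/condition,
  and 10⁵ RT samples — the scales at which the medians and means they
  check are stable.

## Known limitations

* The assembly is purely excitatory and static; ignition is all-or-none
  with no competition between assemblies and no way to model stopping an
  already-ignited action.
* The simulation clock is identified 1:1 with protocol time; real serial
  and servo latencies are folded into a single `comm_latency` scalar.
* The stimulated neurons are identical and perfectly synchronized, which
  quantises early recruitment into volleys; heterogeneous drive would
  smooth the cascade but add a parameter the calibration targets cannot
  constrain.
* The ignition-time scale (~100 ms) is an order of magnitude shorter than
  the human motor build-up (~400 ms); matching the time scale would
  require a larger or competitively inhibited assembly.
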