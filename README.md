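# neurorace

A neurorobotic decision chain in miniature: a spiking cell assembly whose
ignition time races a robot's default action, together with the
lateralized readiness potential (LRP) analysis that motivates it, and
synthetic-data generators that let the whole chain run and be tested
without hardware or human recordings.

## The science

Human actions are not binary switches: EEG over motor cortex shows a
negative-going build-up of activity — the LRP, measured as contralateral
minus ipsilateral voltage at electrodes C3/C4 — starting roughly 400 ms
before a unimanual response. Whether an action can still be overridden
depends on a race between processes (the independent horse-race model).
This package implements both sides of that idea:

* **Cell-assembly ignition.** A 500-neuron leaky integrate-and-fire
  network wired by preferential attachment ("rich get richer", 30
  synapses leaving each neuron, Zipf-like in-degrees) is simulated on a
  1 ms grid. Driving k neurons with a constant current produces a growing
  firing cascade; the assembly *ignites* when 1100 spikes land in a
  trailing 10 ms window. At the package's calibrated defaults, ignition
  occurs near 56 ms when k = 100 and near 102 ms when k = 50.
* **The race.** A mock robot (force-sensor driven explore–grasp state
  machine) grasps an object, sends a start signal, and begins its default
  move-right action at a deadline (80 ms). If ignition's go signal
  arrives strictly earlier, the robot moves left: k = 100 beats the
  deadline, k = 50 does not.
* **LRP derivation.** Epoched two-channel trials (−1500..+200 ms around
  response onset) are band-pass filtered (0.1–40 Hz, zero phase),
  artifact-rejected at ±100 µV, and double-subtracted (C3 − C4 for
  right-hand responses, C4 − C3 for left-hand) to recover the
  condition-wise motor build-up; summary amplitudes are means over the
  400 ms pre-response window (defaults: −1.13 µV for remembered items
  answered with the right hand, −0.49 µV for new items, left hand).

## Worked example

```python
>>> from neurorace import (generate_topology, LIFParams, StimulusSpec, SimConfig,
...                        simulate, choose_stimulated, IgnitionRule,
...                        detect_ignition, run_race, RaceConfig, DEFAULT_DRIVE)
>>> topo = generate_topology(500, 30, seed=1)         # calibrated weight on edges
>>> stim = StimulusSpec(choose_stimulated(500, 100, seed=7919 + 100), drive=DEFAULT_DRIVE)
>>> rec = simulate(topo, LIFParams(), stim, SimConfig(t_max=300), IgnitionRule())
>>> res = detect_ignition(rec)
>>> res.t_ignite, res.count_at_ignite
(58, 1171)
>>> run_race(res.t_ignite, RaceConfig(deadline=80.0)).action
'left'
```

The assembly ignites 58 ms after stimulation onset — 1171 spikes landed in
the trailing 10 ms window, crossing the 1100-spike threshold — and the go
signal beats the 80 ms default-action deadline, so the action is `left`.
With 50 stimulated neurons the same assembly ignites at 99 ms and the
outcome is `right` (`deadline-first`).

The same loop from the shell, end to end:

```bash
$ neurorace demo --k 50 --seed 1
...
{"state": "ignition", "t": 99, "count": 1150}
ACTION: RIGHT (deadline-first)

$ neurorace synth --kind rt --n 5000 --seed 3
remembered: mean 855.7 ms, sd 578.1 ms (n=5000)
new: mean 954.3 ms, sd 646.3 ms (n=5000)
```

Other subcommands: `neurorace sweep` (ignition time vs k over 10
assemblies, CSV + figure), `neurorace simulate --raster` (spike records
and a rastergram), `neurorace synth --kind erp` (synthetic epochs and
their recovered LRP amplitudes).

## Layout

| Module | Contents |
| --- | --- |
| `neurorace.topology` | preferential-attachment graph generator, degree statistics, CSV I/O |
| `neurorace.lif` | 1 ms-grid LIF network simulator, analytic single-neuron oracle, weight/drive calibration |
| `neurorace.decision` | ignition detection, horse race, robot state machine, start/go handshake |
| `neurorace.lrp` | zero-phase filtering, artifact rejection, LRP double subtraction |
| `neurorace.synth` | ERP / response-time / force-sensor generators |
| `neurorace.experiments` | ignition-time sweep and the end-to-end demo |
| `neurorace.cli` | `neurorace` command-line entry points |

See `docs/methods.md` for the models, parameter choices and limitations.
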