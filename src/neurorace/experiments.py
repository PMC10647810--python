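"""Orchestrated runs: the ignition-time sweep and the end-to-end demo.

The sweep measures how fast a 500-neuron assembly ignites as a function of
the number of externally stimulated neurons (50..100), repeated over
independently generated assemblies; the within-assembly design (the same
topology simulated at every k) isolates the stimulation effect from
topology-to-topology variance, and the across-assembly average curve is
smoother than any individual one.

The demo chains the whole decision loop: a synthetic force-sensor trace
drives the robot through explore and grasp, the grasp emits the start
signal, the start signal launches the assembly simulation, ignition emits
the go signal, and the go signal races the default move-right deadline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from neurorace.decision import (
    DecisionOutcome,
    FSRThresholds,
    IgnitionRule,
    RaceConfig,
    detect_ignition,
    robot_state_machine,
)
from neurorace.lif import (
    DEFAULT_DRIVE,
    DEFAULT_WEIGHT,
    LIFParams,
    SimConfig,
    StimulusSpec,
    choose_stimulated,
    simulate,
)
from neurorace.synth import FSRScenario, synth_fsr
from neurorace.topology import generate_topology

__all__ = ["SweepResult", "sweep_ignition", "run_demo"]


@dataclass(frozen=True)
class SweepResult:
    """Per-run ignition times plus the across-assembly average curve.

    ``runs`` has one row per (k, assembly seed) with the ignition time in ms
    (NaN when the run hit t_max without igniting); ``average`` has one row
    per k with the mean over ignited runs and an ``n_failed`` count, so
    non-ignitions are reported rather than silently censored.
    """

    runs: pd.DataFrame  # columns: k, seed, t_ignite
    average: pd.DataFrame  # columns: k, mean_t_ignite, n_ignited, n_failed


def sweep_ignition(
    k_values: Sequence[int] = tuple(range(50, 101, 5)),
    n_assemblies: int = 10,
    n_neurons: int = 500,
    k_out: int = 30,
    weight: float = DEFAULT_WEIGHT,
    drive: float = DEFAULT_DRIVE,
    params: LIFParams | None = None,
    rule: IgnitionRule | None = None,
    t_max: int = 300,
    base_seed: int = 0,
) -> SweepResult:
    """Ignition time for every (assembly, stimulated count) combination.

    Assembly ``i`` uses topology seed ``base_seed + i`` (i = 1..n_assemblies)
    and is simulated at every k on the SAME topology, with the stimulated
    subset drawn per (assembly, k) from the assembly seed.  Runs that reach
    ``t_max`` without igniting are recorded as NaN and counted in
    ``n_failed``; ignited runs enter the average curve.
    """
    params = params or LIFParams()
    rule = rule or IgnitionRule()
    rows = []
    for i in range(1, n_assemblies + 1):
        seed = base_seed + i
        topo = generate_topology(n_neurons, k_out, weight=weight, seed=seed)
        for k in k_values:
            stim = StimulusSpec(
                stimulated_ids=choose_stimulated(n_neurons, k, seed=seed * 7919 + k),
                drive=drive,
            )
            rec = simulate(topo, params, stim, SimConfig(t_max=t_max, seed=seed), rule)
            res = detect_ignition(rec, rule)
            rows.append(
                {"k": k, "seed": seed, "t_ignite": float(res.t_ignite) if res.ignited else np.nan}
            )
    runs = pd.DataFrame(rows)
    grouped = runs.groupby("k")["t_ignite"]
    average = pd.DataFrame(
        {
            "k": sorted(set(k_values)),
            "mean_t_ignite": grouped.mean().reindex(sorted(set(k_values))).to_numpy(),
            "n_ignited": grouped.count().reindex(sorted(set(k_values))).to_numpy(),
            "n_failed": grouped.apply(lambda s: int(s.isna().sum()))
            .reindex(sorted(set(k_values)))
            .to_numpy(),
        }
    )
    return SweepResult(runs=runs, average=average)


def run_demo(
    k: int = 100,
    deadline: float = 80.0,
    seed: int = 0,
    n_neurons: int = 500,
    k_out: int = 30,
    weight: float = DEFAULT_WEIGHT,
    drive: float = DEFAULT_DRIVE,
    comm_latency: float = 0.0,
    t_max: int = 300,
    scenario: FSRScenario | None = None,
) -> tuple[list[dict], DecisionOutcome]:
    """Full decision loop: sensor trace -> grasp -> start -> ignition -> race.

    Returns the robot's ordered action log (including the race outcome) and
    the :class:`DecisionOutcome`.  With the calibrated defaults and an 80 ms
    deadline, k=100 ignites in time to override the default and the robot
    goes left, while k=50 ignites too late and the robot goes right; k=0
    never ignites.
    """
    race = RaceConfig(deadline=deadline, comm_latency=comm_latency)
    rule = IgnitionRule()
    topo = generate_topology(n_neurons, k_out, weight=weight, seed=seed)
    stim = StimulusSpec(
        stimulated_ids=choose_stimulated(n_neurons, k, seed=seed * 7919 + k) if k else [],
        drive=drive if k else 1.0,
    )
    rec = simulate(topo, LIFParams(), stim, SimConfig(t_max=t_max, seed=seed), rule)
    res = detect_ignition(rec, rule)

    trace = synth_fsr(scenario or FSRScenario(seed=seed))
    go_events = [float(res.t_ignite)] if res.ignited else []
    log = robot_state_machine(trace, go_events, FSRThresholds(), race)
    log.insert(0, {"state": "demo-config", "k": k, "deadline": deadline, "seed": seed})
    if res.ignited:
        log.append({"state": "ignition", "t": res.t_ignite, "count": res.count_at_ignite})
    outcome = next(
        DecisionOutcome(action=e["state"], go_time=e["t"], reason=e["reason"])
        for e in log
        if e.get("state") in ("left", "right")
    )
    return log, outcome
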