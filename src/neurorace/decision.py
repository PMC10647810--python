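"""Ignition detection, the go/no-go horse race, and the robot state machine.

The cell assembly "ignites" when the population fires enough within a short
trailing window — here, 1100 spikes within the last 10 ms, evaluated on the
1 ms simulation grid.  Ignition generates the go-left signal, which races the
robot's default move-right action: if the go signal (plus communication
latency) arrives strictly before the default-action deadline, the robot moves
left; otherwise, or if the assembly never ignites, it moves right.  This is
the independent horse-race account of action selection, with the default
action playing the role of the process to beat.

The robot itself is emulated as the explore-grasp-move state machine of the
physical arm: sweep for the object (outer-finger force sensor), grasp it
(inner-finger sensor), send the start signal that launches the neural
simulation, lift, and move left or right depending on the race outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from neurorace.lif import SpikeRecord

__all__ = [
    "IgnitionRule",
    "IgnitionResult",
    "RaceConfig",
    "DecisionOutcome",
    "FSRThresholds",
    "window_count",
    "detect_ignition",
    "run_race",
    "robot_state_machine",
    "handshake_encode",
    "handshake_decode",
]


@dataclass(frozen=True)
class IgnitionRule:
    """Trailing spike-count criterion: ``threshold`` spikes in ``window`` ms."""

    window: int = 10  # ms, trailing and right-closed
    threshold: int = 1100  # population spikes

    def __post_init__(self) -> None:
        if self.window < 1 or self.threshold < 1:
            raise ValueError("window and threshold must be at least 1")


@dataclass(frozen=True)
class IgnitionResult:
    ignited: bool
    t_ignite: int | None  # ms of the first threshold crossing
    count_at_ignite: int | None  # window count at that ms


@dataclass(frozen=True)
class RaceConfig:
    """Timing of the default action and the go-signal path."""

    deadline: float = 80.0  # ms after the start signal; default-right begins here
    comm_latency: float = 0.0  # ms added to the go signal

    def __post_init__(self) -> None:
        if self.deadline <= 0:
            raise ValueError("deadline must be positive")
        if self.comm_latency < 0:
            raise ValueError("comm_latency must be non-negative")


@dataclass(frozen=True)
class DecisionOutcome:
    action: Literal["left", "right"]
    go_time: float | None  # ms; t_ignite + comm_latency, None without ignition
    reason: Literal["ignition-before-deadline", "deadline-first", "no-ignition"]


def window_count(record: SpikeRecord, t: int, window: int) -> int:
    """Number of spikes with time in the trailing right-closed window (t-window, t]."""
    counts = record.counts_per_ms
    lo = max(t - window + 1, 0)
    hi = min(t + 1, len(counts))
    if hi <= lo:
        return 0
    return int(counts[lo:hi].sum())


def detect_ignition(record: SpikeRecord, rule: IgnitionRule | None = None) -> IgnitionResult:
    """First millisecond at which the trailing window count reaches threshold.

    Scans the per-ms population counts with a running window sum; by the
    first-crossing property the count at every earlier millisecond is
    strictly below the threshold.
    """
    rule = rule or IgnitionRule()
    counts = record.counts_per_ms
    running = 0
    for t in range(len(counts)):
        running += int(counts[t])
        if t - rule.window >= 0:
            running -= int(counts[t - rule.window])
        if running >= rule.threshold:
            return IgnitionResult(ignited=True, t_ignite=t, count_at_ignite=running)
    return IgnitionResult(ignited=False, t_ignite=None, count_at_ignite=None)


def run_race(t_ignite: float | None, race: RaceConfig | None = None) -> DecisionOutcome:
    """Race the ignition-driven go signal against the default-action deadline.

    Left requires the go signal strictly before the deadline ("quickly
    enough"); ties and non-ignition fall through to the default right.
    """
    race = race or RaceConfig()
    if t_ignite is None:
        return DecisionOutcome(action="right", go_time=None, reason="no-ignition")
    go_time = t_ignite + race.comm_latency
    if go_time < race.deadline:
        return DecisionOutcome(action="left", go_time=go_time, reason="ignition-before-deadline")
    return DecisionOutcome(action="right", go_time=go_time, reason="deadline-first")


# --- start/go handshake ----------------------------------------------------

_TOKENS = {"start": b"S", "go": b"G"}
_MESSAGES = {v: k for k, v in _TOKENS.items()}


def handshake_encode(message: str) -> bytes:
    """Encode a start/go handshake message as its single-byte wire token."""
    try:
        return _TOKENS[message]
    except KeyError:
        raise ValueError(f"unknown handshake message: {message!r}") from None


def handshake_decode(token: bytes) -> str:
    """Decode a wire token back to its message; unknown bytes are rejected."""
    try:
        return _MESSAGES[bytes(token)]
    except KeyError:
        raise ValueError(f"unknown handshake token: {token!r}") from None


# --- robot state machine ---------------------------------------------------


@dataclass(frozen=True)
class FSRThresholds:
    """Minimum force-sensor reading changes that count as contact/grasp."""

    outer: float = 50.0  # sensor units above baseline: object touched during sweep
    inner: float = 50.0  # object secured between the gripper fingers


def robot_state_machine(
    fsr_trace: dict[str, np.ndarray],
    go_events: Iterable[float],
    thresholds: FSRThresholds | None = None,
    race: RaceConfig | None = None,
) -> list[dict]:
    """Drive the explore-grasp-move sequence from force-sensor readings.

    The trace has two channels sampled on a common index grid: ``outer``
    (object detection during the sweep) and ``inner`` (grasp detection).
    The sweep schedule is implicit in the trace: the first half of the
    samples is sweep 1, the second half sweep 2 (entered, after a small
    forward step, only when sweep 1 finds nothing).  Contact is a reading
    exceeding the channel's initial baseline by the configured threshold.

    ``go_events`` are go-signal emission times in ms after the start signal
    (ignition times on the simulation clock); the earliest one, plus
    ``race.comm_latency``, is raced against ``race.deadline``.  Returns the
    ordered action log: one dict per transition with ``state`` and trigger
    ``t`` (sample index for sensor-driven steps, ms after start for the race).
    """
    thresholds = thresholds or FSRThresholds()
    race = race or RaceConfig()
    outer = np.asarray(fsr_trace["outer"], dtype=float)
    inner = np.asarray(fsr_trace["inner"], dtype=float)
    log: list[dict] = []
    half = len(outer) // 2

    base_outer = outer[0]
    contact = np.nonzero(outer - base_outer >= thresholds.outer)[0]
    log.append({"state": "scan-sweep-1", "t": 0})
    if len(contact) == 0:
        log.append({"state": "object-not-found", "t": len(outer) - 1})
        return log
    t_contact = int(contact[0])
    if t_contact >= half:
        # nothing on the first sweep: step forward, sweep the other way
        log.append({"state": "forward-step", "t": half})
        log.append({"state": "scan-sweep-2", "t": half})
    log.append({"state": "detect", "t": t_contact})
    log.append({"state": "up", "t": t_contact})
    log.append({"state": "over", "t": t_contact})
    log.append({"state": "down", "t": t_contact})

    base_inner = inner[0]
    grasp = np.nonzero((inner - base_inner >= thresholds.inner) & (np.arange(len(inner)) > t_contact))[0]
    if len(grasp) == 0:
        log.append({"state": "object-not-found", "t": len(inner) - 1})
        return log
    t_grasp = int(grasp[0])
    log.append({"state": "grasp", "t": t_grasp})
    log.append({"state": "start-signal", "t": t_grasp, "token": handshake_encode("start").decode()})
    log.append({"state": "lift", "t": t_grasp})

    go_list = sorted(go_events)
    outcome = run_race(go_list[0] if go_list else None, race)
    log.append({"state": outcome.action, "t": outcome.go_time, "reason": outcome.reason})
    log.append({"state": "lower", "t": None})
    log.append({"state": "release", "t": None})
    return log
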