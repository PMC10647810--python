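"""Synthetic inputs: ERP epochs, response times and force-sensor traces.

These generators produce data with exactly the statistical structure the
analysis chain assumes, so every pipeline stage can be exercised — and its
parameter recovery quantified — without human recordings or hardware.

* :func:`synth_erp` builds two-channel (C3/C4) epochs around a response at
  0 ms.  Both channels share a common background-noise component (which the
  LRP double subtraction cancels) and carry independent channel noise (which
  it does not); the contralateral channel for the trial's hand additionally
  carries a negative motor build-up ramp starting 400 ms before the
  response.  The ramp is scaled so the expected mean of the derived LRP over
  the analysis window equals the condition's target amplitude exactly —
  default targets: -1.13 µV for remembered/right-hand trials, -0.49 µV for
  new/left-hand trials.
* :func:`synth_rt` draws response times from a shifted lognormal whose mean
  and standard deviation above a floor match the behavioural targets
  (remembered: 852 ± 577 ms, new: 957 ± 649 ms) — right-skewed and strictly
  positive, as reaction times are.
* :func:`synth_fsr` emits the outer/inner force-sensitive-resistor channels
  that drive the robot state machine: baseline noise with step changes at
  the contact and grasp times, detectable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from neurorace.lrp import CONDITION_HAND, ERPDataset, mean_window_amplitude

__all__ = [
    "SyntheticERPConfig",
    "SyntheticRTConfig",
    "FSRScenario",
    "synth_erp",
    "synth_rt",
    "synth_fsr",
]


@dataclass(frozen=True)
class SyntheticERPConfig:
    """Controls for the ERP generator.

    ``amplitudes`` maps condition -> target mean LRP over the analysis
    window in µV; ``noise_sd`` applies both to the shared background and to
    each channel's independent noise.
    """

    n_trials: int = 100  # per condition
    sampling_rate: float = 1000.0  # Hz
    epoch: tuple[float, float] = (-1500.0, 200.0)  # ms around response onset
    ramp_onset: float = -400.0  # ms; motor build-up begins here
    amplitudes: dict[str, float] = field(
        default_factory=lambda: {"remembered": -1.13, "new": -0.49}
    )
    analysis_window: tuple[float, float] = (-400.0, 0.0)
    noise_sd: float = 10.0  # µV
    ramp_shape: str = "linear"  # or "quadratic": steeper close to the response
    noise_color: str = "white"  # or "pink"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("need at least one trial per condition")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not (self.epoch[0] <= self.ramp_onset < self.epoch[1]):
            raise ValueError("ramp_onset must lie within the epoch")
        if self.ramp_shape not in ("linear", "quadratic"):
            raise ValueError("ramp_shape must be 'linear' or 'quadratic'")
        if self.noise_color not in ("white", "pink"):
            raise ValueError("noise_color must be 'white' or 'pink'")
        for cond in self.amplitudes:
            if cond not in CONDITION_HAND:
                raise ValueError(f"unknown condition {cond!r}")


def _unit_ramp(times_ms: np.ndarray, onset: float, shape: str) -> np.ndarray:
    """Build-up profile rising from 0 at onset to 1 at the response, held after."""
    x = np.clip((times_ms - onset) / (0.0 - onset), 0.0, None)
    x[times_ms >= 0] = 1.0
    if shape == "quadratic":
        x = np.where(times_ms < 0, x**2, x)
    return x


def _noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float, color: str) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape) * sd
    if color == "white":
        return white
    # pink: shape the spectrum by 1/sqrt(f), renormalised to the requested sd
    spectrum = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    f[0] = f[1]
    spectrum /= np.sqrt(f)
    out = np.fft.irfft(spectrum, n=shape[-1], axis=-1)
    out *= sd / out.std()
    return out


def synth_erp(config: SyntheticERPConfig | None = None) -> ERPDataset:
    """Generate epoched C3/C4 trials with a condition-dependent build-up.

    Each condition contributes ``n_trials`` trials with the task's
    condition-hand mapping (remembered -> right, new -> left).  The ramp is
    placed on the contralateral channel (C3 for right-hand trials, C4 for
    left-hand) and normalised so that, in expectation, the derived LRP's
    mean over ``analysis_window`` equals the condition's target amplitude;
    with ``noise_sd=0`` recovery is exact by construction.
    """
    config = config or SyntheticERPConfig()
    rng = np.random.default_rng(config.seed)
    step = 1000.0 / config.sampling_rate
    n_samples = round((config.epoch[1] - config.epoch[0]) / step)
    times = config.epoch[0] + step * np.arange(n_samples)

    unit = _unit_ramp(times, config.ramp_onset, config.ramp_shape)
    unit_mean = mean_window_amplitude(unit, config.analysis_window, times)

    trials, conditions, hands = [], [], []
    for cond, target in config.amplitudes.items():
        hand = CONDITION_HAND[cond]
        contra = "C3" if hand == "right" else "C4"
        ramp = (target / unit_mean) * unit
        for _ in range(config.n_trials):
            shared = _noise(rng, (n_samples,), config.noise_sd, config.noise_color)
            c3 = shared + _noise(rng, (n_samples,), config.noise_sd, config.noise_color)
            c4 = shared + _noise(rng, (n_samples,), config.noise_sd, config.noise_color)
            if contra == "C3":
                c3 = c3 + ramp
            else:
                c4 = c4 + ramp
            trials.append(np.stack([c3, c4]))
            conditions.append(cond)
            hands.append(hand)
    return ERPDataset(
        trials=np.array(trials),
        channels=("C3", "C4"),
        sampling_rate=config.sampling_rate,
        epoch=config.epoch,
        conditions=tuple(conditions),
        hands=tuple(hands),
    )


@dataclass(frozen=True)
class SyntheticRTConfig:
    """Shifted-lognormal response-time targets per condition (ms)."""

    means: dict[str, float] = field(default_factory=lambda: {"remembered": 852.0, "new": 957.0})
    sds: dict[str, float] = field(default_factory=lambda: {"remembered": 577.0, "new": 649.0})
    floor: float = 150.0  # ms; fastest physiologically plausible response
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same conditions")
        for cond, mean in self.means.items():
            if mean <= self.floor:
                raise ValueError(
                    f"condition {cond!r}: mean {mean} must exceed the floor {self.floor} "
                    "(moment matching infeasible)"
                )
            if self.sds[cond] <= 0:
                raise ValueError("sds must be positive")


def synth_rt(config: SyntheticRTConfig | None = None, n: int = 1000) -> dict[str, np.ndarray]:
    """Draw ``n`` response times per condition (ms), all above the floor.

    Samples are ``floor + X`` where X is lognormal with its first two
    moments matched to (mean - floor, sd): with m = mean - floor,
    ``sigma^2 = ln(1 + sd^2/m^2)`` and ``mu = ln m - sigma^2/2``.  Sample
    mean and sd converge to the configured targets as n grows.
    """
    config = config or SyntheticRTConfig()
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(config.seed)
    out: dict[str, np.ndarray] = {}
    for cond in config.means:
        m = config.means[cond] - config.floor
        sd = config.sds[cond]
        sigma2 = np.log1p((sd / m) ** 2)
        mu = np.log(m) - sigma2 / 2
        out[cond] = config.floor + rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    return out


@dataclass(frozen=True)
class FSRScenario:
    """Script for a force-sensor trace feeding the robot state machine.

    ``outer_contact``/``inner_contact`` are sample indices of the step
    change on each channel (None = no contact).  Contact steps must exceed
    3x the noise sd so detection succeeds by construction.
    """

    n_samples: int = 1000  # total sweep schedule length (sweep 1 + sweep 2)
    outer_contact: int | None = 300
    inner_contact: int | None = 600
    baseline: float = 100.0  # sensor units
    contact_level: float = 400.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("trace needs at least 2 samples")
        if abs(self.contact_level - self.baseline) <= 3 * self.noise_sd:
            raise ValueError("contact step must exceed 3x the noise sd to be detectable")
        for idx in (self.outer_contact, self.inner_contact):
            if idx is not None and not (0 < idx < self.n_samples):
                raise ValueError("contact indices must fall inside the trace")
        if (
            self.outer_contact is not None
            and self.inner_contact is not None
            and self.inner_contact <= self.outer_contact
        ):
            raise ValueError("grasp (inner) contact must come after sweep (outer) contact")


def synth_fsr(scenario: FSRScenario | None = None) -> dict[str, np.ndarray]:
    """Generate the outer/inner FSR reading series for a scenario."""
    scenario = scenario or FSRScenario()
    rng = np.random.default_rng(scenario.seed)
    outer = scenario.baseline + rng.standard_normal(scenario.n_samples) * scenario.noise_sd
    inner = scenario.baseline + rng.standard_normal(scenario.n_samples) * scenario.noise_sd
    if scenario.outer_contact is not None:
        outer[scenario.outer_contact :] += scenario.contact_level - scenario.baseline
    if scenario.inner_contact is not None:
        inner[scenario.inner_contact :] += scenario.contact_level - scenario.baseline
    return {"outer": outer, "inner": inner}
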