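"""Virtual transducers and actuators with calibrated error models.

Stand-ins for the rig's physical devices so the controller can be
exercised entirely in simulation: a stepper-driven syringe pump (drug
drops; tight tolerance, ~0.12 µL absolute error per 10 µL drop), a
gravity-fed valve (water drops; wider spread plus slow day-scale drift
that real rigs fix by recalibrating every few days), and a strain-gauge
load cell (gaussian reading noise plus occasional positively biased
movement transients, clipped at the 780 g capacity).

Every stochastic component draws from an explicit numpy Generator so runs
are reproducible and components can be re-seeded independently; with all
noise parameters at zero the devices are exactly deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EmptySyringeError(RuntimeError):
    """Dispense requested from an exhausted syringe (hardware fault)."""


@dataclass(slots=True)
class PumpModel:
    """Stepper-driven syringe pump: 57 steps push one 10 µL drop from a
    30 mL syringe; realized volume is linear in commanded steps."""

    steps_per_drop: int = 57
    nominal_drop_ul: float = 10.0
    volume_error_sd_ul: float = 0.12
    syringe_remaining_ul: float = 30_000.0
    total_dispensed_ul: float = 0.0


def pump_dispense(steps: int, pump: PumpModel, rng: np.random.Generator) -> float:
    """Dispense *steps* motor steps; returns the realized volume in µL."""
    if steps <= 0:
        raise ValueError("steps must be > 0")
    if pump.syringe_remaining_ul <= 0:
        raise EmptySyringeError("syringe is empty")
    volume = pump.nominal_drop_ul * steps / pump.steps_per_drop
    if pump.volume_error_sd_ul > 0:
        volume += rng.normal(0.0, pump.volume_error_sd_ul)
    volume = max(volume, 0.0)
    volume = min(volume, pump.syringe_remaining_ul)
    pump.syringe_remaining_ul -= volume
    pump.total_dispensed_ul += volume
    return volume


@dataclass(slots=True)
class ValveModel:
    """Gravity-fed water valve: per-drop relative spread plus slow
    multiplicative drift (reservoir level / line resistance changes)."""

    nominal_drop_ul: float = 10.0
    size_cv: float = 0.05
    drift_rate_per_day: float = 0.02
    last_recalibration_s: float = 0.0
    total_dispensed_ul: float = 0.0


def valve_dispense(valve: ValveModel, t_s: float, rng: np.random.Generator) -> float:
    """Dispense one water drop at time *t_s* (seconds); returns µL."""
    days = (t_s - valve.last_recalibration_s) / 86_400.0
    volume = valve.nominal_drop_ul * (1.0 + valve.drift_rate_per_day * days)
    if valve.size_cv > 0:
        volume *= 1.0 + rng.normal(0.0, valve.size_cv)
    volume = max(volume, 0.0)
    valve.total_dispensed_ul += volume
    return volume


def recalibrate_valve(valve: ValveModel, t_s: float) -> None:
    """Reset valve drift (models the periodic manual recalibration)."""
    valve.last_recalibration_s = t_s


@dataclass(slots=True)
class LoadCellModel:
    """Strain-gauge load cell under the dosing module.

    ``noise_sd_g`` is animal-movement noise: it applies only while a mass
    is on the platform (an empty module reads quietly, which is what makes
    the 20-reading stability test for automatic taring passable).
    ``sensor_noise_sd_g`` is the small intrinsic electronic noise, always
    present.  Transients model a mouse rearing, climbing on the module or
    entering partially: positively biased offsets drawn uniformly from
    ``transient_range_g``; they can strike empty-module readings too
    (external contact), which is what occasionally vetoes a tare.
    """

    noise_sd_g: float = 0.2
    sensor_noise_sd_g: float = 0.01
    transient_prob: float = 0.05
    transient_range_g: tuple[float, float] = (3.0, 20.0)
    zero_offset_g: float = 0.0
    capacity_g: float = 780.0


def load_cell_read(true_mass_g: float, model: LoadCellModel, rng: np.random.Generator) -> float:
    """One reading of *true_mass_g* grams through the noise model."""
    if true_mass_g < 0:
        raise ValueError("true_mass_g must be >= 0")
    reading = true_mass_g + model.zero_offset_g
    if model.sensor_noise_sd_g > 0:
        reading += rng.normal(0.0, model.sensor_noise_sd_g)
    if true_mass_g > 0 and model.noise_sd_g > 0:
        reading += rng.normal(0.0, model.noise_sd_g)
    if model.transient_prob > 0 and rng.random() < model.transient_prob:
        lo, hi = model.transient_range_g
        reading += rng.uniform(lo, hi)
    return min(reading, model.capacity_g)


def tare(model: LoadCellModel) -> None:
    """Re-zero the load cell (valid only when the module is empty)."""
    model.zero_offset_g = 0.0


@dataclass(slots=True)
class VirtualHardware:
    """The full bench: one pump, one valve, one load cell, seeded streams."""

    pump: PumpModel = field(default_factory=PumpModel)
    valve: ValveModel = field(default_factory=ValveModel)
    load_cell: LoadCellModel = field(default_factory=LoadCellModel)
    rng_pump: np.random.Generator = field(default_factory=np.random.default_rng)
    rng_valve: np.random.Generator = field(default_factory=np.random.default_rng)
    rng_cell: np.random.Generator = field(default_factory=np.random.default_rng)

    @classmethod
    def seeded(cls, seed: int, *, noise_free: bool = False) -> "VirtualHardware":
        """Build a bench with per-component streams fanned out from *seed*."""
        ss = np.random.SeedSequence(seed)
        s_pump, s_valve, s_cell = ss.spawn(3)
        hw = cls(
            rng_pump=np.random.default_rng(s_pump),
            rng_valve=np.random.default_rng(s_valve),
            rng_cell=np.random.default_rng(s_cell),
        )
        if noise_free:
            hw.pump.volume_error_sd_ul = 0.0
            hw.valve.size_cv = 0.0
            hw.valve.drift_rate_per_day = 0.0
            hw.load_cell.noise_sd_g = 0.0
            hw.load_cell.sensor_noise_sd_g = 0.0
            hw.load_cell.transient_prob = 0.0
        return hw

    def dispense(self, kind: str, t_s: float, steps: int) -> float:
        """Resolve a dispense command; returns realized volume in µL."""
        if kind == "drug":
            return pump_dispense(steps, self.pump, self.rng_pump)
        return valve_dispense(self.valve, t_s, self.rng_valve)

    def read_weight(self, true_mass_g: float) -> float:
        return load_cell_read(true_mass_g, self.load_cell, self.rng_cell)
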