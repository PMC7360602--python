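"""Daily drug-drop quota computation and lick-by-lick drop-type choice.

The closed loop: each midnight the mouse's estimated bodyweight sets an
integer quota of drug drops for the coming day (dose in mg/kg divided by
the per-drop drug mass).  Drug drops are delivered first, starting at
midnight, until the quota is met; every further lick earns a water drop.
An optional interleave parameter spaces drug drops out so that only every
n-th drop can be drug, spreading administration across the day.

With the default parameters (1 mg/kg/day, 50 µg/mL, 10 µL drops → 0.5 µg
per drop) the quota works out to two drops per gram of bodyweight, so a
0.5 g weight increase adds exactly one daily drop.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

from .config import MouseProfile, SystemConfig
from .events import DailyMouseState


@dataclass(frozen=True, slots=True)
class DoseSchedule:
    mouse_tag: str
    date: dt.date
    weight_used_g: float | None
    quota_drug_drops: int
    ug_per_drop: float


def required_drug_drops(weight_g: float, dose_mg_per_kg: float, config: SystemConfig) -> int:
    """Integer drug-drop quota hitting *dose_mg_per_kg* at *weight_g*.

    Rounds to the nearest drop with ties up: with the default 0.5 µg drop
    quantum this places quota steps exactly on 0.5 g weight boundaries.
    """
    if dose_mg_per_kg == 0:
        return 0
    if dose_mg_per_kg < 0:
        raise ValueError("dose_mg_per_kg must be >= 0")
    ug_per_drop = config.ug_per_drop
    if ug_per_drop <= 0:
        raise ValueError(
            "nonzero dose requires positive drug concentration and drop volume"
        )
    # required mass in µg: dose[mg/kg] * weight[g] = dose * weight in µg
    exact = dose_mg_per_kg * weight_g / ug_per_drop
    return int(math.floor(exact + 0.5))


def next_drop_type(
    state: DailyMouseState, profile: MouseProfile, config: SystemConfig, *, past_baseline: bool = True
) -> str:
    """Decide whether the next dispensed drop is ``"drug"`` or ``"water"``.

    Drug iff the day's quota is unmet, the mouse is a dosed subject past
    its baseline period, and the day's total drop counter sits on an
    interleave boundary (counter % n == 0, so drug occupies positions
    0, n, 2n, ...).
    """
    if (
        past_baseline
        and profile.effective_dose_mg_per_kg > 0
        and not state.quota_met
        and state.drop_counter % config.drug_interleave_n == 0
    ):
        return "drug"
    return "water"


def rollover_day(
    previous_state: DailyMouseState | None,
    new_weight_estimate_g: float | None,
    profile: MouseProfile,
    config: SystemConfig,
    date: dt.date,
    *,
    day_index: int,
) -> tuple[DailyMouseState, DoseSchedule]:
    """Open a fresh dosing day at the midnight boundary.

    ``day_index`` counts days since the mouse entered the cage; days with
    ``day_index < baseline_day_count`` are baseline days with quota 0.
    When no new estimate is available the previous day's weight is carried
    forward; with no weight at all the quota stays 0 (never dose an
    unweighed mouse).
    """
    if new_weight_estimate_g is not None:
        weight = new_weight_estimate_g
    elif previous_state is not None and previous_state.daily_weight_g is not None:
        weight = previous_state.daily_weight_g
    else:
        weight = None

    baseline = day_index < profile.baseline_day_count
    dose = profile.effective_dose_mg_per_kg
    if baseline or dose == 0 or weight is None:
        quota = 0
    else:
        quota = required_drug_drops(weight, dose, config)

    state = DailyMouseState(date=date, quota_drug_drops=quota, daily_weight_g=weight)
    schedule = DoseSchedule(
        mouse_tag=profile.rfid_tag,
        date=date,
        weight_used_g=weight,
        quota_drug_drops=quota,
        ug_per_drop=config.ug_per_drop,
    )
    return state, schedule


def delivered_dose_mg_per_kg(drug_drops: int, config: SystemConfig, weight_g: float) -> float:
    """Dose actually delivered by *drug_drops* drops to a *weight_g* mouse,
    in mg per kg of bodyweight."""
    if weight_g <= 0:
        raise ValueError("weight_g must be > 0")
    mg = drug_drops * config.ug_per_drop / 1000.0
    kg = weight_g / 1000.0
    return mg / kg
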