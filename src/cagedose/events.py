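"""Core record types shared across the controller, simulator and log I/O.

Events form the ground-truth stream of everything that happens at the
dosing module; weight samples are individual 5 Hz load-cell readings;
``DailyMouseState`` holds the per-day counters that gate dosing.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field


class EventCode(str, enum.Enum):
    """Closed vocabulary of loggable events."""

    ENTRY = "ENTRY"
    EXIT = "EXIT"
    LICK = "LICK"
    DROP_WATER = "DROP_WATER"
    DROP_DRUG = "DROP_DRUG"
    TARE = "TARE"
    RFID_FAIL = "RFID_FAIL"
    REBOOT = "REBOOT"
    IMAGE = "IMAGE"


#: Sentinel mouse tag for cage-level events (RFID failures, reboots, tares).
CAGE_TAG = "CAGE"


@dataclass(frozen=True, slots=True)
class Event:
    timestamp: dt.datetime
    mouse_tag: str
    code: EventCode
    payload: str = ""


@dataclass(frozen=True, slots=True)
class WeightSample:
    """One raw load-cell reading in grams; may lie outside the plausible
    bodyweight range (filtering happens in weight estimation)."""

    timestamp: dt.datetime
    grams: float


@dataclass(slots=True)
class DailyMouseState:
    """Per-mouse counters for one dosing day.

    ``drop_counter`` (total drops so far today) drives drug/water
    interleaving; ``weight_buffer`` accumulates the rolling 24 h of
    load-cell readings from which the midnight estimate is computed.
    """

    date: dt.date
    quota_drug_drops: int = 0
    drug_drops: int = 0
    water_drops: int = 0
    weight_buffer: list[WeightSample] = field(default_factory=list)
    daily_weight_g: float | None = None

    @property
    def drop_counter(self) -> int:
        return self.drug_drops + self.water_drops

    @property
    def quota_met(self) -> bool:
        return self.drug_drops >= self.quota_drug_drops
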