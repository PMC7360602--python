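"""Event-driven session controller for the dosing module.

Tracks which mouse (if any) currently occupies the module via the RFID
tag-in-range signal, gates lick-triggered drop delivery behind the
post-drop lockout, manages the post-exit wait and automatic taring, and
emits every loggable event.

The controller is clock-agnostic: it consumes a time-ordered stream of
sensor signals (tag reads, licks, load-cell ticks, elapsed deadlines, day
boundaries) and produces events plus dispense commands, so the same code
runs against the virtual cage or real hardware.  Identical input streams
yield identical output logs.

Safety properties enforced here and checked over full simulated runs:

* no drop is ever dispensed without a currently confirmed tag;
* inter-drop intervals are at least the lockout;
* daily drug drops never exceed the day's quota;
* every drop is immediately followed by exactly one validation image;
* a reboot (after repeated unreadable RFID reads) resets session state
  but re-reads persisted daily counters, so it can never double-dose.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Callable, Sequence

from .config import MouseProfile, SystemConfig
from .events import CAGE_TAG, DailyMouseState, Event, EventCode, WeightSample
from .scheduler import DoseSchedule, next_drop_type, rollover_day
from .weights import WeightEstimate, daily_weight_estimate, should_tare


class SessionPhase(enum.Enum):
    IDLE = "IDLE"
    OCCUPIED = "OCCUPIED"
    EXIT_WAIT = "EXIT_WAIT"


@dataclass(frozen=True, slots=True)
class DispenseCommand:
    """Instruction to the actuator layer produced by a rewarded lick."""

    mouse_tag: str
    kind: str  # "drug" | "water"
    timestamp: dt.datetime


@dataclass(frozen=True, slots=True)
class CompletedDay:
    """Archived record of one mouse-day, persisted across reboots."""

    mouse_tag: str
    state: DailyMouseState
    schedule: DoseSchedule
    estimate: WeightEstimate | None
    carried_forward: bool


class SessionController:
    """State machine driving one dosing module.

    Parameters
    ----------
    config, profiles
        Validated system parameters and the cage's mouse registry.
    start_time
        Clock time at which the run begins; the first dosing day opens
        here (day 0, which is a baseline day for every mouse by default).
    dispenser
        Optional callback ``(kind, timestamp) -> realized volume µL``
        resolving dispense commands against (virtual) hardware.  Without
        one, drop events carry the nominal drop volume.
    on_tare
        Optional callback invoked when the load cell is tared.
    """

    def __init__(
        self,
        config: SystemConfig,
        profiles: Sequence[MouseProfile],
        start_time: dt.datetime,
        *,
        dispenser: Callable[[str, dt.datetime], float] | None = None,
        on_tare: Callable[[], None] | None = None,
    ) -> None:
        self.config = config
        self.profiles = {p.rfid_tag: p for p in profiles}
        self.dispenser = dispenser
        self.on_tare = on_tare

        self.phase = SessionPhase.IDLE
        self.current_tag: str | None = None
        self.lockout_until: dt.datetime | None = None
        self.failed_read_count = 0
        self.exit_wait_deadline: dt.datetime | None = None

        self.events: list[Event] = []
        self.day_history: list[CompletedDay] = []
        self.schedules: list[DoseSchedule] = []
        self._last_t: dt.datetime | None = None

        # persistent per-mouse stores (survive reboots)
        self._day_index: dict[str, int] = {}
        self.daily: dict[str, DailyMouseState] = {}
        self._last_weight: dict[str, float | None] = {}
        date = start_time.date()
        for tag, profile in self.profiles.items():
            self._day_index[tag] = 0
            state, schedule = rollover_day(
                None, None, profile, config, date, day_index=0
            )
            self.daily[tag] = state
            self._last_weight[tag] = None
            self.schedules.append(schedule)

    # ------------------------------------------------------------------ utils

    def _emit(self, t: dt.datetime, tag: str, code: EventCode, payload: str = "") -> None:
        if self._last_t is not None and t < self._last_t:
            raise ValueError(f"non-monotone event time: {t} < {self._last_t}")
        self._last_t = t
        self.events.append(Event(timestamp=t, mouse_tag=tag, code=code, payload=payload))

    def _close_session(self, t: dt.datetime) -> None:
        if self.current_tag is not None:
            self._emit(t, self.current_tag, EventCode.EXIT)
        self.current_tag = None

    # ---------------------------------------------------------------- signals

    def on_tag_in_range(self, tag_read: str | None, t: dt.datetime) -> None:
        """Handle a completed RFID read triggered by the tag-in-range signal.

        ``tag_read`` is the decoded tag or ``None`` for an unreadable read.
        Unregistered tags are treated as unreadable: logged, never dosed.
        """
        if tag_read is None or tag_read not in self.profiles:
            self.failed_read_count += 1
            self._emit(t, CAGE_TAG, EventCode.RFID_FAIL, payload=tag_read or "")
            if self.failed_read_count >= self.config.max_failed_reads:
                self._reboot(t)
            return

        self.failed_read_count = 0
        if self.phase is SessionPhase.OCCUPIED:
            if tag_read == self.current_tag:
                return  # silent confirmation of the same mouse
            # a different confirmed tag closes the old session implicitly
            self._close_session(t)
        self.phase = SessionPhase.OCCUPIED
        self.current_tag = tag_read
        self.exit_wait_deadline = None
        self._emit(t, tag_read, EventCode.ENTRY)

    def on_lick(self, t: dt.datetime) -> DispenseCommand | None:
        """Handle a capacitive lick signal; may dispense one drop."""
        if self.phase is not SessionPhase.OCCUPIED or self.current_tag is None:
            return None  # no identified subject: never dispense
        self._emit(t, self.current_tag, EventCode.LICK)
        if self.lockout_until is not None and t < self.lockout_until:
            return None
        tag = self.current_tag
        profile = self.profiles[tag]
        state = self.daily[tag]
        past_baseline = self._day_index[tag] >= profile.baseline_day_count
        kind = next_drop_type(state, profile, self.config, past_baseline=past_baseline)
        if self.dispenser is not None:
            volume = self.dispenser(kind, t)
        else:
            volume = self.config.drop_volume_ul
        if kind == "drug":
            state.drug_drops += 1
            code = EventCode.DROP_DRUG
        else:
            state.water_drops += 1
            code = EventCode.DROP_WATER
        self._emit(t, tag, code, payload=f"{volume:.3f}")
        self._emit(t, tag, EventCode.IMAGE, payload="spout_photo")
        self.lockout_until = t + dt.timedelta(seconds=self.config.lockout_s)
        return DispenseCommand(mouse_tag=tag, kind=kind, timestamp=t)

    def on_tag_out_of_range(self, t: dt.datetime) -> None:
        """The occupant left: stop weight collection, start the exit wait."""
        if self.phase is not SessionPhase.OCCUPIED:
            return
        self._close_session(t)
        self.phase = SessionPhase.EXIT_WAIT
        self.exit_wait_deadline = t + dt.timedelta(seconds=self.config.exit_wait_s)

    def on_exit_wait_elapsed(
        self, t: dt.datetime, load_cell_reader: Callable[[int], Sequence[float]]
    ) -> None:
        """Exit wait ran out with no mouse detected: test stability and tare.

        ``load_cell_reader(n)`` returns *n* fresh readings of the (empty)
        module.  Whatever the outcome, the controller returns to IDLE.
        """
        if self.phase is not SessionPhase.EXIT_WAIT:
            return
        if self.exit_wait_deadline is not None and t < self.exit_wait_deadline:
            return
        readings = load_cell_reader(self.config.tare_sample_count)
        if should_tare(readings, self.config):
            if self.on_tare is not None:
                self.on_tare()
            self._emit(t, CAGE_TAG, EventCode.TARE)
        self.phase = SessionPhase.IDLE
        self.exit_wait_deadline = None

    def on_weight_tick(self, t: dt.datetime, reading_g: float) -> None:
        """One 5 Hz load-cell reading; buffered only while OCCUPIED and
        attributed to the currently confirmed tag."""
        if self.phase is not SessionPhase.OCCUPIED or self.current_tag is None:
            return
        self.daily[self.current_tag].weight_buffer.append(
            WeightSample(timestamp=t, grams=reading_g)
        )

    def on_day_rollover(self, t: dt.datetime) -> None:
        """Midnight boundary: estimate each mouse's weight from the past
        day's buffer, archive the day, and open a new one with a fresh
        quota.  A buffer yielding no estimate carries the previous weight
        forward.  An in-progress session continues; its weight buffer is
        split at the boundary and subsequent drops count against the new
        day."""
        date = t.date()
        for tag, profile in self.profiles.items():
            old = self.daily[tag]
            estimate = daily_weight_estimate(
                old.weight_buffer, self.config, mouse_tag=tag, date=old.date
            )
            carried = estimate is None
            new_weight = estimate.grams if estimate is not None else None
            old.daily_weight_g = (
                new_weight if new_weight is not None else self._last_weight[tag]
            )
            self.day_history.append(
                CompletedDay(
                    mouse_tag=tag,
                    state=old,
                    schedule=self._schedule_for(tag, old.date),
                    estimate=estimate,
                    carried_forward=carried,
                )
            )
            if new_weight is not None:
                self._last_weight[tag] = new_weight
            self._day_index[tag] += 1
            prev = DailyMouseState(
                date=old.date, daily_weight_g=self._last_weight[tag]
            )
            state, schedule = rollover_day(
                prev,
                new_weight,
                profile,
                self.config,
                date,
                day_index=self._day_index[tag],
            )
            self.daily[tag] = state
            self.schedules.append(schedule)

    def finalize(self, t: dt.datetime) -> None:
        """Archive the current (possibly partial) day at the end of a run."""
        for tag in self.profiles:
            old = self.daily[tag]
            estimate = daily_weight_estimate(
                old.weight_buffer, self.config, mouse_tag=tag, date=old.date
            )
            old.daily_weight_g = (
                estimate.grams if estimate is not None else self._last_weight[tag]
            )
            self.day_history.append(
                CompletedDay(
                    mouse_tag=tag,
                    state=old,
                    schedule=self._schedule_for(tag, old.date),
                    estimate=estimate,
                    carried_forward=estimate is None,
                )
            )

    # ------------------------------------------------------------------ misc

    def _schedule_for(self, tag: str, date: dt.date) -> DoseSchedule:
        for sched in reversed(self.schedules):
            if sched.mouse_tag == tag and sched.date == date:
                return sched
        raise KeyError(f"no schedule recorded for {tag} on {date}")

    def _reboot(self, t: dt.datetime) -> None:
        """Automatic reboot after too many failed reads.

        Session state resets; the persisted per-mouse daily counters are
        re-read unchanged, so delivered-drop counts survive and the mouse
        cannot be double-dosed."""
        self._emit(t, CAGE_TAG, EventCode.REBOOT)
        self.phase = SessionPhase.IDLE
        self.current_tag = None
        self.lockout_until = None
        self.failed_read_count = 0
        self.exit_wait_deadline = None
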