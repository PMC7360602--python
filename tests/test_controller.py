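"""Session state machine: occupancy tracking, lockout, exit wait, taring,
RFID failure handling, and safety properties over scripted streams."""

import datetime as dt

import pytest

from cagedose import (
    CAGE_TAG,
    EventCode,
    SessionController,
    SessionPhase,
    SystemConfig,
)

T0 = dt.datetime(2020, 1, 1, 8, 0, 0)


def at(seconds: float) -> dt.datetime:
    return T0 + dt.timedelta(seconds=seconds)


def make_controller(config, profiles, **kw):
    return SessionController(config, profiles, dt.datetime(2020, 1, 1), **kw)


def codes(ctrl):
    return [ev.code for ev in ctrl.events]


@pytest.fixture
def ctrl(config, treatment_profile, control_profile):
    return make_controller(config, [treatment_profile, control_profile])


@pytest.fixture
def dosed_ctrl(config, treatment_profile, control_profile):
    """Controller advanced past baseline with an active quota of 50."""
    c = make_controller(config, [treatment_profile, control_profile])
    c._last_weight["T001"] = 25.0
    c.daily["T001"].daily_weight_g = 25.0
    c.on_day_rollover(dt.datetime(2020, 1, 2))
    assert c.daily["T001"].quota_drug_drops == 50
    return c


class TestTagInRange:
    def test_known_tag_opens_session(self, ctrl):
        ctrl.on_tag_in_range("T001", at(0))
        assert ctrl.phase is SessionPhase.OCCUPIED
        assert ctrl.current_tag == "T001"
        assert codes(ctrl) == [EventCode.ENTRY]

    def test_same_tag_confirmation_is_silent(self, ctrl):
        ctrl.on_tag_in_range("T001", at(0))
        ctrl.on_tag_in_range("T001", at(1))
        assert codes(ctrl) == [EventCode.ENTRY]

    def test_different_tag_closes_and_reopens(self, ctrl):
        ctrl.on_tag_in_range("T001", at(0))
        ctrl.on_tag_in_range("C001", at(5))
        assert codes(ctrl) == [EventCode.ENTRY, EventCode.EXIT, EventCode.ENTRY]
        assert ctrl.current_tag == "C001"

    def test_unreadable_and_unknown_tags_logged_never_dosed(self, ctrl):
        ctrl.on_tag_in_range(None, at(0))
        ctrl.on_tag_in_range("GHOST", at(1))
        assert codes(ctrl) == [EventCode.RFID_FAIL] * 2
        assert ctrl.phase is SessionPhase.IDLE
        assert ctrl.on_lick(at(2)) is None  # no subject: no drop

    def test_reboot_after_max_failed_reads_resets_session_state(self, ctrl):
        for i in range(10):
            ctrl.on_tag_in_range(None, at(i))
        assert EventCode.REBOOT in codes(ctrl)
        assert ctrl.failed_read_count == 0
        assert ctrl.phase is SessionPhase.IDLE

    def test_reboot_preserves_daily_counters(self, dosed_ctrl):
        dosed_ctrl.on_tag_in_range("T001", at(0))
        dosed_ctrl.on_lick(at(1))
        drug_before = dosed_ctrl.daily["T001"].drug_drops
        assert drug_before == 1
        for i in range(10):
            dosed_ctrl.on_tag_in_range(None, at(10 + i))
        assert dosed_ctrl.daily["T001"].drug_drops == drug_before


class TestLick:
    def test_lick_dispenses_drug_then_images_and_locks_out(self, dosed_ctrl):
        dosed_ctrl.on_tag_in_range("T001", at(0))
        cmd = dosed_ctrl.on_lick(at(1))
        assert cmd is not None and cmd.kind == "drug"
        assert codes(dosed_ctrl)[-3:] == [
            EventCode.LICK,
            EventCode.DROP_DRUG,
            EventCode.IMAGE,
        ]
        # image shares the drop's timestamp
        assert dosed_ctrl.events[-1].timestamp == dosed_ctrl.events[-2].timestamp
        assert dosed_ctrl.lockout_until == at(11)

    def test_lick_during_lockout_logged_but_not_rewarded(self, dosed_ctrl):
        dosed_ctrl.on_tag_in_range("T001", at(0))
        dosed_ctrl.on_lick(at(1))
        cmd = dosed_ctrl.on_lick(at(5))  # 4 s after drop, lockout 10 s
        assert cmd is None
        assert codes(dosed_ctrl)[-1] == EventCode.LICK
        assert dosed_ctrl.daily["T001"].drop_counter == 1

    def test_lick_without_occupant_is_ignored(self, ctrl):
        assert ctrl.on_lick(at(0)) is None
        assert ctrl.events == []

    def test_control_mouse_gets_water(self, dosed_ctrl):
        dosed_ctrl.on_tag_in_range("C001", at(0))
        cmd = dosed_ctrl.on_lick(at(1))
        assert cmd.kind == "water"

    def test_baseline_day_delivers_water_despite_treatment_group(self, ctrl):
        ctrl.on_tag_in_range("T001", at(0))
        cmd = ctrl.on_lick(at(1))  # day 0 is the baseline day
        assert cmd.kind == "water"

    def test_drug_stops_exactly_at_quota(self, dosed_ctrl):
        dosed_ctrl.on_tag_in_range("T001", at(0))
        kinds = []
        for i in range(60):
            cmd = dosed_ctrl.on_lick(at(1 + 11 * i))
            kinds.append(cmd.kind)
        assert kinds[:50] == ["drug"] * 50
        assert kinds[50:] == ["water"] * 10


class TestExitAndTare:
    def test_exit_starts_wait_then_stable_readings_tare(self, ctrl, config):
        ctrl.on_tag_in_range("T001", at(0))
        ctrl.on_tag_out_of_range(at(60))
        assert ctrl.phase is SessionPhase.EXIT_WAIT
        assert ctrl.exit_wait_deadline == at(90)
        tared = []
        ctrl.on_tare = lambda: tared.append(True)
        ctrl.on_exit_wait_elapsed(at(90), lambda n: [0.0] * n)
        assert tared and codes(ctrl)[-1] == EventCode.TARE
        assert ctrl.phase is SessionPhase.IDLE

    def test_unstable_reading_vetoes_tare(self, ctrl):
        ctrl.on_tag_in_range("T001", at(0))
        ctrl.on_tag_out_of_range(at(60))
        ctrl.on_exit_wait_elapsed(at(90), lambda n: [0.0] * (n - 1) + [0.15])
        assert EventCode.TARE not in codes(ctrl)
        assert ctrl.phase is SessionPhase.IDLE

    def test_reentry_during_wait_returns_to_occupied(self, ctrl):
        ctrl.on_tag_in_range("T001", at(0))
        ctrl.on_tag_out_of_range(at(60))
        ctrl.on_tag_in_range("T001", at(65))
        assert ctrl.phase is SessionPhase.OCCUPIED
        assert ctrl.exit_wait_deadline is None

    def test_out_of_range_while_idle_is_ignored(self, ctrl):
        ctrl.on_tag_out_of_range(at(0))
        assert ctrl.events == [] and ctrl.phase is SessionPhase.IDLE


class TestWeightTicks:
    def test_occupied_ticks_buffer_samples(self, ctrl):
        ctrl.on_tag_in_range("T001", at(0))
        for i in range(300):  # 60 s at 5 Hz
            ctrl.on_weight_tick(at(0.2 * (i + 1)), 25.0)
        assert len(ctrl.daily["T001"].weight_buffer) == 300

    def test_idle_tick_is_noop(self, ctrl):
        ctrl.on_weight_tick(at(0), 25.0)
        assert all(not s.weight_buffer for s in ctrl.daily.values())

    def test_samples_follow_the_confirmed_tag(self, ctrl):
        ctrl.on_tag_in_range("T001", at(0))
        ctrl.on_weight_tick(at(1), 25.0)
        ctrl.on_tag_in_range("C001", at(2))
        ctrl.on_weight_tick(at(3), 30.0)
        assert len(ctrl.daily["T001"].weight_buffer) == 1
        assert len(ctrl.daily["C001"].weight_buffer) == 1


class TestRolloverSemantics:
    def test_rollover_splits_weight_buffer_mid_session(self, ctrl):
        ctrl.on_tag_in_range("T001", at(0))
        ctrl.on_weight_tick(at(1), 25.0)
        ctrl.on_day_rollover(dt.datetime(2020, 1, 2))
        ctrl.on_weight_tick(dt.datetime(2020, 1, 2, 0, 0, 5), 25.0)
        assert ctrl.phase is SessionPhase.OCCUPIED
        assert len(ctrl.daily["T001"].weight_buffer) == 1
        assert ctrl.day_history[0].state.date == dt.date(2020, 1, 1)

    def test_quota_appears_after_baseline_with_estimate(self, ctrl, config):
        ctrl.on_tag_in_range("T001", at(0))
        for i in range(100):
            ctrl.on_weight_tick(at(0.2 * (i + 1)), 25.0)
        ctrl.on_day_rollover(dt.datetime(2020, 1, 2))
        assert ctrl.daily["T001"].quota_drug_drops == 50

    def test_mid_day_weight_never_changes_active_quota(self, dosed_ctrl):
        quota = dosed_ctrl.daily["T001"].quota_drug_drops
        dosed_ctrl.on_tag_in_range("T001", at(0))
        for i in range(200):
            dosed_ctrl.on_weight_tick(at(0.2 * (i + 1)), 40.0)
        assert dosed_ctrl.daily["T001"].quota_drug_drops == quota


def test_identical_input_streams_yield_identical_logs(
    config, treatment_profile, control_profile
):
    """The controller is deterministic: replaying a scripted stream twice
    produces byte-identical event logs."""
    from cagedose.logio import format_event

    def run_once():
        c = make_controller(config, [treatment_profile, control_profile])
        c.on_tag_in_range("T001", at(0))
        for i in range(50):
            c.on_weight_tick(at(0.2 * i + 0.2), 25.0)
        c.on_lick(at(12))
        c.on_lick(at(15))
        c.on_lick(at(25))
        c.on_tag_out_of_range(at(30))
        c.on_exit_wait_elapsed(at(60), lambda n: [0.0] * n)
        return "\n".join(format_event(ev) for ev in c.events)

    assert run_once() == run_once()
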