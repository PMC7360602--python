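"""Post-hoc analytics: weighing accuracy, circadian structure, dosing
window, strategy comparison, weight-intake correlation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cagedose import (
    Event,
    EventCode,
    SystemConfig,
    compare_cage_water_strategy,
    dark_phase_fraction,
    dosing_window_hours,
    hourly_drop_histogram,
    weight_accuracy,
    weight_intake_correlation,
)

D0 = dt.date(2020, 1, 1)


def frame(tags_dates_weights, col):
    return pd.DataFrame(
        [{"tag": t, "date": d, col: w} for t, d, w in tags_dates_weights]
    )


def drop_at(hour, minute=0, code=EventCode.DROP_WATER, tag="M", day=0):
    ts = dt.datetime(2020, 1, 1 + day, hour, minute)
    return Event(timestamp=ts, mouse_tag=tag, code=code)


class TestWeightAccuracy:
    def test_identical_series_has_zero_error_unit_correlation(self):
        pairs = [("M", D0 + dt.timedelta(days=i), 25.0 + 0.2 * i) for i in range(5)]
        rep = weight_accuracy(frame(pairs, "estimate_g"), frame(pairs, "reference_g"))
        assert rep.mean_abs_error_g == 0.0
        assert rep.mean_pct_error == 0.0
        assert rep.r_squared == pytest.approx(1.0)

    def test_correlation_matches_hand_computation(self):
        """4 pairs with known covariance: r^2 checked against the
        closed-form product-moment formula computed by hand."""
        est = [25.0, 26.0, 27.0, 30.0]
        ref = [25.2, 25.8, 27.4, 29.6]
        e = frame(
            [("M", D0 + dt.timedelta(days=i), v) for i, v in enumerate(est)],
            "estimate_g",
        )
        r = frame(
            [("M", D0 + dt.timedelta(days=i), v) for i, v in enumerate(ref)],
            "reference_g",
        )
        x, y = np.array(est), np.array(ref)
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        expected_r2 = sxy**2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        rep = weight_accuracy(e, r)
        assert rep.r_squared == pytest.approx(expected_r2)
        assert rep.mean_abs_error_g == pytest.approx(np.abs(x - y).mean())

    def test_fewer_than_three_pairs_omits_correlation(self):
        pairs = [("M", D0, 25.0), ("M", D0 + dt.timedelta(days=1), 26.0)]
        rep = weight_accuracy(frame(pairs, "estimate_g"), frame(pairs, "reference_g"))
        assert rep.r_squared is None

    def test_day_to_day_change_uses_reference_series(self):
        pairs = [("M", D0 + dt.timedelta(days=i), w) for i, w in enumerate([25.0, 25.5, 25.0])]
        rep = weight_accuracy(frame(pairs, "estimate_g"), frame(pairs, "reference_g"))
        assert rep.mean_day_to_day_pct_change == pytest.approx(
            100 * (0.5 / 25.0 + 0.5 / 25.5) / 2
        )


class TestDarkPhaseFraction:
    def test_all_night_drops_give_one(self, config):
        events = [drop_at(2) for _ in range(10)]
        assert dark_phase_fraction(events, config) == 1.0

    def test_matches_per_event_tally(self, config, rng):
        events = [
            drop_at(int(h), int(m))
            for h, m in zip(rng.integers(0, 24, 200), rng.integers(0, 60, 200))
        ]
        expected = np.mean(
            [config.is_dark(e.timestamp.hour + e.timestamp.minute / 60) for e in events]
        )
        assert dark_phase_fraction(events, config) == pytest.approx(expected)

    def test_no_drops_is_flagged_undefined(self, config):
        with pytest.raises(ValueError):
            dark_phase_fraction([], config)

    def test_hourly_histogram_totals(self, config):
        events = [drop_at(2)] * 3 + [drop_at(13)] * 2
        hist = hourly_drop_histogram(events)
        assert hist[2] == 3 and hist[13] == 2 and hist.sum() == 5


class TestDosingWindow:
    def test_window_is_first_to_last_drug_drop(self):
        events = [
            drop_at(0, 10, EventCode.DROP_DRUG),
            drop_at(5, 0, EventCode.DROP_DRUG),
            drop_at(10, 28, EventCode.DROP_DRUG),
            drop_at(11, 0, EventCode.DROP_WATER),  # water does not count
        ]
        win = dosing_window_hours(events)
        assert len(win) == 1
        assert win.window_h.iloc[0] == pytest.approx(10.3)

    def test_single_drop_day_has_zero_window(self):
        win = dosing_window_hours([drop_at(3, 0, EventCode.DROP_DRUG)])
        assert win.window_h.iloc[0] == 0.0

    def test_control_mouse_absent_from_result(self):
        win = dosing_window_hours([drop_at(3, 0, EventCode.DROP_WATER, tag="C")])
        assert len(win) == 0


class TestStrategyComparison:
    def _truth(self, rows):
        return pd.DataFrame(
            rows, columns=["tag", "day", "true_weight_g", "consumed_ul", "drug_drops"]
        )

    def test_intake_proportional_to_weight_hits_target(self, config):
        """If every mouse drinks exactly weight x 0.4 mL/g (i.e. 20 µL/g at
        50 µg/mL -> 1 mg/kg), the drinking-water dose equals the target."""
        rows = [
            (tag, d, w, w * 20.0, 2 * w)
            for d in range(5)
            for tag, w in (("A", 20.0), ("B", 40.0))
        ]
        out = compare_cage_water_strategy(self._truth(rows), config)
        assert np.allclose(out.water_strategy_dose_mean, 1.0)

    def test_equal_intake_halves_dose_for_double_weight(self, config):
        rows = [
            (tag, d, w, 1500.0, 0)
            for d in range(3)
            for tag, w in (("light", 20.0), ("heavy", 40.0))
        ]
        out = compare_cage_water_strategy(self._truth(rows), config).set_index("tag")
        light = out.loc["light", "water_strategy_dose_mean"]
        heavy = out.loc["heavy", "water_strategy_dose_mean"]
        assert heavy == pytest.approx(light / 2)

    def test_zero_intake_day_retained_as_zero_dose(self, config):
        rows = [("A", 0, 25.0, 0.0, 0), ("A", 1, 25.0, 2000.0, 0)]
        out = compare_cage_water_strategy(self._truth(rows), config)
        # mean over both days includes the zero
        assert out.water_strategy_dose_mean.iloc[0] == pytest.approx(
            (0.0 + 50 * 2.0 / 25.0) / 2
        )


class TestWeightIntakeCorrelation:
    def test_exact_proportionality_gives_unit_r2(self):
        w = np.linspace(20, 30, 10)
        r2, sig = weight_intake_correlation(w, 2 * w)
        assert r2 == pytest.approx(1.0)
        assert sig

    def test_independent_series_give_near_zero_r2(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(20, 30, 70)
        v = rng.uniform(1.0, 2.5, 70)
        r2, _ = weight_intake_correlation(w, v)
        assert r2 < 0.1

    def test_hand_built_five_pair_table(self):
        w = np.array([20.0, 22.0, 24.0, 26.0, 28.0])
        v = np.array([1.0, 1.4, 1.2, 1.8, 1.6])
        sxy = ((w - w.mean()) * (v - v.mean())).sum()
        expected = sxy**2 / (((w - w.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum())
        r2, _ = weight_intake_correlation(w, v)
        assert r2 == pytest.approx(expected)

    def test_constant_series_flagged_undefined(self):
        with pytest.raises(ValueError):
            weight_intake_correlation([25.0] * 5, [1, 2, 3, 4, 5])


def test_reports_invariant_to_event_order(config, rng):
    """Dark fraction and dosing window are pure functions of the event
    multiset: concatenation order of log files does not matter."""
    events = [
        drop_at(int(h), int(m), EventCode.DROP_DRUG, day=int(d))
        for h, m, d in zip(
            rng.integers(0, 24, 100), rng.integers(0, 60, 100), rng.integers(0, 3, 100)
        )
    ]
    shuffled = list(events)
    rng.shuffle(shuffled)
    assert dark_phase_fraction(events, config) == dark_phase_fraction(shuffled, config)
    pd.testing.assert_frame_equal(
        dosing_window_hours(events).reset_index(drop=True),
        dosing_window_hours(shuffled).reset_index(drop=True),
    )
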