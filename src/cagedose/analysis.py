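"""Post-hoc analytics over dosing logs and simulation ground truth.

Reproduces the study-style summaries: weighing accuracy against reference
weights, circadian structure of drinking (per-hour histogram, dark-phase
drop fraction), the daily dosing window, the bodyweight–consumption
correlation, and the head-to-head comparison between closed-loop dosing
and the conventional drug-in-drinking-water strategy, where each animal's
realized dose is whatever its intake happened to be that day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import SystemConfig
from .events import Event, EventCode

_DROP_CODES = (EventCode.DROP_WATER, EventCode.DROP_DRUG)


# ------------------------------------------------------------- weight accuracy


@dataclass(frozen=True, slots=True)
class AccuracyReport:
    """Per-mouse-day weighing accuracy against a reference method."""

    table: pd.DataFrame  # tag, date, estimate_g, reference_g, abs_error_g, pct_error
    mean_abs_error_g: float
    mean_pct_error: float
    r_squared: float | None  # None (flagged) with < 3 pairs
    mean_day_to_day_pct_change: float | None


def weight_accuracy(
    estimates: pd.DataFrame, references: pd.DataFrame
) -> AccuracyReport:
    """Compare daily weight estimates against reference weights.

    Both frames need columns ``tag``, ``date`` and a weight column
    (``estimate_g`` / ``reference_g`` or ``grams``).  Pairs are matched on
    (tag, date); the discrepancy percentage is 100·|est − ref|/ref, and
    the squared Pearson correlation is computed over all pairs.
    """
    est = estimates.rename(columns={"grams": "estimate_g"})[["tag", "date", "estimate_g"]]
    ref = references.rename(columns={"grams": "reference_g"})[["tag", "date", "reference_g"]]
    merged = est.merge(ref, on=["tag", "date"]).dropna()
    merged = merged.sort_values(["tag", "date"]).reset_index(drop=True)
    merged["abs_error_g"] = (merged.estimate_g - merged.reference_g).abs()
    merged["pct_error"] = 100.0 * merged.abs_error_g / merged.reference_g

    if len(merged) >= 3 and merged.reference_g.nunique() > 1:
        r, _ = stats.pearsonr(merged.estimate_g, merged.reference_g)
        r2 = float(r**2)
    else:
        r2 = None

    changes = []
    for _, grp in merged.groupby("tag"):
        w = grp.reference_g.to_numpy()
        if len(w) >= 2:
            changes.extend(100.0 * np.abs(np.diff(w)) / w[:-1])
    day_change = float(np.mean(changes)) if changes else None

    return AccuracyReport(
        table=merged,
        mean_abs_error_g=float(merged.abs_error_g.mean()),
        mean_pct_error=float(merged.pct_error.mean()),
        r_squared=r2,
        mean_day_to_day_pct_change=day_change,
    )


# ---------------------------------------------------------- circadian structure


def drop_events(events: list[Event]) -> list[Event]:
    return [ev for ev in events if ev.code in _DROP_CODES]


def dark_phase_fraction(events: list[Event], config: SystemConfig) -> float:
    """Fraction of drop deliveries falling in the dark phase
    [lights_off, lights_on), computed per event; undefined without drops."""
    drops = drop_events(events)
    if not drops:
        raise ValueError("no drop events: dark-phase fraction undefined")
    hours = np.array(
        [ev.timestamp.hour + ev.timestamp.minute / 60 + ev.timestamp.second / 3600 for ev in drops]
    )
    in_dark = np.array([config.is_dark(h) for h in hours])
    return float(in_dark.mean())


def hourly_drop_histogram(events: list[Event]) -> pd.Series:
    """Drop counts by clock hour (0..23), for circadian profiles."""
    counts = np.zeros(24, dtype=int)
    for ev in drop_events(events):
        counts[ev.timestamp.hour] += 1
    return pd.Series(counts, index=range(24), name="drops")


def dosing_window_hours(events: list[Event]) -> pd.DataFrame:
    """Per mouse-day span from first to last drug drop, in hours.

    Days without a drug drop are absent from the result; a single-drop
    day has window 0.
    """
    rows: dict[tuple[str, dt.date], list[dt.datetime]] = {}
    for ev in events:
        if ev.code is EventCode.DROP_DRUG:
            rows.setdefault((ev.mouse_tag, ev.timestamp.date()), []).append(ev.timestamp)
    out = [
        {
            "tag": tag,
            "date": date,
            "window_h": (max(ts) - min(ts)).total_seconds() / 3600.0,
            "n_drug_drops": len(ts),
        }
        for (tag, date), ts in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["tag", "date", "window_h", "n_drug_drops"])


# ----------------------------------------------------------- dosing strategies


def compare_cage_water_strategy(truth: pd.DataFrame, config: SystemConfig) -> pd.DataFrame:
    """Realized daily dose under drug-in-drinking-water vs closed-loop dosing.

    Under the drinking-water strategy the whole fluid intake carries drug,
    so the realized dose is concentration × intake / weight and inherits
    the full day-to-day intake variability; under closed-loop control the
    dose is the delivered drug-drop mass over weight, bounded by drop
    quantization.  *truth* needs per-mouse-day columns ``tag``,
    ``true_weight_g``, ``consumed_ul`` and ``drug_drops``.

    Returns one row per mouse with the mean and coefficient of variation
    of both realized dose series (mg/kg).
    """
    df = truth.copy()
    # µg/mL × mL / g = µg/g = mg/kg
    df["water_strategy_dose"] = (
        config.drug_conc_ug_per_ml * (df.consumed_ul / 1000.0) / df.true_weight_g
    )
    df["closed_loop_dose"] = (
        df.drug_drops * config.ug_per_drop / df.true_weight_g
    )

    def _summarize(grp: pd.DataFrame) -> pd.Series:
        out = {}
        for col in ("water_strategy_dose", "closed_loop_dose"):
            x = grp[col].to_numpy(dtype=float)
            mean = x.mean()
            out[f"{col}_mean"] = mean
            out[f"{col}_cv"] = float(x.std(ddof=1) / mean) if mean > 0 and len(x) > 1 else np.nan
        return pd.Series(out)

    result = df.groupby("tag").apply(_summarize, include_groups=False).reset_index()
    return result


# ------------------------------------------------------------------ correlation


def weight_intake_correlation(
    weights: np.ndarray | pd.Series, intakes: np.ndarray | pd.Series
) -> tuple[float, bool]:
    """Squared Pearson correlation between paired daily weights and intakes,
    with a significance flag (p < 0.05).  Raises on < 3 pairs or constant
    series (correlation undefined)."""
    w = np.asarray(weights, dtype=float)
    v = np.asarray(intakes, dtype=float)
    if w.shape != v.shape or w.size < 3:
        raise ValueError("need >= 3 paired mouse-days")
    if np.ptp(w) == 0 or np.ptp(v) == 0:
        raise ValueError("constant series: correlation undefined")
    r, p = stats.pearsonr(w, v)
    return float(r**2), bool(p < 0.05)
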