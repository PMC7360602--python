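"""Robust daily bodyweight estimation from 5 Hz load-cell streams.

A mouse standing on the load-cell platform produces thousands of noisy
readings per day, contaminated by movement transients (rearing, climbing,
partial entries) that are strongly positively biased.  The daily estimate
is the mode of the readings after rounding to a fixed precision and
removing outliers: the mode is insensitive to the transient tail in a way
the mean is not, and with 0.1 g rounding it recovers the true weight to a
single rounding quantum under realistic noise.

Outlier removal is two-stage:

1. discard readings outside the plausible bodyweight interval (removes
   near-zero readings around entries/exits and gross artifacts);
2. discard readings more than 3 MAD-scaled deviations from the median of
   the survivors (removes climbing/two-mice transients that still fall in
   the plausible range while preserving the modal mass).

Filtering operates on raw values; rounding is applied afterwards, before
mode counting.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import SystemConfig
from .events import WeightSample

# consistency factor making MAD estimate sigma for gaussian noise
_MAD_SCALE = 1.4826


@dataclass(frozen=True, slots=True)
class WeightEstimate:
    mouse_tag: str
    date: dt.date
    grams: float
    n_readings: int
    n_retained: int


def round_half_away(values: np.ndarray, dp: int) -> np.ndarray:
    """Round half away from zero at *dp* decimal places (element-wise).

    numpy's ``round`` rounds half to even; the rig's convention is the
    grade-school one, so 25.05 g rounds to 25.1 g (up to float
    representation of the input).
    """
    factor = 10.0**dp
    scaled = np.asarray(values, dtype=float) * factor
    return np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / factor


def retained_readings(grams: np.ndarray, config: SystemConfig) -> np.ndarray:
    """Apply the two-stage outlier filter; returns surviving raw readings."""
    grams = np.asarray(grams, dtype=float)
    grams = grams[np.isfinite(grams)]
    lo, hi = config.plausible_weight_g
    stage1 = grams[(grams >= lo) & (grams <= hi)]
    if stage1.size == 0:
        return stage1
    med = np.median(stage1)
    mad = np.median(np.abs(stage1 - med))
    sigma = _MAD_SCALE * mad
    if sigma == 0.0:
        # degenerate spread (e.g. constant stream): nothing left to reject
        return stage1
    return stage1[np.abs(stage1 - med) <= 3.0 * sigma]


def _mode_with_tiebreak(rounded: np.ndarray, retained_raw: np.ndarray, dp: int) -> float:
    """Most frequent rounded value; ties go to the value nearest the median
    of the retained raw readings, and to the smaller value if equidistant."""
    factor = 10**dp
    # integer keys avoid float-equality pitfalls in the histogram
    keys = np.round(rounded * factor).astype(np.int64)
    uniq, counts = np.unique(keys, return_counts=True)
    best = counts.max()
    candidates = uniq[counts == best] / factor
    if candidates.size == 1:
        return float(candidates[0])
    med = float(np.median(retained_raw))
    dist = np.abs(candidates - med)
    nearest = candidates[dist == dist.min()]
    return float(nearest.min())


def daily_weight_estimate(
    samples: Iterable[WeightSample],
    config: SystemConfig,
    *,
    mouse_tag: str = "",
    date: dt.date | None = None,
) -> WeightEstimate | None:
    """Compute the mode-based daily bodyweight estimate for one mouse-day.

    Returns ``None`` when no readings survive filtering (the caller falls
    back to the previous day's estimate).  The estimate is invariant to
    sample order and stable under duplication of the modal value.
    """
    samples = list(samples)
    grams = np.array([s.grams for s in samples], dtype=float)
    n_readings = grams.size
    if date is None and samples:
        date = samples[0].timestamp.date()
    retained = retained_readings(grams, config)
    if retained.size == 0:
        return None
    rounded = round_half_away(retained, config.weight_round_dp)
    grams_est = _mode_with_tiebreak(rounded, retained, config.weight_round_dp)
    return WeightEstimate(
        mouse_tag=mouse_tag,
        date=date if date is not None else dt.date.min,
        grams=grams_est,
        n_readings=n_readings,
        n_retained=int(retained.size),
    )


def should_tare(readings: Sequence[float], config: SystemConfig) -> bool:
    """Stability test gating automatic taring of the empty module.

    True iff every one of the ``tare_sample_count`` readings lies within
    ``tare_tolerance_g`` of their mean.  Requires exactly the configured
    number of readings.
    """
    readings = np.asarray(readings, dtype=float)
    if readings.size != config.tare_sample_count:
        raise ValueError(
            f"should_tare requires exactly {config.tare_sample_count} readings, got {readings.size}"
        )
    return bool(np.max(np.abs(readings - readings.mean())) <= config.tare_tolerance_g)


def occupancy_minutes(n_readings: int, config: SystemConfig) -> float:
    """Minutes of module occupancy implied by a count of load-cell readings."""
    if n_readings < 0:
        raise ValueError("n_readings must be >= 0")
    return n_readings / config.sampling_rate_hz / 60.0
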