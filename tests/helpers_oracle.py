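"""Independent brute-force oracles shared by test modules.

Deliberately written in plain Python (loops, Counter) so they share no
code path with the numpy implementation they check.
"""

import datetime as dt
from collections import Counter

import numpy as np

from cagedose import WeightSample

T0 = dt.datetime(2020, 1, 1)


def make_samples(grams):
    return [
        WeightSample(timestamp=T0 + dt.timedelta(seconds=i), grams=float(g))
        for i, g in enumerate(grams)
    ]


def oracle_mode(grams, config):
    """Exhaustive-count mode of rounded, outlier-filtered readings with the
    tie rule applied by hand: nearest the median of retained raw readings,
    then the smaller value."""
    lo, hi = config.plausible_weight_g
    stage1 = [g for g in grams if lo <= g <= hi]
    if not stage1:
        return None
    med = float(np.median(stage1))
    mad = float(np.median([abs(g - med) for g in stage1]))
    sigma = 1.4826 * mad
    retained = stage1 if sigma == 0 else [g for g in stage1 if abs(g - med) <= 3 * sigma]
    if not retained:
        return None
    dp = config.weight_round_dp
    keys = [
        int(np.floor(abs(g) * 10**dp + 0.5)) * (1 if g >= 0 else -1) for g in retained
    ]
    counts = Counter(keys)
    best = max(counts.values())
    cands = sorted(k / 10**dp for k, c in counts.items() if c == best)
    med_r = float(np.median(retained))
    return min(cands, key=lambda v: (abs(v - med_r), v))
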