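"""Virtual colony: circadian drinking behavior and the simulation harness.

Generates realistic group-housed mouse behavior — module visits, lick
bouts, daily intake, gradual weight gain — and drives the session
controller with the resulting sensor stream, recording ground truth
alongside the controller's own logs so every accuracy claim can be
checked against known true values.

Statistical structure emulated (defaults; all configurable per mouse):

* nocturnal drinking: visit rates differ between dark and light phase so
  that roughly 74% of drops fall in the dark;
* daily intake ~1.68 mL with 30–40% day-to-day coefficient of variation
  (lognormal across days), allocated over the day's visits in proportion
  to per-visit bout sizes and capped by satiety;
* gradual weight gain of ~5 g over two months from a ~25 g start, with
  small day-to-day fluctuation (~1–2% of bodyweight);
* single occupancy: only one mouse fits in the module, so overlapping
  visit proposals are shifted or dropped.

Features of real colonies NOT modeled: social rank effects on module
access, learning curves (all mice lick from day one), illness, and any
pharmacodynamic effect of the drug on behavior.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import Group, MouseProfile, SystemConfig
from .controller import SessionController
from .hardware import VirtualHardware, tare as tare_load_cell

_DAY_S = 86_400.0


@dataclass(frozen=True, slots=True)
class SimMouse:
    """Ground-truth behavioral and physiological parameters of one mouse."""

    tag: str
    start_weight_g: float = 25.0
    growth_g_per_day: float = 5.0 / 60.0  # ~5 g over two months
    weight_fluct_sd_g: float = 0.25
    visit_rate_dark_per_h: float = 1.45
    visit_rate_light_per_h: float = 0.51  # dark:light odds ~2.85 → ~74% dark drops
    bout_drops_mean: float = 7.0
    daily_intake_target_ml: float = 1.68
    intake_day_cv: float = 0.35
    satiety_decline_per_day: float = 0.0  # optional slow decline in intake, off by default


@dataclass(slots=True)
class Visit:
    """One resolved occupancy interval with its planned drinking bout."""

    tag: str
    start_s: float  # seconds since run start
    duration_s: float
    planned_drops: int
    lick_times_s: list[float] = field(default_factory=list)

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True, slots=True)
class ColonyRun:
    """Specification of one simulated cage run."""

    mice: tuple[SimMouse, ...]
    profiles: tuple[MouseProfile, ...]
    days: int
    seed: int
    config: SystemConfig = field(default_factory=SystemConfig)
    start: dt.datetime = dt.datetime(2020, 1, 1, 0, 0, 0)
    noise_free: bool = False


@dataclass(slots=True)
class ColonyResult:
    """Outputs of a run: controller logs plus aligned ground truth."""

    run: ColonyRun
    controller: SessionController
    truth: pd.DataFrame  # per mouse-day: true weight, consumed volume, drop counts
    estimates: pd.DataFrame  # per mouse-day weight estimates (carried-forward flagged)
    hardware: VirtualHardware

    @property
    def events(self):
        return self.controller.events


# --------------------------------------------------------------------- weights


def step_weight(mouse: SimMouse, day: int, rng: np.random.Generator) -> float:
    """True bodyweight (g) on *day*: deterministic growth plus fluctuation."""
    w = mouse.start_weight_g + mouse.growth_g_per_day * day
    if mouse.weight_fluct_sd_g > 0:
        w += rng.normal(0.0, mouse.weight_fluct_sd_g)
    return w


def weight_trajectory(mouse: SimMouse, n_days: int, rng: np.random.Generator) -> np.ndarray:
    """True daily weights over *n_days* (one draw per day)."""
    return np.array([step_weight(mouse, d, rng) for d in range(n_days)])


# ---------------------------------------------------------------------- visits


def _hour_rates(mouse: SimMouse, config: SystemConfig) -> np.ndarray:
    """Visit rate (per hour) for each clock hour 0..23."""
    return np.array(
        [
            mouse.visit_rate_dark_per_h
            if config.is_dark(h)
            else mouse.visit_rate_light_per_h
            for h in range(24)
        ]
    )


def generate_visits(
    mouse: SimMouse, day: int, config: SystemConfig, rng: np.random.Generator
) -> list[Visit]:
    """Visit start times for one mouse-day: an inhomogeneous Poisson
    process, piecewise-constant over clock hours (dark vs light rate).

    Durations and bout sizes are provisional here; satiety capping and
    overlap resolution happen at the cage level.
    """
    rates = _hour_rates(mouse, config)
    visits: list[Visit] = []
    for hour, rate in enumerate(rates):
        if rate <= 0:
            continue
        n = rng.poisson(rate)
        for u in np.sort(rng.uniform(0.0, 3600.0, size=n)):
            start = day * _DAY_S + hour * 3600.0 + float(u)
            bout = int(rng.poisson(mouse.bout_drops_mean))
            # dwell before/after drinking plus one lockout-spaced lick per drop
            duration = rng.uniform(4.0, 10.0) + bout * (config.lockout_s + 1.0) + rng.uniform(2.0, 6.0)
            visits.append(Visit(tag=mouse.tag, start_s=start, duration_s=duration, planned_drops=bout))
    visits.sort(key=lambda v: v.start_s)
    return visits


def resolve_overlaps(visits: list[Visit], min_gap_s: float = 3.0) -> list[Visit]:
    """Enforce single occupancy: visits are processed in start order; a
    visit starting while the module is occupied is shifted to after the
    occupant leaves (plus a small gap), and dropped if the shift exceeds
    its own duration (the mouse gave up waiting)."""
    resolved: list[Visit] = []
    free_at = -math.inf
    for v in sorted(visits, key=lambda x: x.start_s):
        start = max(v.start_s, free_at)
        if start - v.start_s > v.duration_s:
            continue
        moved = replace_start(v, start)
        resolved.append(moved)
        free_at = moved.end_s + min_gap_s
    return resolved


def replace_start(v: Visit, new_start: float) -> Visit:
    return Visit(
        tag=v.tag,
        start_s=new_start,
        duration_s=v.duration_s,
        planned_drops=v.planned_drops,
        lick_times_s=list(v.lick_times_s),
    )


# ----------------------------------------------------------------------- licks


def generate_licks(
    visit: Visit,
    remaining_drops: int,
    config: SystemConfig,
    rng: np.random.Generator,
    *,
    extra_lick_prob: float = 0.3,
) -> tuple[list[float], int]:
    """Lick timestamps within a visit, modulated by remaining satiety.

    Drinking licks are spaced just over one lockout apart so each earns a
    drop; a fraction of drops is followed by an extra within-lockout lick
    (unrewarded, as real lick bouts contain more licks than drops).  With
    satiety exhausted the visit produces no licks.
    """
    n_drops = min(visit.planned_drops, max(remaining_drops, 0))
    if n_drops <= 0:
        return [], 0
    licks: list[float] = []
    n_drink = 0
    t = visit.start_s + rng.uniform(4.0, 10.0)
    for _ in range(n_drops):
        if t >= visit.end_s:
            break
        licks.append(t)
        n_drink += 1
        if extra_lick_prob > 0 and rng.random() < extra_lick_prob:
            extra = t + rng.uniform(1.0, config.lockout_s - 1.0)
            if extra < visit.end_s:
                licks.append(extra)
        t += config.lockout_s + rng.exponential(0.5) + 1e-3
    licks.sort()
    return licks, n_drink


# ------------------------------------------------------------- day scheduling


def _daily_target_drops(
    mouse: SimMouse, day: int, config: SystemConfig, rng: np.random.Generator
) -> int:
    """Drops the mouse intends to drink today (lognormal day-to-day CV)."""
    mean_ml = mouse.daily_intake_target_ml * (
        1.0 - mouse.satiety_decline_per_day * day
    )
    mean_ml = max(mean_ml, 0.0)
    if mouse.intake_day_cv > 0:
        sigma = math.sqrt(math.log(1.0 + mouse.intake_day_cv**2))
        factor = rng.lognormal(-0.5 * sigma**2, sigma)  # unit mean
    else:
        factor = 1.0
    return int(round(mean_ml * factor * 1000.0 / config.drop_volume_ul))


def build_schedule(
    mice: tuple[SimMouse, ...],
    n_days: int,
    config: SystemConfig,
    rngs: dict[str, np.random.Generator],
) -> list[Visit]:
    """Resolved, lick-annotated visit schedule for a whole cage run.

    Each mouse-day's intake target is allocated over that day's visits in
    proportion to per-visit bout sizes, then consumed sequentially under a
    satiety cap as licks are laid down.  Overlap resolution is global
    (visits may spill across midnight), so the schedule respects single
    occupancy over the entire run.
    """
    all_visits: list[Visit] = []
    targets: dict[tuple[str, int], int] = {}
    for day in range(n_days):
        for mouse in mice:
            rng = rngs[mouse.tag]
            visits = generate_visits(mouse, day, config, rng)
            target = _daily_target_drops(mouse, day, config, rng)
            targets[(mouse.tag, day)] = target
            total_bout = sum(v.planned_drops for v in visits)
            if total_bout > 0:
                scale = target / total_bout
                for v in visits:
                    v.planned_drops = int(round(v.planned_drops * scale))
            all_visits.extend(visits)

    resolved = resolve_overlaps(all_visits)
    remaining = dict(targets)
    for v in resolved:
        rng = rngs[v.tag]
        key = (v.tag, min(int(v.start_s // _DAY_S), n_days - 1))
        licks, intended = generate_licks(v, remaining.get(key, 0), config, rng)
        v.lick_times_s = licks
        remaining[key] = remaining.get(key, 0) - intended
    return resolved


def build_day_schedule(
    mice: tuple[SimMouse, ...],
    day: int,
    config: SystemConfig,
    rngs: dict[str, np.random.Generator],
) -> list[Visit]:
    """Single-day convenience wrapper around :func:`build_schedule`.

    Note the day index still seeds circadian placement via each visit's
    absolute start time; satiety state does not carry across calls.
    """
    shifted = []
    for v in build_schedule(mice, 1, config, rngs):
        shifted.append(
            Visit(
                tag=v.tag,
                start_s=v.start_s + day * _DAY_S,
                duration_s=v.duration_s,
                planned_drops=v.planned_drops,
                lick_times_s=[t + day * _DAY_S for t in v.lick_times_s],
            )
        )
    return shifted


def sample_drop_times(
    mice: tuple[SimMouse, ...],
    n_days: int,
    config: SystemConfig,
    seed: int,
) -> pd.DataFrame:
    """Fast path: intended drop times only, without running the controller.

    Useful for checking the circadian statistics of the generator itself
    (e.g. the dark-phase fraction) at large mouse-day counts.
    """
    ss = np.random.SeedSequence(seed)
    rngs = {m.tag: np.random.default_rng(s) for m, s in zip(mice, ss.spawn(len(mice)))}
    rows = []
    prev_drop = -math.inf  # the lockout is cage-wide (one shared spout)
    for v in build_schedule(mice, n_days, config, rngs):
        for t in v.lick_times_s:
            # a lick inside the lockout of the previous drop is unrewarded
            if t - prev_drop >= config.lockout_s:
                rows.append((v.tag, int(t // _DAY_S), t))
                prev_drop = t
    return pd.DataFrame(rows, columns=["tag", "day", "t_s"])


# ------------------------------------------------------------------ simulation


def default_colony(
    n_mice: int = 4,
    n_treatment: int = 3,
    days: int = 14,
    seed: int = 0,
    *,
    dose_mg_per_kg: float = 1.0,
    config: SystemConfig | None = None,
    noise_free: bool = False,
) -> ColonyRun:
    """A cage of 3–4 littermates with spread start weights, first day
    baseline (no drug), treatment mice dosed at 1 mg/kg/day."""
    if not 1 <= n_treatment <= n_mice:
        raise ValueError("need 1 <= n_treatment <= n_mice")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    mice = []
    profiles = []
    for i in range(n_mice):
        tag = f"M{i + 1:03d}"
        mice.append(
            SimMouse(tag=tag, start_weight_g=float(rng.uniform(22.0, 28.0)))
        )
        treated = i < n_treatment
        profiles.append(
            MouseProfile(
                rfid_tag=tag,
                group=Group.TREATMENT if treated else Group.CONTROL,
                dose_mg_per_kg=dose_mg_per_kg if treated else 0.0,
            )
        )
    return ColonyRun(
        mice=tuple(mice),
        profiles=tuple(profiles),
        days=days,
        seed=seed,
        config=config or SystemConfig(),
        noise_free=noise_free,
    )


def run_colony(run: ColonyRun) -> ColonyResult:
    """Simulate a full cage run and drive the session controller.

    Builds each day's resolved visit schedule, converts it to the
    time-ordered sensor stream the controller consumes (tag reads, 5 Hz
    load-cell ticks, licks, exit waits, day rollovers), resolves dispense
    commands against the virtual hardware, and records ground truth
    (true weights, realized consumed volumes, delivered drop counts)
    alongside the controller's event log.
    """
    config = run.config
    ss = np.random.SeedSequence(run.seed)
    s_behav, s_hw, s_weights = ss.spawn(3)
    behav_rngs = {
        m.tag: np.random.default_rng(s)
        for m, s in zip(run.mice, s_behav.spawn(len(run.mice)))
    }
    hw = VirtualHardware.seeded(int(s_hw.generate_state(1)[0] % 2**31), noise_free=run.noise_free)
    w_rng = np.random.default_rng(s_weights)
    true_w = {m.tag: weight_trajectory(m, run.days, w_rng) for m in run.mice}
    if run.noise_free:
        for m in run.mice:
            true_w[m.tag] = m.start_weight_g + m.growth_g_per_day * np.arange(run.days)

    # ground-truth accumulators, keyed (tag, day)
    consumed_ul: dict[tuple[str, int], float] = {}
    drop_counts: dict[tuple[str, int], dict[str, int]] = {}

    controller = SessionController(
        config,
        run.profiles,
        run.start,
        on_tare=lambda: tare_load_cell(hw.load_cell),
    )

    def clock(t_s: float) -> dt.datetime:
        return run.start + dt.timedelta(seconds=t_s)

    def dispenser(kind: str, t: dt.datetime) -> float:
        t_s = (t - run.start).total_seconds()
        vol = hw.dispense(kind, t_s, steps=config.pump_steps_per_drop)
        tag = controller.current_tag
        day = int(t_s // _DAY_S)
        key = (tag, day)
        consumed_ul[key] = consumed_ul.get(key, 0.0) + vol
        counts = drop_counts.setdefault(key, {"drug": 0, "water": 0})
        counts[kind] += 1
        return vol

    controller.dispenser = dispenser

    tick = 1.0 / config.sampling_rate_hz
    rollovers = [d * _DAY_S for d in range(1, run.days)]
    next_roll = 0

    def process_rollovers(up_to_s: float) -> None:
        nonlocal next_roll
        while next_roll < len(rollovers) and rollovers[next_roll] <= up_to_s:
            t_s = rollovers[next_roll]
            controller.on_day_rollover(clock(t_s))
            if not run.noise_free and hw.load_cell.noise_sd_g > 0:
                # slow zero drift of the cell, corrected by automatic tares
                hw.load_cell.zero_offset_g += float(hw.rng_cell.normal(0.0, 0.02))
            next_roll += 1

    visits = build_schedule(run.mice, run.days, config, behav_rngs)
    run_end_s = run.days * _DAY_S
    visits = [v for v in visits if v.start_s < run_end_s - 1.0]
    for v in visits:  # clamp spillover past the run's final midnight
        if v.end_s > run_end_s - 0.5:
            v.duration_s = run_end_s - 0.5 - v.start_s
            v.lick_times_s = [t for t in v.lick_times_s if t < v.end_s]

    pending_tare_s: float | None = None

    def empty_reader(n: int) -> list[float]:
        return [hw.read_weight(0.0) for _ in range(n)]

    for v in visits:
        if pending_tare_s is not None and pending_tare_s <= v.start_s:
            process_rollovers(pending_tare_s)
            controller.on_exit_wait_elapsed(clock(pending_tare_s), empty_reader)
            pending_tare_s = None
        process_rollovers(v.start_s)

        controller.on_tag_in_range(v.tag, clock(v.start_s))

        def w_day(t_s: float, tag: str = v.tag) -> float:
            return float(true_w[tag][min(int(t_s // _DAY_S), run.days - 1)])

        tick_times = np.arange(v.start_s + tick, v.end_s, tick)
        licks = v.lick_times_s
        ti = li = 0
        while ti < len(tick_times) or li < len(licks):
            if li >= len(licks) or (ti < len(tick_times) and tick_times[ti] <= licks[li]):
                t_s = float(tick_times[ti])
                ti += 1
                process_rollovers(t_s)
                controller.on_weight_tick(clock(t_s), hw.read_weight(w_day(t_s)))
            else:
                t_s = float(licks[li])
                li += 1
                process_rollovers(t_s)
                controller.on_lick(clock(t_s))
        controller.on_tag_out_of_range(clock(v.end_s))
        pending_tare_s = v.end_s + config.exit_wait_s

    end_s = run.days * _DAY_S
    if pending_tare_s is not None and pending_tare_s < end_s:
        process_rollovers(pending_tare_s)
        controller.on_exit_wait_elapsed(clock(pending_tare_s), empty_reader)
    process_rollovers(end_s - 1e-9)
    controller.on_day_rollover(clock(end_s))  # close the final day

    # assemble ground truth and estimates
    truth_rows = []
    for m in run.mice:
        for day in range(run.days):
            counts = drop_counts.get((m.tag, day), {"drug": 0, "water": 0})
            truth_rows.append(
                {
                    "tag": m.tag,
                    "day": day,
                    "date": (run.start + dt.timedelta(days=day)).date(),
                    "true_weight_g": float(true_w[m.tag][day]),
                    "consumed_ul": consumed_ul.get((m.tag, day), 0.0),
                    "drug_drops": counts["drug"],
                    "water_drops": counts["water"],
                }
            )
    truth = pd.DataFrame(truth_rows)

    est_rows = []
    for rec in controller.day_history:
        est_rows.append(
            {
                "tag": rec.mouse_tag,
                "date": rec.state.date,
                "estimate_g": rec.state.daily_weight_g,
                "carried_forward": rec.carried_forward,
                "quota_drug_drops": rec.state.quota_drug_drops,
                "drug_drops": rec.state.drug_drops,
                "water_drops": rec.state.water_drops,
                "n_readings": len(rec.state.weight_buffer),
            }
        )
    estimates = pd.DataFrame(est_rows)

    return ColonyResult(
        run=run, controller=controller, truth=truth, estimates=estimates, hardware=hw
    )
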