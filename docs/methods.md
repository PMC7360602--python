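# Methods

This note documents the models implemented in `cagedose`, the defaults
they ship with, and the choices made where the design was genuinely
open.

## The dosing loop

A dosing day runs from midnight to midnight (`day_rollover_hour`,
default 0). At each rollover the controller estimates every mouse's
bodyweight from the past day's load-cell buffer and sets the next day's
drug-drop quota:

    quota = round(dose_mg_per_kg × weight_g / q),   q = conc × drop_volume / 1000 (µg/drop)

rounded to the nearest integer with ties up. With the defaults
(1 mg/kg, 50 µg/mL, 10 µL ⇒ q = 0.5 µg) this is `round(2·weight_g)`:
quota steps land exactly on 0.5 g weight boundaries, which is why
ties-up was chosen — 0.1 g-precision weights hit the 0.25 g tie points
exactly and must resolve deterministically. Once a quota is set it never
changes mid-day; weight updates take effect at the next rollover only.

Drug drops are dispensed from the day's first rewarded lick until the
quota is met, then water. An interleave parameter `drug_interleave_n`
(default 1) restricts drug to every n-th drop of the day (positions
0, n, 2n, … of the day's total drop counter) to spread administration
out for fast-metabolized compounds.

The first `baseline_day_count` days (default 1, per mouse) deliver no
drug: they exist to establish a weight estimate before dosing, and a
mouse with no weight estimate at all is never dosed. If a day produces
no estimate (the mouse never entered the module), the previous estimate
carries forward and the gap is flagged in the summary file.

## Weight estimation

Input: all load-cell readings attributed to the mouse over one dosing
day (5 Hz while the module is occupied; ~9,000 readings for a typical
~30 min of daily occupancy). The estimate is the mode of the readings
after rounding to `weight_round_dp` (default 1 decimal), with outliers
removed first:

1. **Plausibility filter** — discard readings outside
   `plausible_weight_g` (default [10, 60] g, a margin around the 20–45 g
   range the hardware was validated on). Removes near-zero
   entry/exit readings and gross artifacts.
2. **MAD fence** — discard readings further than 3 scaled-MAD
   (1.4826·MAD) from the median of the survivors. Removes climbing and
   partial-entry transients that fall inside the plausible interval
   while leaving the modal mass untouched.

Filtering operates on raw values; rounding (half away from zero — the
grade-school convention, so 25.05 → 25.1) happens afterwards, before
mode counting. Ties in the mode are broken toward the candidate nearest
the median of retained raw readings, then toward the smaller value:
deterministic, and favoring the bulk of the distribution. A degenerate
spread (MAD = 0) skips the fence rather than discarding everything but
the median.

The estimator is permutation-invariant and stable under duplication of
the modal value; the test suite checks exact agreement with an
independent brute-force counting oracle on randomized instances, and
recovery of the true weight to within one 0.1 g quantum on ≥95% of
synthetic mouse-days at movement-noise σ = 0.2–0.3 g with 5–20%
positive transients.

**Taring.** After the occupant leaves and 30 s (`exit_wait_s`) pass with
no tag detected, 20 readings (`tare_sample_count`) are collected; if
none deviates more than 0.1 g (`tare_tolerance_g`) from their mean the
cell is re-zeroed. A single unstable reading (e.g. a mouse climbing on
the module) vetoes the tare.

## Session controller

An event-driven state machine (IDLE / OCCUPIED / EXIT_WAIT) consuming a
time-ordered stream of sensor signals, so the identical code runs
against the simulator or real transducers. Key behaviors:

- every tag-in-range transition triggers a fresh RFID read; the same tag
  confirms silently, a different tag closes the old session implicitly;
- unreadable or unregistered tags are logged (`RFID_FAIL`) and never
  dosed; `max_failed_reads` consecutive failures (default 10 — the
  count is not prescribed by the hardware, only that "too many" causes
  a restart) emit `REBOOT` and reset session state while **persisted
  daily counters are re-read unchanged**, so a reboot can never
  double-dose;
- licks are rewarded only in OCCUPIED and outside the 10 s lockout;
  every drop event is immediately followed by one `IMAGE` event with
  the same timestamp (ingestion-validation bookkeeping);
- the lockout is cage-wide (one shared spout), which implies the
  per-mouse inter-drop guarantee;
- a midnight rollover during an active session splits the weight buffer
  at the boundary; in-progress drop accounting joins the new day.

Safety invariants (no drop without a confirmed tag, inter-drop interval
≥ lockout, daily drug drops ≤ quota, determinism of logs given the
input stream) are asserted over full simulated runs in the test suite.

## Virtual hardware

- **Syringe pump** (drug): linear step model, 57 steps per 10 µL from a
  30 mL syringe; per-drop gaussian error sd 0.12 µL, matching the
  ~0.12 µL mean absolute error a well-calibrated stepper pump achieves.
  Volume is conserved against the syringe reservoir; an empty syringe
  raises a hardware fault.
- **Gravity valve** (water): nominal 10 µL with 5% per-drop CV and a
  slow multiplicative drift (default 2%/day) reflecting reservoir-level
  and line-resistance changes; `recalibrate_valve` resets the drift, as
  rigs do every few days. The valve's spread deliberately exceeds the
  pump's — the reason drug goes through the pump.
- **Load cell**: reading = true mass + zero offset + intrinsic sensor
  noise (sd 0.01 g, always) + movement noise (sd 0.2 g, only while a
  mass is on the platform) + with probability 5% a positive transient
  (uniform 3–20 g; rearing/climbing/partial entry), clipped at the
  780 g capacity. Movement noise scaling with presence is what makes
  empty-module readings quiet enough for the tare stability test while
  occupied readings show the realistic ~0.2 g spread. Transients can
  also strike empty readings (external contact), occasionally vetoing a
  tare.

All stochastic components draw from per-component numpy Generators
fanned out from one master seed; with noise parameters zeroed the whole
bench is exactly deterministic.

## Behavior generator

What it emulates, per mouse (all parameters configurable; defaults are
the study-profile values):

- **Visits**: inhomogeneous Poisson process, piecewise-constant per
  clock hour; dark-phase rate 1.45/h vs light 0.51/h under a 12/12
  cycle (lights on 06:00). Because a day's intake is allocated across
  visits proportionally (below), the expected dark-phase drop fraction
  is the rate odds 1.45/(1.45+0.51) ≈ 0.74, matching the ~74% of drops
  observed in the dark phase empirically.
- **Intake**: daily target drawn lognormally around 1.68 mL (≈168
  drops) with 35% day-to-day CV (inside the reported 30–40% band),
  allocated over the day's visits in proportion to Poisson bout-size
  weights and consumed sequentially under a satiety cap. Drinking licks
  are spaced one lockout plus an exponential jitter apart (each earns a
  drop); ~30% of drops are followed by an extra unrewarded lick inside
  the lockout, since real lick bouts contain more licks than drops.
  Per-visit bout statistics are invented defaults — no empirical
  bout-level data back them.
- **Weight**: linear growth of 5 g / 60 days from a ~25 g start plus an
  iid daily fluctuation (sd 0.25 g), yielding a mean absolute
  day-to-day change of ~1.2% of bodyweight, within the 1–2% observed.
- **Single occupancy**: one mouse fits the module, so overlapping visit
  proposals are shifted behind the current occupant (3 s minimum gap)
  or dropped when the wait would exceed the visit's own length.
  Resolution is global across days, so visits may legitimately span
  midnight.
- An optional linear satiety decline (off by default) can emulate the
  slow decrease in drinking over weeks of treatment.

What passing tests on this generator do **not** show about real data:
no social-rank structure in module access, no acquisition/learning
phase (all mice drink from day one — a deliberate modeling assumption),
no illness or pharmacodynamic feedback on behavior, and lick bouts with
invented microstructure. The generator validates the *controller and
estimator*, not the biology.

## Analytics

- Weighing accuracy: per-mouse-day |estimate − reference| in g and in %
  of bodyweight, squared Pearson correlation (reported as R², the
  field's convention) and the mean day-to-day % weight change of the
  reference series. Correlation is omitted and flagged under 3 pairs.
- Dark phase is the half-open clock interval [lights_off, lights_on),
  wrapping midnight; the drop fraction is a per-event tally.
- Dosing window: first-to-last drug drop per mouse-day, hours; absent
  (not zero) for days without a drug drop.
- Strategy comparison: on common ground truth, the drinking-water dose
  is concentration × daily intake / weight (µg/g ≡ mg/kg) so intake CV
  lands directly on dose CV; the closed-loop dose is delivered drug
  mass / weight, bounded by quota quantization. Consumed volume uses
  realized per-drop volumes when ground truth is available; from logs
  alone it is nominal volume × count (a documented approximation).

## Numerical and scale choices

- Timestamps are ISO-8601 at microsecond resolution; logs are
  tab-delimited text, summaries CSV. Writers and parsers are exact
  inverses (round-trip identity is tested byte-for-byte).
- Dosing accuracy in the end-to-end test is judged against the true
  bodyweight on the day the weight was measured (the quota for day *d*
  derives from day *d−1*'s readings). Judged against the same-day
  weight, genuine overnight bodyweight fluctuation (~1.4% of
  bodyweight) alone can exceed the ~2% drop-quantum budget regardless
  of estimator quality; the chosen comparator keeps estimation error
  and quantization — the system's own error sources — inside the test.
- The simulated study analogue runs 4 mice × 14 days (one cage of
  3 treated + 1 control), the package's scaled-down stand-in for a
  two-month cohort; larger statistical checks (dark-phase convergence
  at 10 mice × 56 days) use the fast generator path that skips the 5 Hz
  tick stream.
- Quota rounding ties go up; mode ties go to the median-nearest, then
  smaller, value; `round_half_away` is subject to the usual binary
  representation of decimal inputs (25.049999… rounds down), which is
  irrelevant at load-cell noise scales.

## Known limitations

- The controller models a single dosing module per cage; multi-module
  cages would need one controller instance each.
- `REBOOT` is an event plus a state-reload inside the simulation, not a
  process restart.
- No pharmacokinetics: the quota targets delivered mass, not blood
  concentration.
- Valve drift is linear-in-time and sign-fixed per run; real drift
  wanders. The distributional form of valve variability is this
  package's construction (none is published) and is configurable.
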