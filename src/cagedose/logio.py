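"""Writers and parsers for the rig's three plain-text file families.

* per-mouse event logs ``<tag>_events.txt``: one row per event,
  ``ISO-8601 timestamp <TAB> event code [<TAB> payload]``;
* per-mouse daily weight files ``<tag>_weights_<YYYY-MM-DD>.txt``:
  ``timestamp <TAB> grams`` to two decimal places, a new file per day;
* a cage summary CSV: one row per mouse per day with drop counts, the
  daily weight and the delivered drug mass.

All writers are lossless inverses of their parsers (round-trip identity),
which the tests exercise on randomized fixtures.  Timestamps are ISO-8601
with tab delimiters — the repository's logging dialect.
"""

from __future__ import annotations

import datetime as dt
import io
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import SystemConfig
from .events import Event, EventCode, WeightSample


class LogFormatError(ValueError):
    """A log file or row violates the format (message names the line)."""


# ----------------------------------------------------------------- event logs


def format_event(event: Event) -> str:
    """One log row (no trailing newline)."""
    row = f"{event.timestamp.isoformat()}\t{event.code.value}"
    if event.payload:
        row += f"\t{event.payload}"
    return row


class EventLogWriter:
    """Streaming, order-enforcing writer for one event log."""

    def __init__(self, stream: io.TextIOBase):
        self._stream = stream
        self._last: dt.datetime | None = None

    def write(self, event: Event) -> None:
        if not isinstance(event.code, EventCode):
            raise LogFormatError(f"unknown event code: {event.code!r}")
        if self._last is not None and event.timestamp < self._last:
            raise LogFormatError(
                f"out-of-order event at {event.timestamp.isoformat()} (last {self._last.isoformat()})"
            )
        self._last = event.timestamp
        self._stream.write(format_event(event) + "\n")

    def flush(self) -> None:
        self._stream.flush()


def write_event_log(events: Iterable[Event], path: Path | str) -> None:
    with open(path, "w") as fh:
        writer = EventLogWriter(fh)
        for ev in events:
            writer.write(ev)


def parse_event_row(row: str, mouse_tag: str, lineno: int) -> Event:
    parts = row.rstrip("\n").split("\t")
    if len(parts) not in (2, 3) or not parts[0] or not parts[1]:
        raise LogFormatError(f"line {lineno}: malformed row {row!r}")
    try:
        ts = dt.datetime.fromisoformat(parts[0])
    except ValueError as exc:
        raise LogFormatError(f"line {lineno}: bad timestamp {parts[0]!r}") from exc
    try:
        code = EventCode(parts[1])
    except ValueError as exc:
        raise LogFormatError(f"line {lineno}: unknown event code {parts[1]!r}") from exc
    payload = parts[2] if len(parts) == 3 else ""
    return Event(timestamp=ts, mouse_tag=mouse_tag, code=code, payload=payload)


def parse_event_log(source: Path | str | io.TextIOBase, mouse_tag: str = "") -> list[Event]:
    """Parse one event log; raises :class:`LogFormatError` with the line
    number on any malformed, out-of-order or unknown-code row."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    events: list[Event] = []
    last: dt.datetime | None = None
    if text and not text.endswith("\n"):
        nlines = text.count("\n") + 1
        raise LogFormatError(f"line {nlines}: truncated final row")
    for lineno, row in enumerate(text.splitlines(), start=1):
        ev = parse_event_row(row, mouse_tag, lineno)
        if last is not None and ev.timestamp < last:
            raise LogFormatError(f"line {lineno}: out-of-order timestamp")
        last = ev.timestamp
        events.append(ev)
    return events


def split_events_by_mouse(events: Iterable[Event]) -> dict[str, list[Event]]:
    """Partition a cage stream into per-mouse streams (cage-level events
    keyed by their sentinel tag)."""
    by_mouse: dict[str, list[Event]] = {}
    for ev in events:
        by_mouse.setdefault(ev.mouse_tag, []).append(ev)
    return by_mouse


def event_log_path(directory: Path | str, tag: str) -> Path:
    return Path(directory) / f"{tag}_events.txt"


# --------------------------------------------------------------- weight files


def format_weight_row(sample: WeightSample) -> str:
    return f"{sample.timestamp.isoformat()}\t{sample.grams:.2f}"


def write_weight_file(samples: Iterable[WeightSample], path: Path | str) -> None:
    with open(path, "w") as fh:
        last: dt.datetime | None = None
        for s in samples:
            if last is not None and s.timestamp < last:
                raise LogFormatError(f"out-of-order weight sample at {s.timestamp}")
            last = s.timestamp
            fh.write(format_weight_row(s) + "\n")


def parse_weight_file(source: Path | str | io.TextIOBase) -> list[WeightSample]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    samples: list[WeightSample] = []
    for lineno, row in enumerate(text.splitlines(), start=1):
        parts = row.split("\t")
        if len(parts) != 2:
            raise LogFormatError(f"line {lineno}: malformed row {row!r}")
        try:
            ts = dt.datetime.fromisoformat(parts[0])
            grams = float(parts[1])
        except ValueError as exc:
            raise LogFormatError(f"line {lineno}: {exc}") from exc
        samples.append(WeightSample(timestamp=ts, grams=grams))
    return samples


def weight_file_path(directory: Path | str, tag: str, date: dt.date) -> Path:
    return Path(directory) / f"{tag}_weights_{date.isoformat()}.txt"


# -------------------------------------------------------------------- summary

SUMMARY_COLUMNS = [
    "date",
    "tag",
    "weight_g",
    "water_drops",
    "drug_drops",
    "drug_ug",
    "weight_carried_forward",
]


def build_summary(
    events: Iterable[Event],
    weight_estimates: dict[tuple[str, dt.date], tuple[float | None, bool]],
    config: SystemConfig,
) -> pd.DataFrame:
    """Per mouse-day summary table from an event stream plus daily weights.

    ``weight_estimates`` maps (tag, date) to (grams-or-None, carried_forward
    flag); every mouse-day appearing in either source gets exactly one row.
    Drug mass is derived as drop count times the per-drop quantum.
    """
    counts: dict[tuple[str, dt.date], dict[str, int]] = {}
    for ev in events:
        if ev.code not in (EventCode.DROP_WATER, EventCode.DROP_DRUG):
            continue
        key = (ev.mouse_tag, ev.timestamp.date())
        c = counts.setdefault(key, {"water": 0, "drug": 0})
        c["water" if ev.code is EventCode.DROP_WATER else "drug"] += 1

    keys = sorted(set(counts) | set(weight_estimates))
    rows = []
    for tag, date in keys:
        c = counts.get((tag, date), {"water": 0, "drug": 0})
        weight, carried = weight_estimates.get((tag, date), (None, True))
        rows.append(
            {
                "date": date,
                "tag": tag,
                "weight_g": weight,
                "water_drops": c["water"],
                "drug_drops": c["drug"],
                "drug_ug": c["drug"] * config.ug_per_drop,
                "weight_carried_forward": carried,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary(summary: pd.DataFrame, path: Path | str) -> None:
    out = summary.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def parse_summary(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise LogFormatError(f"summary missing columns: {sorted(missing)}")
    df["date"] = df["date"].map(dt.date.fromisoformat)
    return df[SUMMARY_COLUMNS]


# ------------------------------------------------------------------ run dumps


def write_run_logs(result, directory: Path | str) -> None:
    """Persist a simulated run: per-mouse event logs, daily weight files
    and the summary CSV, under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_mouse = split_events_by_mouse(result.events)
    for tag, evs in by_mouse.items():
        write_event_log(evs, event_log_path(directory, tag))
    estimates: dict[tuple[str, dt.date], tuple[float | None, bool]] = {}
    for rec in result.controller.day_history:
        estimates[(rec.mouse_tag, rec.state.date)] = (
            rec.state.daily_weight_g,
            rec.carried_forward,
        )
        if rec.state.weight_buffer:
            write_weight_file(
                rec.state.weight_buffer,
                weight_file_path(directory, rec.mouse_tag, rec.state.date),
            )
    summary = build_summary(result.events, estimates, result.run.config)
    write_summary(summary, directory / "summary.csv")
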