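"""System configuration and per-mouse profiles.

The configuration mirrors the operating parameters of a closed-loop
home-cage oral dosing rig: a load-cell-mounted dosing module samples
bodyweight at 5 Hz while a mouse is inside, a capacitive lick spout
triggers drop delivery (10 µL drops of either water or drug solution at
50 µg/mL), a 10 s lockout follows each drop, and the load cell is tared
after a 30 s empty-module wait if 20 consecutive readings are stable to
within 0.1 g.  All numeric defaults are the rig's published operating
values; every one is configurable.
"""

from __future__ import annotations

import enum
from typing import Any

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class Group(str, enum.Enum):
    """Treatment assignment of a mouse."""

    TREATMENT = "treatment"
    CONTROL = "control"


class SystemConfig(BaseModel, frozen=True, extra="forbid"):
    """Validated cage-level operating parameters.

    Units are embedded in field names (``_ul`` microlitres, ``_s`` seconds,
    ``_g`` grams, ``_hz`` hertz).
    """

    drop_volume_ul: float = 10.0
    drug_conc_ug_per_ml: float = 50.0
    sampling_rate_hz: float = 5.0
    lockout_s: float = 10.0
    exit_wait_s: float = 30.0
    tare_sample_count: int = 20
    tare_tolerance_g: float = 0.1
    day_rollover_hour: int = 0
    lights_on_hour: int = 6
    lights_off_hour: int = 18
    drug_interleave_n: int = 1
    max_failed_reads: int = 10
    pump_steps_per_drop: int = 57
    weight_round_dp: int = 1
    plausible_weight_g: tuple[float, float] = (10.0, 60.0)

    @field_validator(
        "drop_volume_ul",
        "drug_conc_ug_per_ml",
        "sampling_rate_hz",
        "lockout_s",
        "exit_wait_s",
        "tare_tolerance_g",
    )
    @classmethod
    def _strictly_positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be strictly positive, got {v}")
        return v

    @field_validator("tare_sample_count")
    @classmethod
    def _tare_count(cls, v: int) -> int:
        if v < 2:
            raise ValueError(f"tare_sample_count must be >= 2, got {v}")
        return v

    @field_validator("drug_interleave_n")
    @classmethod
    def _interleave(cls, v: int) -> int:
        if v < 1:
            raise ValueError(f"drug_interleave_n must be >= 1, got {v}")
        return v

    @field_validator("max_failed_reads", "pump_steps_per_drop")
    @classmethod
    def _positive_int(cls, v: int, info) -> int:
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1, got {v}")
        return v

    @field_validator("weight_round_dp")
    @classmethod
    def _round_dp(cls, v: int) -> int:
        if v < 0:
            raise ValueError(f"weight_round_dp must be >= 0, got {v}")
        return v

    @model_validator(mode="after")
    def _cross_checks(self) -> "SystemConfig":
        for name in ("day_rollover_hour", "lights_on_hour", "lights_off_hour"):
            h = getattr(self, name)
            if not 0 <= h < 24:
                raise ValueError(f"{name} must lie in [0, 24), got {h}")
        if self.lights_on_hour == self.lights_off_hour:
            raise ValueError("lights_on_hour and lights_off_hour must differ")
        lo, hi = self.plausible_weight_g
        if not (0 < lo < hi):
            raise ValueError(
                f"plausible_weight_g must be an increasing positive interval, got {self.plausible_weight_g}"
            )
        return self

    @property
    def ug_per_drop(self) -> float:
        """Drug mass per drop (µg): the quantum of dose control."""
        return self.drug_conc_ug_per_ml * self.drop_volume_ul / 1000.0

    def is_dark(self, hour_of_day: float) -> bool:
        """True if *hour_of_day* falls in the dark phase [lights_off, lights_on)."""
        on, off = self.lights_on_hour, self.lights_off_hour
        if off > on:  # usual case: dark wraps midnight
            return not (on <= hour_of_day < off)
        return off <= hour_of_day < on

    def to_dict(self) -> dict[str, Any]:
        d = self.model_dump()
        d["plausible_weight_g"] = list(d["plausible_weight_g"])
        return d


class MouseProfile(BaseModel, frozen=True, extra="forbid"):
    """One subject: identity, group and dosing target.

    ``baseline_day_count`` initial days deliver no drug so that a first
    bodyweight estimate exists before any quota is computed.
    """

    rfid_tag: str
    group: Group
    dose_mg_per_kg: float = 0.0
    baseline_day_count: int = 1

    @field_validator("rfid_tag")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("rfid_tag must be non-empty")
        return v

    @field_validator("dose_mg_per_kg")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"dose_mg_per_kg must be >= 0, got {v}")
        return v

    @field_validator("baseline_day_count")
    @classmethod
    def _baseline(cls, v: int) -> int:
        if v < 0:
            raise ValueError(f"baseline_day_count must be >= 0, got {v}")
        return v

    @property
    def effective_dose_mg_per_kg(self) -> float:
        """Dose actually scheduled: control mice always dose at 0."""
        return 0.0 if self.group is Group.CONTROL else self.dose_mg_per_kg


class ConfigError(ValueError):
    """Raised when a configuration document fails to parse or validate."""


def load_config(source: str) -> tuple[SystemConfig, list[MouseProfile]]:
    """Parse a YAML configuration document into a validated config + profiles.

    The document has two top-level keys: ``system`` (any subset of
    :class:`SystemConfig` fields; omitted fields take defaults) and ``mice``
    (a non-empty list of mappings with ``rfid_tag``, ``group`` and optional
    ``dose_mg_per_kg`` / ``baseline_day_count``).

    Parameters
    ----------
    source
        YAML text (not a path).

    Raises
    ------
    ConfigError
        On malformed YAML, missing/unknown fields, duplicate tags, or any
        invariant violation; the message names the offending field.
    """
    try:
        doc = yaml.safe_load(source)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed configuration document: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")

    unknown = set(doc) - {"system", "mice"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    try:
        config = SystemConfig(**(doc.get("system") or {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid system configuration: {exc}") from exc

    raw_mice = doc.get("mice")
    if not raw_mice:
        raise ConfigError("field 'mice': at least one mouse profile is required")
    profiles = []
    for i, entry in enumerate(raw_mice):
        try:
            profiles.append(MouseProfile(**entry))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid mouse profile at index {i}: {exc}") from exc

    tags = [p.rfid_tag for p in profiles]
    if len(set(tags)) != len(tags):
        dupes = sorted({t for t in tags if tags.count(t) > 1})
        raise ConfigError(f"duplicate rfid_tag values: {dupes}")
    return config, profiles


def dump_config(config: SystemConfig, profiles: list[MouseProfile]) -> str:
    """Serialize config + profiles back to the YAML dialect read by load_config."""
    doc = {
        "system": config.to_dict(),
        "mice": [
            {
                "rfid_tag": p.rfid_tag,
                "group": p.group.value,
                "dose_mg_per_kg": p.dose_mg_per_kg,
                "baseline_day_count": p.baseline_day_count,
            }
            for p in profiles
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)
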