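"""Sampling-schema registry: the per-sensor acquisition plan of a study.

A sampling schema describes *how* a sensor acquires data:

``interval``
    one measurement every ``period_s`` seconds (e.g. location once a minute);
``interval_burst``
    every ``period_s`` seconds the sensor records continuously for
    ``burst_s`` seconds (e.g. 1 s of accelerometer data every 5 s);
``event``
    measurements fire when something happens (screen unlock, battery
    change) — no expected count can be derived;
``daily``
    one measurement per local calendar day.

The registry is the single source of "expected counts" used by the
quality layer, and the schedule the synthetic generator replays.  Two
profiles ship with the package: ``pilot`` (the default) and ``table1``
(the framework defaults, which disagree with the pilot profile on Wi-Fi
frequency and are therefore kept as a separate named profile, never
merged).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

MODES = ("interval", "interval_burst", "event", "daily")
OSES = ("android", "ios")

_NAME_RE = re.compile(r"^[a-z][a-z0-9_]*$")


class SchemaError(ValueError):
    """Raised for an invalid sampling-schema document; names the sensor."""


@dataclass(frozen=True)
class SamplingSchema:
    """Acquisition plan for one sensor."""

    sensor_name: str
    mode: str
    period_s: float | None = None
    burst_s: float | None = None
    os_support: frozenset[str] = field(default_factory=lambda: frozenset(OSES))

    def __post_init__(self) -> None:
        name = self.sensor_name
        if not _NAME_RE.match(name):
            raise SchemaError(f"{name!r}: sensor name must match {_NAME_RE.pattern}")
        if self.mode not in MODES:
            raise SchemaError(f"{name}: unknown mode {self.mode!r} (choose from {MODES})")
        if self.mode in ("interval", "interval_burst"):
            if self.period_s is None or not self.period_s > 0:
                raise SchemaError(f"{name}: mode {self.mode} requires period_s > 0")
        elif self.period_s is not None:
            raise SchemaError(f"{name}: period_s not allowed for mode {self.mode}")
        if self.mode == "interval_burst":
            if self.burst_s is None or not 0 < self.burst_s <= self.period_s:
                raise SchemaError(
                    f"{name}: interval_burst requires 0 < burst_s <= period_s"
                )
        elif self.burst_s is not None:
            raise SchemaError(f"{name}: burst_s only allowed for mode interval_burst")
        if not self.os_support or not set(self.os_support) <= set(OSES):
            raise SchemaError(f"{name}: os support must be a non-empty subset of {OSES}")
        object.__setattr__(self, "os_support", frozenset(self.os_support))

    def supports(self, os: str) -> bool:
        return os in self.os_support

    def to_dict(self) -> dict:
        d: dict = {"mode": self.mode}
        if self.period_s is not None:
            d["period_s"] = self.period_s
        if self.burst_s is not None:
            d["burst_s"] = self.burst_s
        d["os"] = sorted(self.os_support)
        return d


class SchemaRegistry(Mapping[str, SamplingSchema]):
    """Validated, immutable mapping sensor_name -> :class:`SamplingSchema`.

    Exactly one entry per sensor; duplicates are a validation error.
    """

    def __init__(self, schemas: Iterable[SamplingSchema]):
        self._sensors: dict[str, SamplingSchema] = {}
        for s in schemas:
            if s.sensor_name in self._sensors:
                raise SchemaError(f"{s.sensor_name}: duplicate sensor entry")
            self._sensors[s.sensor_name] = s

    def __getitem__(self, name: str) -> SamplingSchema:
        try:
            return self._sensors[name]
        except KeyError:
            raise KeyError(f"unknown sensor {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._sensors))

    def __len__(self) -> int:
        return len(self._sensors)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SchemaRegistry):
            return NotImplemented
        return self._sensors == other._sensors

    def sensors_for(self, os: str) -> list[str]:
        """Sensor names available on the given operating system."""
        return [n for n in self if self[n].supports(os)]

    def to_yaml(self) -> str:
        """Canonical serialisation (sensors sorted by name)."""
        doc = {"sensors": {n: self[n].to_dict() for n in self}}
        return yaml.safe_dump(doc, sort_keys=False)


def _entry(name: str, spec: Mapping) -> SamplingSchema:
    if not isinstance(spec, Mapping):
        raise SchemaError(f"{name}: entry must be a mapping, got {type(spec).__name__}")
    known = {"mode", "period_s", "burst_s", "os", "name"}
    extra = set(spec) - known
    if extra:
        raise SchemaError(f"{name}: unknown keys {sorted(extra)}")
    if "mode" not in spec:
        raise SchemaError(f"{name}: missing required key 'mode'")
    return SamplingSchema(
        sensor_name=name,
        mode=spec["mode"],
        period_s=spec.get("period_s"),
        burst_s=spec.get("burst_s"),
        os_support=frozenset(spec.get("os", OSES)),
    )


def load_schema(source: str | Path | Mapping) -> SchemaRegistry:
    """Load and validate a sampling-schema registry.

    ``source`` may be a built-in profile name (``"pilot"``, ``"table1"``),
    a path to a YAML file, a YAML string, or an already-parsed mapping.
    The document holds a top-level ``sensors`` key whose value is either a
    mapping ``name -> entry`` or a list of entries each carrying ``name``.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if isinstance(source, str) and source in ("pilot", "table1"):
            text = (
                resources.files("sensepipe.data")
                .joinpath(f"{source}_schema.yaml")
                .read_text()
            )
        elif isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml"))
        ):
            text = Path(source).read_text()
        else:
            text = source
        doc = yaml.safe_load(text)
    if doc is None:
        return SchemaRegistry([])
    if not isinstance(doc, Mapping) or "sensors" not in doc:
        raise SchemaError("document must be a mapping with a top-level 'sensors' key")
    sensors = doc["sensors"]
    if sensors is None:
        return SchemaRegistry([])
    if isinstance(sensors, Mapping):
        entries = [_entry(str(n), s) for n, s in sensors.items()]
    elif isinstance(sensors, list):
        entries = []
        for s in sensors:
            if not isinstance(s, Mapping) or "name" not in s:
                raise SchemaError("list-form sensor entries require a 'name' key")
            entries.append(_entry(str(s["name"]), s))
    else:
        raise SchemaError("'sensors' must be a mapping or a list of entries")
    return SchemaRegistry(entries)


def pilot_registry() -> SchemaRegistry:
    """The pilot-study schema (default profile)."""
    return load_schema("pilot")


def table1_registry() -> SchemaRegistry:
    """The framework-default schema (alternate profile)."""
    return load_schema("table1")
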