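"""Shared domain types and time conventions.

All internal timestamps are UTC with millisecond precision (``int``
epoch-milliseconds).  Each record additionally carries the device's UTC
offset in minutes at acquisition time, so local-time concepts (the
night-window exclusion of the quality layer, daily sensors) can be
recovered without a timezone database.  Every interval in the package —
1-second epochs, hour buckets, link windows, gaps — is half-open
``[start, end)``, which makes counts partition exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Mapping

MS = 1000
HOUR_MS = 3_600_000
DAY_MS = 86_400_000

#: Documented payload keys per sensor; anything else is stored verbatim in
#: the record's payload map but only these become typed store columns.
PAYLOAD_FIELDS: dict[str, tuple[str, ...]] = {
    "accelerometer": ("x", "y", "z"),
    "gyroscope": ("x", "y", "z"),
    "location": ("latitude", "longitude"),
    "battery": ("level",),
    "device": ("os", "os_version", "brand"),
}
DEFAULT_PAYLOAD_FIELDS: tuple[str, ...] = ("value",)
TEXT_PAYLOAD_FIELDS = {"os", "os_version", "brand"}

INERTIAL_SENSORS = ("accelerometer", "gyroscope")


def payload_fields(sensor_name: str) -> tuple[str, ...]:
    return PAYLOAD_FIELDS.get(sensor_name, DEFAULT_PAYLOAD_FIELDS)


def parse_timestamp(text: str) -> tuple[int, int]:
    """Parse an ISO-8601 timestamp into ``(utc_ms, utc_offset_min)``.

    Naive timestamps are taken as UTC (offset 0).
    """
    dt = datetime.fromisoformat(text)
    if dt.tzinfo is None:
        off_min = 0
        dt = dt.replace(tzinfo=timezone.utc)
    else:
        off_min = int(dt.utcoffset().total_seconds() // 60)
    return round(dt.timestamp() * MS), off_min


def format_timestamp(utc_ms: int, utc_offset_min: int = 0) -> str:
    """Render a UTC instant as local ISO-8601 with explicit offset."""
    tz = timezone(timedelta(minutes=utc_offset_min))
    dt = datetime.fromtimestamp(utc_ms / MS, tz)
    return dt.isoformat(timespec="milliseconds")


@dataclass(frozen=True)
class TimeWindow:
    """Half-open UTC interval ``[start_ms, end_ms)``."""

    start_ms: int
    end_ms: int

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError("TimeWindow requires start < end")

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms

    def contains(self, utc_ms: int) -> bool:
        return self.start_ms <= utc_ms < self.end_ms


@dataclass
class SensorRecord:
    """One timestamped measurement from one sensor for one participant."""

    record_id: str
    participant_id: str
    sensor_name: str
    timestamp_utc_ms: int
    utc_offset_min: int
    payload: Mapping[str, object] = field(default_factory=dict)

    def validate_inertial(self) -> None:
        """Inertial payloads must contain finite x, y, z."""
        if self.sensor_name in INERTIAL_SENSORS:
            for k in ("x", "y", "z"):
                v = self.payload.get(k)
                if not isinstance(v, (int, float)) or not math.isfinite(v):
                    raise ValueError(
                        f"{self.sensor_name} record {self.record_id}: "
                        f"non-finite or missing component {k!r}"
                    )


@dataclass
class Beep:
    """One ESM prompt: the anchor for sensor linking.

    ``scheduled_ms`` is when the prompt fired; ``answered_ms`` is when the
    questionnaire was completed (absent if never answered).
    """

    beep_id: str
    participant_id: str
    scheduled_ms: int
    answered_ms: int | None = None
    answers: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.answered_ms is not None and self.answered_ms < self.scheduled_ms:
            raise ValueError(f"beep {self.beep_id}: answered before scheduled")

    def anchor_ms(self, anchor: str = "auto") -> int:
        """Anchor instant for time-window linking.

        ``auto`` prefers completion time and falls back to schedule time.
        """
        if anchor == "scheduled":
            return self.scheduled_ms
        if anchor == "answered":
            if self.answered_ms is None:
                raise ValueError(f"beep {self.beep_id}: no answered_at to anchor on")
            return self.answered_ms
        if anchor == "auto":
            return self.answered_ms if self.answered_ms is not None else self.scheduled_ms
        raise ValueError(f"unknown anchor {anchor!r}")


@dataclass(frozen=True)
class ParticipantDevice:
    """General device information for one participant."""

    participant_id: str
    os: str
    os_version: str = ""
    brand: str = ""

    def __post_init__(self) -> None:
        if self.os not in ("android", "ios"):
            raise ValueError(f"unknown OS {self.os!r}")
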