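"""Raw-file ingestion: unpack, repair, decode, import.

The sensing app writes measurements to a JSON file until it reaches
about 5 MB, then zips it and starts a new one.  When the app is killed
mid-write the current file is left behind as loose JSON with an
incorrect ending (no closing bracket, possibly a truncated last
element).  ``repair_json`` recovers the longest valid prefix of
top-level array elements and closes the array; ``import_files`` walks a
per-participant directory tree, repairs what it can, decodes the
measurement dialect and writes records idempotently into a
:class:`~sensepipe.store.SenseStore`.

Measurement dialect (repo-defined; the canonical fixture format):
a JSON array of objects ``{"id": ..., "timestamp": ISO-8601 with
offset, "sensor": ..., "body": {...}}``.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
import zipfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .model import (
    INERTIAL_SENSORS,
    TEXT_PAYLOAD_FIELDS,
    SensorRecord,
    parse_timestamp,
    payload_fields,
)
from .schema import SchemaRegistry
from .store import SenseStore, StorageError

log = logging.getLogger("sensepipe.ingest")

ZIP_MAGIC = b"PK\x03\x04"


class ArchiveError(RuntimeError):
    """Unreadable or garbled archive; carries the offending path."""


class DecodeError(ValueError):
    """A single measurement object could not be decoded."""


@dataclass(frozen=True)
class RawFile:
    """One file of raw app output; container sniffed from content."""

    path: Path
    container: str  # "zip" | "json"
    byte_size: int
    sha256: str

    @classmethod
    def from_path(cls, path: str | Path) -> "RawFile":
        path = Path(path)
        data = path.read_bytes()
        container = "zip" if data[:4] == ZIP_MAGIC else "json"
        return cls(path, container, len(data), hashlib.sha256(data).hexdigest())


@dataclass(frozen=True)
class RepairOutcome:
    status: str  # valid | fixed | unfixable
    records_recovered: int
    bytes_discarded: int

    def __post_init__(self) -> None:
        if self.status == "valid" and self.bytes_discarded != 0:
            raise ValueError("valid implies no bytes discarded")
        if self.status == "unfixable" and self.records_recovered != 0:
            raise ValueError("unfixable implies no records recovered")


@dataclass
class ImportReport:
    """Bookkeeping of one import batch; totals consistent with store deltas."""

    files_seen: int = 0
    files_imported: int = 0
    files_repaired: int = 0
    files_unfixable: int = 0
    duplicate_files: int = 0
    duplicates_skipped: int = 0  # record-level
    decode_errors: int = 0
    records_by_sensor: dict[str, int] = field(default_factory=dict)
    unknown_sensors: set[str] = field(default_factory=set)

    def add_records(self, sensor: str, n: int) -> None:
        self.records_by_sensor[sensor] = self.records_by_sensor.get(sensor, 0) + n

    @property
    def records_total(self) -> int:
        return sum(self.records_by_sensor.values())

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["unknown_sensors"] = sorted(self.unknown_sensors)
        d["records_total"] = self.records_total
        return d


# ---------------------------------------------------------------------------
# JSON repair
# ---------------------------------------------------------------------------

_WS = frozenset(b" \t\r\n")
_OPEN = (ord("{"), ord("["))
_CLOSE = (ord("}"), ord("]"))


def _scan_string(raw: bytes, i: int) -> int | None:
    n = len(raw)
    i += 1
    while i < n:
        c = raw[i]
        if c == 0x5C:  # backslash
            i += 2
            continue
        if c == 0x22:  # quote
            return i + 1
        i += 1
    return None


def _scan_value(raw: bytes, i: int) -> int | None:
    """End offset of the JSON value starting at ``i``, or None if truncated."""
    n = len(raw)
    c = raw[i]
    if c == 0x22:
        return _scan_string(raw, i)
    if c in _OPEN:
        depth = 0
        while i < n:
            c = raw[i]
            if c == 0x22:
                j = _scan_string(raw, i)
                if j is None:
                    return None
                i = j
                continue
            if c in _OPEN:
                depth += 1
            elif c in _CLOSE:
                depth -= 1
                if depth == 0:
                    return i + 1
            i += 1
        return None
    j = i  # scalar: run to a delimiter; a scalar at EOF may be truncated
    while j < n and raw[j] not in b",]} \t\r\n":
        j += 1
    return None if j == n else j


def _scan_elements(raw: bytes) -> tuple[list[tuple[int, int]], int | None] | None:
    """Byte spans of complete top-level array elements.

    Returns ``(spans, closed_at)`` where ``closed_at`` is the offset just
    past the top-level closing bracket if it was reached, else None.
    Returns None outright if the input does not begin with ``[``.
    """
    n = len(raw)
    i = 0
    while i < n and raw[i] in _WS:
        i += 1
    if i >= n or raw[i] != 0x5B:  # '['
        return None
    i += 1
    spans: list[tuple[int, int]] = []
    while True:
        while i < n and (raw[i] in _WS or raw[i] == 0x2C):  # ws or comma
            i += 1
        if i >= n:
            return spans, None
        if raw[i] == 0x5D:  # ']'
            return spans, i + 1
        end = _scan_value(raw, i)
        if end is None:
            return spans, None
        spans.append((i, end))
        i = end


def repair_json(raw: bytes | str, salvage: bool = False) -> tuple[str, RepairOutcome]:
    """Repair a possibly-truncated JSON measurement array.

    Truncates after the last byte position at which the prefix is a
    complete sequence of top-level array elements, then closes the array;
    valid input passes through unchanged.  With ``salvage=True``,
    unparseable elements *mid*-array are dropped too (instead of stopping
    the kept prefix at the first bad element).  Never raises on bad input:
    hopeless bytes come back as status ``unfixable``.
    """
    if isinstance(raw, str):
        raw = raw.encode("utf-8")
    try:
        obj = json.loads(raw)
    except (ValueError, UnicodeDecodeError):
        obj = None
    if isinstance(obj, list):
        return raw.decode("utf-8"), RepairOutcome("valid", len(obj), 0)

    scanned = _scan_elements(raw)
    if scanned is None:
        return "", RepairOutcome("unfixable", 0, len(raw))
    spans, closed_at = scanned

    kept: list[tuple[int, int]] = []
    contiguous = True
    for s, e in spans:
        try:
            json.loads(raw[s:e])
        except (ValueError, UnicodeDecodeError):
            if salvage:
                contiguous = False
                continue
            break
        kept.append((s, e))
    if not kept:
        return "", RepairOutcome("unfixable", 0, len(raw))

    if contiguous:
        end = kept[-1][1]
        repaired = raw[:end] + b"]"
        discarded = len(raw) - end
    else:
        body = b",".join(raw[s:e] for s, e in kept)
        repaired = b"[" + body + b"]"
        discarded = len(raw) - sum(e - s for s, e in kept)
    try:
        text = repaired.decode("utf-8")
        parsed = json.loads(text)
    except (ValueError, UnicodeDecodeError):  # pragma: no cover - defensive
        return "", RepairOutcome("unfixable", 0, len(raw))
    return text, RepairOutcome("fixed", len(parsed), discarded)


# ---------------------------------------------------------------------------
# Unpack & decode
# ---------------------------------------------------------------------------

def unpack(raw_file: RawFile | str | Path) -> list[bytes]:
    """Member JSON byte streams of a raw file, in archive order.

    A loose JSON file yields itself, byte-identical.
    """
    if not isinstance(raw_file, RawFile):
        raw_file = RawFile.from_path(raw_file)
    if raw_file.container == "json":
        return [raw_file.path.read_bytes()]
    try:
        with zipfile.ZipFile(raw_file.path) as zf:
            return [zf.read(name) for name in zf.namelist()]
    except (zipfile.BadZipFile, OSError) as e:
        raise ArchiveError(f"{raw_file.path}: {e}") from e


def decode_record(
    obj: dict,
    participant_id: str,
    registry: SchemaRegistry | None = None,
) -> tuple[SensorRecord, bool]:
    """Decode one measurement object into a typed :class:`SensorRecord`.

    Returns ``(record, known)`` where ``known`` is False for sensors
    absent from the registry (retained with payload verbatim, flagged by
    the caller).  Raises :class:`DecodeError` for records missing the
    dialect's header keys or with unusable timestamps.
    """
    if not isinstance(obj, dict):
        raise DecodeError(f"measurement must be an object, got {type(obj).__name__}")
    rid = obj.get("id")
    ts = obj.get("timestamp")
    sensor = obj.get("sensor")
    if rid is None:
        raise DecodeError("missing id")
    if ts is None:
        raise DecodeError("missing timestamp")
    if not sensor or not isinstance(sensor, str):
        raise DecodeError("missing sensor")
    try:
        utc_ms, off_min = parse_timestamp(str(ts))
    except (ValueError, OverflowError) as e:
        raise DecodeError(f"bad timestamp {ts!r}: {e}") from e
    body = obj.get("body") or {}
    if not isinstance(body, dict):
        raise DecodeError("body must be an object")
    rec = SensorRecord(
        record_id=str(rid),
        participant_id=participant_id,
        sensor_name=sensor,
        timestamp_utc_ms=utc_ms,
        utc_offset_min=off_min,
        payload=body,
    )
    known = registry is None or sensor in registry
    if known and sensor in INERTIAL_SENSORS:
        try:
            rec.validate_inertial()
        except ValueError as e:
            raise DecodeError(str(e)) from e
    return rec, known


def _record_row(rec: SensorRecord) -> tuple:
    fields = payload_fields(rec.sensor_name)
    vals = []
    extra = {}
    for k, v in rec.payload.items():
        if k not in fields:
            extra[k] = v
    for f in fields:
        v = rec.payload.get(f)
        if f in TEXT_PAYLOAD_FIELDS:
            vals.append(None if v is None else str(v))
        else:
            vals.append(v if isinstance(v, (int, float)) and math.isfinite(v) else None)
    return (
        rec.record_id,
        rec.participant_id,
        rec.timestamp_utc_ms,
        rec.utc_offset_min,
        *vals,
        json.dumps(extra) if extra else None,
    )


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------

def iter_raw_files(root: str | Path):
    """Yield ``(participant_id, RawFile)`` over a per-participant tree.

    ``root`` contains one directory per participant; files directly under
    ``root`` are attributed to participant ``root.name``.  A ``ledger.json``
    (simulator ground truth) is never app output and is skipped.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    entries = sorted(root.iterdir())
    for entry in entries:
        if entry.name == "ledger.json":
            continue
        if entry.is_dir():
            for f in sorted(entry.iterdir()):
                if f.is_file() and f.suffix.lower() in (".zip", ".json"):
                    yield entry.name, RawFile.from_path(f)
        elif entry.is_file() and entry.suffix.lower() in (".zip", ".json"):
            yield root.name, RawFile.from_path(entry)


def import_stream(
    data: bytes,
    participant_id: str,
    store: SenseStore,
    registry: SchemaRegistry,
    report: ImportReport,
    salvage: bool = False,
) -> str:
    """Repair + decode + insert one JSON byte stream. Returns repair status."""
    text, outcome = repair_json(data, salvage=salvage)
    if outcome.status == "unfixable":
        return "unfixable"
    objs = json.loads(text)
    by_sensor: dict[str, list[tuple]] = {}
    device_info: dict | None = None
    for obj in objs:
        try:
            rec, known = decode_record(obj, participant_id, registry)
        except DecodeError:
            report.decode_errors += 1
            continue
        if not known:
            report.unknown_sensors.add(rec.sensor_name)
        by_sensor.setdefault(rec.sensor_name, []).append(_record_row(rec))
        if rec.sensor_name == "device":
            device_info = dict(rec.payload)
    for sensor, rows in by_sensor.items():
        inserted = store.insert_records(sensor, rows)
        report.add_records(sensor, inserted)
        report.duplicates_skipped += len(rows) - inserted
    store.upsert_participant(participant_id)
    if device_info:
        store.upsert_participant(
            participant_id,
            os=device_info.get("os"),
            os_version=device_info.get("os_version"),
            brand=device_info.get("brand"),
        )
    return outcome.status


def import_files(
    root: str | Path,
    store: SenseStore,
    registry: SchemaRegistry,
    salvage: bool = False,
) -> ImportReport:
    """Import every raw file under ``root`` exactly once (idempotent).

    Files already imported (by sha256) and records already present (by
    record_id) are skipped and counted as duplicates.  Per-file failures
    degrade to counts and never abort the batch; only an unusable store
    raises (:class:`~sensepipe.store.StorageError`).
    """
    store.initialize(registry)
    report = ImportReport()
    started = datetime.now(timezone.utc).isoformat()
    for participant_id, raw in iter_raw_files(root):
        report.files_seen += 1
        if store.file_seen(raw.sha256):
            report.duplicate_files += 1
            report.files_imported += 1  # imported previously; not unfixable
            continue
        try:
            streams = unpack(raw)
        except ArchiveError as e:
            log.warning("unreadable archive: %s", e)
            report.files_unfixable += 1
            store.remember_file(raw.sha256, str(raw.path), raw.container,
                               "unfixable", 0, raw.byte_size)
            continue
        statuses = []
        n_before = report.records_total
        for data in streams:
            statuses.append(
                import_stream(data, participant_id, store, registry, report,
                              salvage=salvage)
            )
        if statuses and all(s == "unfixable" for s in statuses):
            report.files_unfixable += 1
            status = "unfixable"
        else:
            report.files_imported += 1
            if any(s == "fixed" for s in statuses):
                report.files_repaired += 1
                status = "fixed"
            else:
                status = "valid"
        store.remember_file(raw.sha256, str(raw.path), raw.container, status,
                            report.records_total - n_before, raw.byte_size)
    store.log_import(started, report.to_dict())
    try:
        store.commit()
    except StorageError:
        raise
    for s in sorted(report.unknown_sensors):
        log.warning("unknown sensor: %s", s)
    log.info(
        "import: %d files seen, %d imported, %d repaired, %d unfixable, "
        "%d records", report.files_seen, report.files_imported,
        report.files_repaired, report.files_unfixable, report.records_total,
    )
    return report
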