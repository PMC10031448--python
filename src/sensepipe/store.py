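"""SQLite-backed relational store for sensing data.

Layout: one table per sensor (``record_id`` primary key, participant,
UTC-millisecond timestamp, UTC offset, typed payload columns, and a
``payload_json`` spill column for undocumented keys), plus
``participants``, ``files`` (sha256-keyed import ledger) and
``import_log``.  Each sensor table carries an index on
``(participant_id, timestamp_utc_ms)`` so window queries run inside
SQLite and only results cross into Python.

Binned inertial data live in ``accelerometer_1s`` / ``gyroscope_1s``
keyed by ``(participant_id, epoch_start_ms)``.
"""
from __future__ import annotations

import json
import sqlite3
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    DEFAULT_PAYLOAD_FIELDS,
    INERTIAL_SENSORS,
    TEXT_PAYLOAD_FIELDS,
    payload_fields,
)
from .schema import _NAME_RE, SchemaRegistry


class StorageError(RuntimeError):
    pass


def _check_name(sensor: str) -> str:
    if not _NAME_RE.match(sensor):
        raise StorageError(f"illegal sensor table name {sensor!r}")
    return sensor


_BIN_COLUMNS = ("n", "mean_x", "mean_y", "mean_z", "l1", "l2")


class SenseStore:
    """A relational store for one study (a single SQLite file)."""

    def __init__(self, path: str | Path = ":memory:", registry: SchemaRegistry | None = None):
        self.path = str(path)
        try:
            self.conn = sqlite3.connect(self.path)
        except sqlite3.Error as e:  # pragma: no cover - environment dependent
            raise StorageError(f"cannot open store at {self.path}: {e}") from e
        self.conn.execute("PRAGMA journal_mode=MEMORY")
        self.conn.execute("PRAGMA synchronous=OFF")
        self._create_meta()
        if registry is not None:
            self.initialize(registry)

    # -- schema ---------------------------------------------------------
    def _create_meta(self) -> None:
        c = self.conn
        c.execute(
            "CREATE TABLE IF NOT EXISTS participants ("
            "participant_id TEXT PRIMARY KEY, os TEXT, os_version TEXT, brand TEXT)"
        )
        c.execute(
            "CREATE TABLE IF NOT EXISTS files ("
            "sha256 TEXT PRIMARY KEY, path TEXT, container TEXT, status TEXT,"
            " records INTEGER, bytes INTEGER)"
        )
        c.execute(
            "CREATE TABLE IF NOT EXISTS import_log ("
            "id INTEGER PRIMARY KEY AUTOINCREMENT, started_at TEXT, report TEXT)"
        )
        c.commit()

    def initialize(self, registry: SchemaRegistry) -> None:
        """Create one table per registry sensor (idempotent)."""
        for sensor in registry:
            self.create_sensor_table(sensor)
        self.conn.commit()

    def create_sensor_table(self, sensor: str) -> None:
        _check_name(sensor)
        cols = []
        for f in payload_fields(sensor):
            typ = "TEXT" if f in TEXT_PAYLOAD_FIELDS else "REAL"
            cols.append(f"{f} {typ}")
        self.conn.execute(
            f"CREATE TABLE IF NOT EXISTS {sensor} ("
            "record_id TEXT PRIMARY KEY,"
            "participant_id TEXT NOT NULL,"
            "timestamp_utc_ms INTEGER NOT NULL,"
            "utc_offset_min INTEGER NOT NULL,"
            + ",".join(cols)
            + ", payload_json TEXT)"
        )
        self.conn.execute(
            f"CREATE INDEX IF NOT EXISTS idx_{sensor}_pt "
            f"ON {sensor} (participant_id, timestamp_utc_ms)"
        )

    def create_bin_table(self, sensor: str) -> str:
        _check_name(sensor)
        table = f"{sensor}_1s"
        self.conn.execute(
            f"CREATE TABLE IF NOT EXISTS {table} ("
            "participant_id TEXT NOT NULL,"
            "epoch_start_ms INTEGER NOT NULL,"
            "n INTEGER NOT NULL,"
            "mean_x REAL, mean_y REAL, mean_z REAL, l1 REAL, l2 REAL,"
            "PRIMARY KEY (participant_id, epoch_start_ms))"
        )
        return table

    def has_table(self, name: str) -> bool:
        row = self.conn.execute(
            "SELECT 1 FROM sqlite_master WHERE type='table' AND name=?", (name,)
        ).fetchone()
        return row is not None

    def sensor_tables(self) -> list[str]:
        rows = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'"
        ).fetchall()
        meta = {"participants", "files", "import_log", "sqlite_sequence"}
        return sorted(
            n for (n,) in rows if n not in meta and not n.endswith("_1s")
        )

    # -- records --------------------------------------------------------
    def insert_records(self, sensor: str, rows: Sequence[tuple]) -> int:
        """Insert rows, ignoring already-seen record_ids. Returns inserted count.

        Row layout: (record_id, participant_id, timestamp_utc_ms,
        utc_offset_min, *payload_columns, payload_json).
        """
        if not rows:
            return 0
        _check_name(sensor)
        if not self.has_table(sensor):
            self.create_sensor_table(sensor)
        ncols = 5 + len(payload_fields(sensor))
        ph = ",".join("?" * ncols)
        before = self.conn.total_changes
        try:
            self.conn.executemany(f"INSERT OR IGNORE INTO {sensor} VALUES ({ph})", rows)
        except sqlite3.Error as e:
            raise StorageError(f"insert into {sensor} failed: {e}") from e
        return self.conn.total_changes - before

    def record_count(self, sensor: str) -> int:
        _check_name(sensor)
        if not self.has_table(sensor):
            return 0
        return self.conn.execute(f"SELECT COUNT(*) FROM {sensor}").fetchone()[0]

    def record_counts(self) -> dict[str, int]:
        return {s: self.record_count(s) for s in self.sensor_tables()}

    def timestamps(
        self, participant_id: str, sensors: Iterable[str]
    ) -> "pd.Series":
        """All timestamps (ms) of a participant over the given sensor tables,
        sorted ascending; inertial sensors fall back to their 1-s bin table
        when the raw table is empty or dropped."""
        parts = []
        for s in sensors:
            t = self._resolve_time_table(s)
            if t is None:
                continue
            col = "epoch_start_ms" if t.endswith("_1s") else "timestamp_utc_ms"
            parts.append(f"SELECT {col} AS ts FROM {t} WHERE participant_id = ?")
        if not parts:
            return pd.Series([], dtype="int64")
        sql = " UNION ALL ".join(parts)
        df = pd.read_sql_query(
            f"SELECT DISTINCT ts FROM ({sql}) ORDER BY ts",
            self.conn,
            params=[participant_id] * len(parts),
        )
        return df["ts"].astype("int64")

    def _resolve_time_table(self, sensor: str) -> str | None:
        _check_name(sensor)
        if self.has_table(sensor) and self.record_count(sensor) > 0:
            return sensor
        if sensor in INERTIAL_SENSORS and self.has_table(f"{sensor}_1s"):
            return f"{sensor}_1s"
        if self.has_table(sensor):
            return sensor
        return None

    # -- participants & files ------------------------------------------
    def upsert_participant(self, participant_id: str, os: str | None = None,
                           os_version: str | None = None, brand: str | None = None) -> None:
        self.conn.execute(
            "INSERT INTO participants (participant_id, os, os_version, brand) "
            "VALUES (?,?,?,?) ON CONFLICT(participant_id) DO UPDATE SET "
            "os=COALESCE(excluded.os, os), "
            "os_version=COALESCE(excluded.os_version, os_version), "
            "brand=COALESCE(excluded.brand, brand)",
            (participant_id, os, os_version, brand),
        )

    def participants(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM participants ORDER BY participant_id", self.conn
        )

    def file_seen(self, sha256: str) -> bool:
        row = self.conn.execute(
            "SELECT 1 FROM files WHERE sha256=?", (sha256,)
        ).fetchone()
        return row is not None

    def remember_file(self, sha256: str, path: str, container: str,
                      status: str, records: int, nbytes: int) -> None:
        self.conn.execute(
            "INSERT OR IGNORE INTO files VALUES (?,?,?,?,?,?)",
            (sha256, path, container, status, records, nbytes),
        )

    def log_import(self, started_at: str, report: dict) -> None:
        self.conn.execute(
            "INSERT INTO import_log (started_at, report) VALUES (?,?)",
            (started_at, json.dumps(report)),
        )

    # -- misc -----------------------------------------------------------
    def query(self, sql: str, params: Sequence = ()) -> pd.DataFrame:
        return pd.read_sql_query(sql, self.conn, params=list(params))

    def commit(self) -> None:
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "SenseStore":
        return self

    def __exit__(self, *exc) -> None:
        self.commit()
        self.close()

    def content_fingerprint(self) -> dict[str, int]:
        """Cheap content digest used by idempotence checks: per-table row
        counts plus a checksum over record ids and timestamps."""
        out: dict[str, int] = {}
        for t in self.sensor_tables():
            n = self.record_count(t)
            (s,) = self.conn.execute(
                f"SELECT COALESCE(SUM(timestamp_utc_ms % 1000003), 0) FROM {t}"
            ).fetchone()
            out[t] = (n, s)  # type: ignore[assignment]
        return out
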