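"""Attach sensor records to ESM beeps within a time window.

ESM answers and passive sensing live on different timescales; analyses
need, say, the 30 minutes of location data before each beep.  ``link``
builds, for every beep, the half-open window
``[anchor - before_s, anchor + after_s)`` and attaches every record of
the requested sensors whose timestamp falls inside it and that belongs
to the beep's participant.  The window query executes inside SQLite;
only the linked rows are returned.  Records may legitimately attach to
several overlapping beeps; beeps with no records keep an empty map and
are never dropped.

The anchor defaults to the completion time when present, else the
schedule time.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .model import Beep, TimeWindow, parse_timestamp
from .store import SenseStore

log = logging.getLogger("sensepipe.linking")

_META_COLUMNS = {"beep_id", "participant_id", "scheduled_at", "answered_at"}


@dataclass
class LinkedBeep:
    beep: Beep
    window: TimeWindow
    records_by_sensor: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(df) for s, df in self.records_by_sensor.items()}


def read_beeps(path) -> pd.DataFrame:
    """Read the beep CSV dialect: ``beep_id, participant_id, scheduled_at,
    answered_at`` (ISO-8601; empty = unanswered) plus answer columns."""
    df = pd.read_csv(path, dtype={"beep_id": str, "participant_id": str})
    missing = {"beep_id", "participant_id", "scheduled_at"} - set(df.columns)
    if missing:
        raise ValueError(f"beep CSV missing columns: {sorted(missing)}")
    return df


def beeps_from_frame(df: pd.DataFrame) -> list[Beep]:
    out = []
    for row in df.to_dict("records"):
        scheduled, _ = parse_timestamp(str(row["scheduled_at"]))
        answered = None
        raw = row.get("answered_at")
        if raw is not None and not pd.isna(raw) and str(raw) != "":
            answered, _ = parse_timestamp(str(raw))
        answers = {k: v for k, v in row.items() if k not in _META_COLUMNS}
        out.append(
            Beep(str(row["beep_id"]), str(row["participant_id"]),
                 scheduled, answered, answers)
        )
    return out


def _resolve_table(store: SenseStore, sensor: str) -> str:
    """Sensor name -> store table; inertial names fall back to 1-s bins."""
    t = store._resolve_time_table(sensor)
    if t is None:
        raise KeyError(f"unknown sensor {sensor!r}: no such table in store")
    return t


def link(
    store: SenseStore,
    beeps: pd.DataFrame | list[Beep],
    sensors: list[str],
    before_s: float,
    after_s: float,
    anchor: str = "auto",
) -> list[LinkedBeep]:
    """Link sensor records to each beep within ``[anchor-before, anchor+after)``.

    ``before_s`` and ``after_s`` are non-negative seconds; at least one
    must be positive.  Unknown sensor names raise before any query runs.
    """
    if before_s < 0 or after_s < 0 or before_s + after_s <= 0:
        raise ValueError("need before_s >= 0, after_s >= 0 and a non-empty window")
    if isinstance(beeps, pd.DataFrame):
        beeps = beeps_from_frame(beeps)
    tables = {s: _resolve_table(store, s) for s in sensors}  # fail fast

    known = set(store.participants()["participant_id"])
    linked: list[LinkedBeep] = []
    cur = store.conn
    cur.execute("DROP TABLE IF EXISTS _link_beeps")
    cur.execute(
        "CREATE TEMP TABLE _link_beeps "
        "(beep_id TEXT, participant_id TEXT, w0 INTEGER, w1 INTEGER)"
    )
    rows = []
    for b in beeps:
        a = b.anchor_ms(anchor)
        w = TimeWindow(a - round(before_s * 1000), a + round(after_s * 1000))
        linked.append(LinkedBeep(b, w))
        rows.append((b.beep_id, b.participant_id, w.start_ms, w.end_ms))
        if b.participant_id not in known:
            warnings.warn(
                f"beep {b.beep_id}: participant {b.participant_id!r} absent from store",
                stacklevel=2,
            )
    cur.executemany("INSERT INTO _link_beeps VALUES (?,?,?,?)", rows)
    by_id = {lb.beep.beep_id: lb for lb in linked}
    for sensor, table in tables.items():
        tcol = "epoch_start_ms" if table.endswith("_1s") else "timestamp_utc_ms"
        df = store.query(
            f"SELECT b.beep_id, r.* FROM _link_beeps b JOIN {table} r "
            "ON r.participant_id = b.participant_id "
            f"AND r.{tcol} >= b.w0 AND r.{tcol} < b.w1 "
            f"ORDER BY b.beep_id, r.{tcol}"
        )
        for beep_id, sub in df.groupby("beep_id", sort=False):
            by_id[str(beep_id)].records_by_sensor[sensor] = sub.drop(
                columns=["beep_id"]
            ).reset_index(drop=True)
        for lb in linked:
            lb.records_by_sensor.setdefault(sensor, df.iloc[0:0].drop(columns=["beep_id"]))
    cur.execute("DROP TABLE IF EXISTS _link_beeps")
    return linked


def link_long(
    store: SenseStore,
    beeps: pd.DataFrame | list[Beep],
    sensors: list[str],
    before_s: float,
    after_s: float,
    anchor: str = "auto",
) -> pd.DataFrame:
    """Long-format view of :func:`link`: one row per attached record, with
    ``beep_id`` and ``sensor_name`` columns.  This is the CSV export."""
    linked = link(store, beeps, sensors, before_s, after_s, anchor)
    frames = []
    for lb in linked:
        for sensor, df in lb.records_by_sensor.items():
            if df.empty:
                continue
            out = df.copy()
            out.insert(0, "beep_id", lb.beep.beep_id)
            out.insert(1, "sensor_name", sensor)
            frames.append(out)
    if not frames:
        return pd.DataFrame(columns=["beep_id", "sensor_name"])
    return pd.concat(frames, ignore_index=True)
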