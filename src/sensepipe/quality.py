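"""Sampling-reliability statistics: coverage, gaps, night clipping.

Two complementary views of data quality:

* **Coverage** — per participant, sensor and half-open UTC hour, the
  actual number of measurements, and where the sampling schema defines
  an expectation, the *coverage rate* actual/expected (1.0 = the app
  did exactly what it was configured to do; 0.5 = half the data).
  Event-driven sensors have no expectation and their rate is undefined,
  never zero.  Rates are not clipped at 1: observed counts can exceed
  the schema.

* **Gaps** — maximal periods of at least ``threshold_s`` (default 5
  minutes) during which no reference sensor recorded anything, the
  signature of the OS suspending the app.  Spans before the first or
  after the last record are censored edges, not gaps.  Because device
  suspension at night is often benign (participant asleep, phone off),
  total gap time can exclude a local-time daily window (default
  midnight–06:00), clipping each gap against it using the participant's
  recorded UTC offset.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HOUR_MS, INERTIAL_SENSORS
from .schema import SchemaRegistry
from .store import SenseStore

log = logging.getLogger("sensepipe.quality")

DEFAULT_GAP_THRESHOLD_S = 300
#: Local seconds-of-day window excluded from gap totals (midnight-06:00).
DEFAULT_NIGHT_WINDOW = (0, 6 * 3600)


@dataclass(frozen=True)
class GapInterval:
    """A maximal period of sensing silence for one participant."""

    participant_id: str
    start_ms: int
    end_ms: int

    @property
    def duration_s(self) -> float:
        return (self.end_ms - self.start_ms) / 1000.0


@dataclass
class GapResult:
    gaps: list[GapInterval]
    censored_edges: list[tuple[int, int]]
    n_reference_records: int


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def expected_counts(registry: SchemaRegistry, sensor: str, os: str) -> float | None:
    """Schema-expected measurements per hour, or None when undefined.

    interval: 3600/period.  interval_burst: counted in 1-second-bin units,
    one bin per started burst second, i.e. (3600/period)*ceil(burst).
    daily: 1/24.  event sensors and sensors unsupported on the
    participant's OS: undefined.
    """
    schema = registry[sensor]  # KeyError for unknown sensor
    if not schema.supports(os):
        return None
    if schema.mode == "interval":
        return 3600.0 / schema.period_s
    if schema.mode == "interval_burst":
        return (3600.0 / schema.period_s) * math.ceil(schema.burst_s)
    if schema.mode == "daily":
        return 1.0 / 24.0
    return None  # event


def coverage_rate(actual: float, expected: float | None) -> float | None:
    """actual/expected, unclipped; None when the expectation is undefined."""
    if expected is None:
        return None
    if expected <= 0:
        raise ValueError("expected must be positive")
    return actual / expected


def hourly_counts(
    store: SenseStore,
    sensors: list[str] | None = None,
    participants: list[str] | None = None,
) -> pd.DataFrame:
    """Actual measurement counts per (participant, sensor, UTC hour).

    Hours are half-open ``[h, h+1h)`` buckets, so daily counts partition
    exactly.  Inertial sensors are counted as 1-s bins when their bin
    table exists.  Columns: participant_id, sensor_name, hour_start_ms,
    actual.
    """
    if sensors is None:
        sensors = store.sensor_tables()
    frames = []
    for sensor in sensors:
        table = store._resolve_time_table(sensor)
        if table is None:
            continue
        tcol = "epoch_start_ms" if table.endswith("_1s") else "timestamp_utc_ms"
        where, params = "", []
        if participants:
            where = (
                " WHERE participant_id IN (" + ",".join("?" * len(participants)) + ")"
            )
            params = list(participants)
        df = store.query(
            f"SELECT participant_id, ({tcol} / {HOUR_MS}) * {HOUR_MS} AS hour_start_ms,"
            f" COUNT(*) AS actual FROM {table}{where}"
            " GROUP BY participant_id, hour_start_ms",
            params,
        )
        if df.empty:
            continue
        df.insert(1, "sensor_name", sensor)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "sensor_name", "hour_start_ms", "actual"]
        )
    return pd.concat(frames, ignore_index=True)


def coverage(
    store: SenseStore,
    registry: SchemaRegistry,
    sensors: list[str] | None = None,
    participants: list[str] | None = None,
) -> pd.DataFrame:
    """Coverage cells: hourly actual counts joined with schema expectations.

    Adds ``expected`` and ``rate`` columns (NaN where undefined — event
    sensors, or sensors the participant's OS does not support).  The OS
    comes from the store's participants table.
    """
    cells = hourly_counts(store, sensors, participants)
    if cells.empty:
        return cells.assign(expected=pd.Series(dtype=float), rate=pd.Series(dtype=float))
    os_by_pid = dict(
        zip(store.participants()["participant_id"], store.participants()["os"])
    )
    expected = []
    for pid, sensor in zip(cells["participant_id"], cells["sensor_name"]):
        os = os_by_pid.get(pid)
        if os is None or sensor not in registry:
            expected.append(np.nan)
            continue
        e = expected_counts(registry, sensor, os)
        expected.append(np.nan if e is None else e)
    cells["expected"] = expected
    cells["rate"] = cells["actual"] / cells["expected"]
    return cells


def mean_rate_by_hour_of_day(cells: pd.DataFrame, utc_offset_min: int = 0) -> pd.DataFrame:
    """Average coverage rate per sensor and local hour-of-day (0-23).

    Averages per participant first, then across participants, so heavy
    users do not dominate the chart.
    """
    df = cells.dropna(subset=["rate"]).copy()
    if df.empty:
        return pd.DataFrame(columns=["sensor_name", "hour_of_day", "rate"])
    local = df["hour_start_ms"] + utc_offset_min * 60_000
    df["hour_of_day"] = (local // HOUR_MS) % 24
    per_part = (
        df.groupby(["sensor_name", "hour_of_day", "participant_id"])["rate"]
        .mean()
        .reset_index()
    )
    return (
        per_part.groupby(["sensor_name", "hour_of_day"])["rate"].mean().reset_index()
    )


def coverage_heatmap(cells: pd.DataFrame, ax=None):
    """Minimal sensor x hour-of-day heatmap of mean coverage rates."""
    import matplotlib.pyplot as plt

    table = mean_rate_by_hour_of_day(cells).pivot(
        index="sensor_name", columns="hour_of_day", values="rate"
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.4 * len(table) + 1))
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="RdYlBu", vmin=0)
    ax.set_yticks(range(len(table.index)), table.index)
    ax.set_xlabel("hour of day")
    ax.figure.colorbar(im, ax=ax, label="coverage rate")
    return ax


# ---------------------------------------------------------------------------
# Gaps
# ---------------------------------------------------------------------------

def gaps_from_timestamps(
    timestamps_ms: np.ndarray, threshold_s: float = DEFAULT_GAP_THRESHOLD_S
) -> list[tuple[int, int]]:
    """Maximal inter-timestamp spans of at least ``threshold_s`` seconds.

    Input need not be sorted or unique.  A gap runs from one record to
    the next, half-open.
    """
    if threshold_s <= 0:
        raise ValueError("threshold_s must be positive")
    ts = np.unique(np.asarray(timestamps_ms, dtype="int64"))
    if ts.size < 2:
        return []
    d = np.diff(ts)
    idx = np.nonzero(d >= threshold_s * 1000)[0]
    return [(int(ts[i]), int(ts[i + 1])) for i in idx]


def detect_gaps(
    store: SenseStore,
    participant_id: str,
    threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
    reference: str | list[str] = "any_sensor",
    observation: tuple[int, int] | None = None,
) -> GapResult:
    """Detect sensing gaps for one participant.

    ``reference`` selects the sensor set whose merged timestamps define
    "silence": ``"any_sensor"`` (every sensor table), ``"accelerometer"``
    (inertial-only view), or an explicit list of sensor names.  With an
    ``observation`` window ``(start_ms, end_ms)``, the spans before the
    first and after the last record are reported as censored edges.
    """
    if reference == "any_sensor":
        sensors = store.sensor_tables()
    elif isinstance(reference, str):
        sensors = [reference]
    else:
        sensors = list(reference)
    ts = store.timestamps(participant_id, sensors).to_numpy()
    if ts.size < 2:
        warnings.warn(
            f"participant {participant_id!r}: fewer than 2 reference records; "
            "no gaps detectable",
            stacklevel=2,
        )
        return GapResult([], [], int(ts.size))
    gaps = [
        GapInterval(participant_id, s, e)
        for s, e in gaps_from_timestamps(ts, threshold_s)
    ]
    edges = []
    if observation is not None:
        o0, o1 = observation
        if o0 < ts[0]:
            edges.append((int(o0), int(ts[0])))
        if ts[-1] < o1:
            edges.append((int(ts[-1]), int(o1)))
    return GapResult(gaps, edges, int(ts.size))


def _night_overlap_s(
    start_s: float, end_s: float, window: tuple[int, int]
) -> float:
    """Seconds of [start, end) falling inside the daily seconds-of-day window."""
    w0, w1 = window
    if w0 == w1:
        return 0.0
    halves = [(w0, w1)] if w0 < w1 else [(w0, 86400), (0, w1)]
    total = 0.0
    day = math.floor(start_s / 86400) * 86400
    while day < end_s:
        for a, b in halves:
            lo = max(start_s, day + a)
            hi = min(end_s, day + b)
            if hi > lo:
                total += hi - lo
        day += 86400
    return total


def clipped_gap_duration_s(
    gap: GapInterval,
    utc_offset_min: int = 0,
    exclude_local: tuple[int, int] | None = DEFAULT_NIGHT_WINDOW,
) -> float:
    """Gap duration minus its overlap with the local-time exclusion window."""
    if exclude_local is None:
        return gap.duration_s
    w0, w1 = exclude_local
    if not (0 <= w0 < 86400 and 0 <= w1 <= 86400):
        raise ValueError("exclusion window must be seconds-of-day in [0, 86400]")
    off = utc_offset_min * 60
    local_start = gap.start_ms / 1000.0 + off
    local_end = gap.end_ms / 1000.0 + off
    return gap.duration_s - _night_overlap_s(local_start, local_end, (w0, w1))


def total_gap_time(
    gaps: list[GapInterval],
    utc_offset_min: int | dict[str, int] = 0,
    exclude_local: tuple[int, int] | None = DEFAULT_NIGHT_WINDOW,
) -> pd.DataFrame:
    """Per-participant gap summary after night-window clipping.

    ``utc_offset_min`` is a single offset or a participant->offset map.
    Columns: participant_id, n_gaps, median_duration_s (of the raw,
    unclipped durations), total_gap_time_s (clipped).  Gaps of one
    participant are assumed disjoint.
    """
    rows: dict[str, dict] = {}
    for g in gaps:
        off = (
            utc_offset_min.get(g.participant_id, 0)
            if isinstance(utc_offset_min, dict)
            else utc_offset_min
        )
        r = rows.setdefault(
            g.participant_id, {"durations": [], "clipped": 0.0}
        )
        r["durations"].append(g.duration_s)
        r["clipped"] += clipped_gap_duration_s(g, off, exclude_local)
    out = [
        {
            "participant_id": pid,
            "n_gaps": len(r["durations"]),
            "median_duration_s": float(np.median(r["durations"])),
            "total_gap_time_s": r["clipped"],
        }
        for pid, r in sorted(rows.items())
    ]
    return pd.DataFrame(
        out,
        columns=["participant_id", "n_gaps", "median_duration_s", "total_gap_time_s"],
    )


# ---------------------------------------------------------------------------
# Per-OS export
# ---------------------------------------------------------------------------

def os_version_class(os: str, os_version: str) -> str:
    """Classify an OS version as old/new (iOS >= 15 and Android >= 11 are
    new; iOS <= 14 and Android <= 10 are old; anything unparseable is
    retained as 'unknown')."""
    try:
        major = int(str(os_version).split(".")[0])
    except (ValueError, AttributeError):
        return "unknown"
    if os == "ios":
        return "new" if major >= 15 else "old"
    if os == "android":
        return "new" if major >= 11 else "old"
    return "unknown"


def export_gap_table(
    store: SenseStore,
    threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
    reference: str | list[str] = "any_sensor",
    exclude_local: tuple[int, int] | None = DEFAULT_NIGHT_WINDOW,
) -> pd.DataFrame:
    """One row per participant: OS, version class, gap count, total gap time.

    This is the input table for downstream between-OS comparisons (run in
    any stats package); rows with zero gaps are present with total 0.
    """
    parts = store.participants()
    rows = []
    for _, p in parts.iterrows():
        pid = p["participant_id"]
        offs = _participant_offset(store, pid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = detect_gaps(store, pid, threshold_s, reference)
        summary = total_gap_time(res.gaps, offs, exclude_local)
        n_gaps = int(summary["n_gaps"].iloc[0]) if len(summary) else 0
        total = float(summary["total_gap_time_s"].iloc[0]) if len(summary) else 0.0
        os = p["os"] or "unknown"
        rows.append(
            {
                "participant_id": pid,
                "os": os,
                "os_version_class": os_version_class(os, p["os_version"]),
                "n_gaps": n_gaps,
                "total_gap_time_s": total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "os", "os_version_class", "n_gaps", "total_gap_time_s"],
    )


def _participant_offset(store: SenseStore, participant_id: str) -> int:
    """Participant's UTC offset in minutes, from any of their records."""
    for table in store.sensor_tables():
        row = store.conn.execute(
            f"SELECT utc_offset_min FROM {table} WHERE participant_id=? LIMIT 1",
            (participant_id,),
        ).fetchone()
        if row is not None:
            return int(row[0])
    return 0
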