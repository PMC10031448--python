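"""1-Hz binning of high-rate inertial streams.

Accelerometer and gyroscope streams arrive at many samples per second
and dominate storage; for most analyses one value per second suffices.
Each whole UTC second (half-open epoch ``[t, t+1s)``) with at least one
sample yields one row holding the sample count, per-axis arithmetic
means, and the mean per-sample Manhattan (L1) and Euclidean (L2)
magnitudes.  Norms are computed per sample and then averaged within the
second — not the norm of the mean — so oscillating motion retains its
energy (two samples (1,0,0) and (−1,0,0) give L2 = 1, where the norm of
the mean would give 0).  For every bin the vector-norm inequality
``l2 <= l1 <= sqrt(3)*l2`` holds, and it survives averaging.

``incremental_bin_import`` processes files in bounded-size chunks and
merges bins already in the store with pooled means, so the result is
identical to a single pass regardless of chunking and file order.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import ImportReport, decode_record, repair_json, unpack
from .model import INERTIAL_SENSORS
from .store import SenseStore

log = logging.getLogger("sensepipe.binning")

BIN_COLUMNS = ["participant_id", "epoch_start_ms", "n",
               "mean_x", "mean_y", "mean_z", "l1", "l2"]


class ChunkBudgetError(RuntimeError):
    """A single input exceeds the chunk budget; a larger budget is required."""


@dataclass
class BinResult:
    bins: pd.DataFrame  # BIN_COLUMNS
    n_excluded: int  # samples dropped for non-finite components


def bin_inertial(records: pd.DataFrame, participant_id: str | None = None) -> BinResult:
    """Bin raw inertial samples to one row per non-empty second.

    ``records`` needs columns ``timestamp_utc_ms, x, y, z`` (plus
    ``participant_id`` unless given explicitly).  Samples with non-finite
    components are excluded and counted, never propagated.
    """
    if records.empty:
        return BinResult(pd.DataFrame(columns=BIN_COLUMNS), 0)
    df = records
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    finite = np.isfinite(xyz).all(axis=1)
    n_excluded = int((~finite).sum())
    if n_excluded:
        df = df.loc[finite]
        xyz = xyz[finite]
    if df.empty:
        return BinResult(pd.DataFrame(columns=BIN_COLUMNS), n_excluded)
    epoch = (df["timestamp_utc_ms"].to_numpy(dtype="int64") // 1000) * 1000
    l1 = np.abs(xyz).sum(axis=1)
    l2 = np.sqrt((xyz**2).sum(axis=1))
    work = pd.DataFrame(
        {
            "participant_id": (
                participant_id if participant_id is not None else df["participant_id"].to_numpy()
            ),
            "epoch_start_ms": epoch,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "l1": l1,
            "l2": l2,
        }
    )
    g = work.groupby(["participant_id", "epoch_start_ms"], sort=True)
    out = g.agg(
        n=("l1", "size"),
        mean_x=("x", "mean"),
        mean_y=("y", "mean"),
        mean_z=("z", "mean"),
        l1=("l1", "mean"),
        l2=("l2", "mean"),
    ).reset_index()
    return BinResult(out[BIN_COLUMNS], n_excluded)


def merge_bins(store: SenseStore, sensor: str, bins: pd.DataFrame) -> None:
    """Upsert bins into ``<sensor>_1s``, pooling with any existing epoch row.

    Pooled mean: m = (n1*m1 + n2*m2) / (n1+n2) — identical to binning the
    concatenated raw samples in one pass.
    """
    table = store.create_bin_table(sensor)
    rows = list(
        bins[BIN_COLUMNS].itertuples(index=False, name=None)
    )
    store.conn.executemany(
        f"INSERT INTO {table} (participant_id, epoch_start_ms, n, mean_x, mean_y,"
        " mean_z, l1, l2) VALUES (?,?,?,?,?,?,?,?) "
        "ON CONFLICT(participant_id, epoch_start_ms) DO UPDATE SET "
        "mean_x=(mean_x*n + excluded.mean_x*excluded.n)/(n+excluded.n),"
        "mean_y=(mean_y*n + excluded.mean_y*excluded.n)/(n+excluded.n),"
        "mean_z=(mean_z*n + excluded.mean_z*excluded.n)/(n+excluded.n),"
        "l1=(l1*n + excluded.l1*excluded.n)/(n+excluded.n),"
        "l2=(l2*n + excluded.l2*excluded.n)/(n+excluded.n),"
        "n=n+excluded.n",
        rows,
    )


def bin_store(
    store: SenseStore,
    sensors: Sequence[str] = INERTIAL_SENSORS,
    chunk_rows: int = 2_000_000,
    keep_raw: bool = False,
) -> dict[str, int]:
    """Shrink raw inertial tables in the store to their 1-s bin tables.

    Rows are read in fixed-size chunks, binned, and merge-upserted; the
    pooled merge makes the outcome independent of where chunks split.
    Raw rows are dropped afterwards unless ``keep_raw``.  Returns bins
    written per sensor (bins touched twice by a boundary split count once).
    """
    written: dict[str, int] = {}
    for sensor in sensors:
        if not store.has_table(sensor):
            continue
        table = store.create_bin_table(sensor)
        offset = 0
        while True:
            df = store.query(
                f"SELECT participant_id, timestamp_utc_ms, x, y, z FROM {sensor} "
                "ORDER BY participant_id, timestamp_utc_ms LIMIT ? OFFSET ?",
                (chunk_rows, offset),
            )
            if df.empty:
                break
            res = bin_inertial(df)
            merge_bins(store, sensor, res.bins)
            offset += chunk_rows
        total = store.conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]
        if not keep_raw:
            store.conn.execute(f"DELETE FROM {sensor}")
        store.commit()
        written[sensor] = total
        log.info("binned %s: %d bins%s", sensor, total,
                 "" if keep_raw else " (raw rows dropped)")
    return written


def incremental_bin_import(
    files: Iterable[str | Path],
    store: SenseStore,
    participant_id: str,
    chunk_budget: int = 64 * 2**20,
) -> ImportReport:
    """Bin inertial records straight from raw files, in bounded chunks.

    Files are grouped into chunks whose total byte size stays within
    ``chunk_budget`` (a single file larger than the budget raises
    :class:`ChunkBudgetError`); each chunk is decoded, binned per sensor
    and merge-upserted, so the result equals a single pass over the
    concatenation regardless of chunk boundaries.
    """
    report = ImportReport()
    chunk: list[Path] = []
    size = 0

    def flush() -> None:
        nonlocal chunk, size
        if not chunk:
            return
        frames: dict[str, list[dict]] = {s: [] for s in INERTIAL_SENSORS}
        for path in chunk:
            for data in unpack(path):
                text, outcome = repair_json(data)
                if outcome.status == "unfixable":
                    continue
                for obj in json.loads(text):
                    try:
                        rec, _ = decode_record(obj, participant_id)
                    except Exception:
                        report.decode_errors += 1
                        continue
                    if rec.sensor_name in frames:
                        frames[rec.sensor_name].append(
                            {
                                "timestamp_utc_ms": rec.timestamp_utc_ms,
                                "x": rec.payload.get("x"),
                                "y": rec.payload.get("y"),
                                "z": rec.payload.get("z"),
                            }
                        )
        for sensor, recs in frames.items():
            if not recs:
                continue
            res = bin_inertial(pd.DataFrame(recs), participant_id)
            merge_bins(store, sensor, res.bins)
            report.add_records(sensor, len(recs) - res.n_excluded)
            report.decode_errors += res.n_excluded
        chunk, size = [], 0

    for f in files:
        f = Path(f)
        nbytes = f.stat().st_size
        if nbytes > chunk_budget:
            raise ChunkBudgetError(
                f"{f} is {nbytes} bytes, larger than the chunk budget "
                f"{chunk_budget}; increase the budget"
            )
        if size + nbytes > chunk_budget:
            flush()
        chunk.append(f)
        size += nbytes
        report.files_seen += 1
        report.files_imported += 1
    flush()
    store.commit()
    return report
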