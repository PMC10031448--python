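"""Study-level descriptive summary: file inventory, proportions, beep issues.

Every percentage in a summary is computed by one shared rule —
``100*count/total`` rounded half-up to two decimals — and is emitted
next to its numerator/denominator pair so the report is self-auditing:
each printed percentage re-derives exactly from its own counts.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from .ingest import ImportReport
from .store import SenseStore


def proportion(count: int, total: int) -> float:
    """Percentage ``100*count/total``, rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("need 0 <= count <= total")
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class FileInventory:
    n_files: int
    n_json: int
    n_zip: int
    n_repaired: int
    n_unfixable: int = 0
    pct_json: float = 0.0
    pct_zip: float = 0.0
    pct_repaired: float = 0.0

    def __post_init__(self) -> None:
        self.pct_json = proportion(self.n_json, self.n_files)
        self.pct_zip = proportion(self.n_zip, self.n_files)
        self.pct_repaired = proportion(self.n_repaired, self.n_files)


def file_inventory(source: ImportReport | SenseStore | Mapping) -> FileInventory:
    """Container/repair breakdown of an import batch.

    Accepts an :class:`ImportReport` plus-store pair is not needed: a
    store's ``files`` table, an ImportReport, or a plain mapping with
    ``n_json``/``n_zip``/``n_repaired`` counts all work.
    """
    if isinstance(source, SenseStore):
        df = source.query("SELECT container, status FROM files")
        if df.empty:
            raise ValueError("no input files")
        return FileInventory(
            n_files=len(df),
            n_json=int((df["container"] == "json").sum()),
            n_zip=int((df["container"] == "zip").sum()),
            n_repaired=int((df["status"] == "fixed").sum()),
            n_unfixable=int((df["status"] == "unfixable").sum()),
        )
    if isinstance(source, ImportReport):
        raise TypeError(
            "ImportReport does not carry container counts; pass the store"
        )
    n_json, n_zip = int(source["n_json"]), int(source["n_zip"])
    if n_json + n_zip == 0:
        raise ValueError("no input files")
    return FileInventory(
        n_files=n_json + n_zip,
        n_json=n_json,
        n_zip=n_zip,
        n_repaired=int(source.get("n_repaired", 0)),
        n_unfixable=int(source.get("n_unfixable", 0)),
    )


def beep_issue_rates(
    beeps: pd.DataFrame,
    issue_column: str = "app_issue",
    os_column: str = "os",
    flagged_value: str = "yes",
) -> pd.DataFrame:
    """Per-OS counts and percentage of beeps flagging an app issue.

    ``issue_column`` holds the answer to the "has your phone/app worked
    normally"-style item; a beep is flagged when the answer equals
    ``flagged_value``.  Columns: os, n_beeps, n_flagged, pct_flagged.
    """
    for col in (issue_column, os_column):
        if col not in beeps.columns:
            raise KeyError(f"beep table missing column {col!r}")
    rows = []
    for os, sub in beeps.groupby(os_column, sort=True):
        n = len(sub)
        flagged = int((sub[issue_column].astype(str) == flagged_value).sum())
        rows.append(
            {"os": os, "n_beeps": n, "n_flagged": flagged,
             "pct_flagged": proportion(flagged, n)}
        )
    return pd.DataFrame(rows, columns=["os", "n_beeps", "n_flagged", "pct_flagged"])


@dataclass
class StudySummary:
    n_participants: int
    files: FileInventory | None
    beeps: list[dict] = field(default_factory=list)
    cohort: dict = field(default_factory=dict)
    per_day: dict = field(default_factory=dict)
    records_by_sensor: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def render_text(self) -> str:
        lines = [f"participants: {self.n_participants}"]
        if self.files:
            f = self.files
            lines.append(
                f"files: {f.n_files} total — {f.n_json} JSON ({f.pct_json}%), "
                f"{f.n_zip} ZIP ({f.pct_zip}%), {f.n_repaired} repaired "
                f"({f.pct_repaired}%)"
            )
        for k, v in sorted(self.per_day.items()):
            lines.append(f"{k}: {v}")
        for b in self.beeps:
            lines.append(
                f"beep issues [{b['os']}]: {b['n_flagged']}/{b['n_beeps']} "
                f"({b['pct_flagged']}%)"
            )
        for cat, counts in sorted(self.cohort.items()):
            parts = ", ".join(
                f"{k}: {v['count']} ({v['pct']}%)" for k, v in sorted(counts.items())
            )
            lines.append(f"{cat}: {parts}")
        if self.records_by_sensor:
            total = sum(self.records_by_sensor.values())
            lines.append(f"records: {total}")
            for s, n in sorted(self.records_by_sensor.items()):
                lines.append(f"  {s}: {n} ({proportion(n, total)}%)")
        return "\n".join(lines)


def _category_counts(series: pd.Series) -> dict:
    total = len(series)
    out = {}
    for k, v in series.value_counts().items():
        out[str(k)] = {"count": int(v), "pct": proportion(int(v), total)}
    return out


def build_study_summary(
    store: SenseStore,
    beeps: pd.DataFrame | None = None,
    issue_column: str = "app_issue",
) -> StudySummary:
    """Assemble the descriptive study report from a store (+ beep table).

    Per-day file/volume averages are computed both ways — pooled
    (grand total / participant-days) and per-participant-first (mean of
    each participant's own rate) — and labelled, since the two disagree
    whenever spans differ.
    """
    parts = store.participants()
    n_participants = len(parts)
    inv = None
    files_df = store.query("SELECT container, status, bytes FROM files")
    if not files_df.empty:
        inv = file_inventory(store)
    summary = StudySummary(n_participants=n_participants, files=inv)
    if not parts.empty:
        summary.cohort["os"] = _category_counts(parts["os"].dropna())
        brands = parts["brand"].dropna()
        if len(brands):
            summary.cohort["brand"] = _category_counts(brands)
    summary.records_by_sensor = {
        k: v for k, v in store.record_counts().items() if v
    }
    # participant-days from observed record spans
    spans = store.query(
        " UNION ALL ".join(
            f"SELECT participant_id, MIN(timestamp_utc_ms) a, MAX(timestamp_utc_ms) b"
            f" FROM {t} GROUP BY participant_id"
            for t in store.sensor_tables()
        )
        or "SELECT NULL participant_id, NULL a, NULL b WHERE 0"
    )
    if not files_df.empty and not spans.empty:
        g = spans.groupby("participant_id").agg(a=("a", "min"), b=("b", "max"))
        days = ((g["b"] - g["a"]) / 86_400_000.0).clip(lower=1 / 24)
        total_days = float(days.sum())
        n_files = len(files_df)
        total_mb = float(files_df["bytes"].sum()) / 2**20
        summary.per_day = {
            "files_per_participant_day_pooled": round(n_files / total_days, 2),
            "mb_per_participant_day_pooled": round(total_mb / total_days, 2),
        }
    if beeps is not None and len(beeps):
        summary.beeps = beep_issue_rates(beeps, issue_column).to_dict("records")
    return summary
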