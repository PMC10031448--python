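"""Ground-truthed synthetic sensing streams, app output files, and beeps.

The generator replays a study's sampling schema through an alternating
renewal process of up-periods and gaps, then writes the raw files the
sensing app would have produced (sequential JSON files capped at 5 MB,
zipped, with optional tail-truncation corruption), together with a
ledger that fully determines what ingestion and the quality layer
should recover.

Phenomenology emulated:

* up-periods are exponential; gap durations log-normal with the median
  as the location parameter (heavy right tail, matching the observation
  that one OS family produces far longer gaps than the other).  Default
  medians: 453 s (7.55 min) for Android, 2841.6 s (47.36 min) for iOS.
* the mean up-time is calibrated so a 21-day run yields on average the
  reference gap counts (157 Android / 165 iOS): mean_uptime =
  21*86400/count − gap_median*exp(sigma²/2), the renewal-theoretic mean
  cycle length minus the mean gap.
* during up-periods interval sensors fire at their period from the
  up-period start; burst sensors emit ``burst_s`` seconds of samples at
  an inner rate (default 10 Hz, within the 5–50 Hz range devices
  deliver); event sensors fire as a Poisson process; daily sensors once
  per local day (at local noon, skipped if the app was down).
* sensors unsupported on the participant's OS never fire.

Everything is driven by one seed; identical (seed, parameters) give
byte-identical output.
"""
from __future__ import annotations

import json
import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import format_timestamp, parse_timestamp
from .schema import SchemaRegistry, pilot_registry

DEFAULT_GAP_MEDIAN_S = {"android": 453.0, "ios": 2841.6}
DEFAULT_GAP_COUNT_21D = {"android": 157, "ios": 165}
DEFAULT_BURST_HZ = 10.0
DEFAULT_EVENT_RATE_PER_HOUR = 60.0
DEFAULT_START = "2021-06-07T00:00:00+02:00"
DEFAULT_BEEP_ISSUE_RATE = {"android": 0.0134, "ios": 0.15}

_BRANDS = {"android": ("samsung", "oneplus", "nokia", "xiaomi"), "ios": ("apple",)}


@dataclass(frozen=True)
class GapProcess:
    """Alternating-renewal missingness: exponential up-times, log-normal gaps."""

    mean_uptime_s: float
    gap_median_s: float
    gap_sigma: float = 1.0
    night_gap_multiplier: float = 1.0  # >1 shortens up-times starting at night

    def __post_init__(self) -> None:
        if min(self.mean_uptime_s, self.gap_median_s, self.gap_sigma) <= 0:
            raise ValueError("GapProcess parameters must be positive")
        if self.night_gap_multiplier <= 0:
            raise ValueError("night_gap_multiplier must be positive")

    @classmethod
    def for_os(cls, os: str, days: float = 21.0, gap_sigma: float = 1.0,
               **overrides) -> "GapProcess":
        """OS defaults calibrated to the reference gap medians and counts."""
        median = DEFAULT_GAP_MEDIAN_S[os]
        count = DEFAULT_GAP_COUNT_21D[os]
        mean_gap = median * math.exp(gap_sigma**2 / 2)
        mean_up = days * 86400.0 / count - mean_gap
        params = {"mean_uptime_s": mean_up, "gap_median_s": median,
                  "gap_sigma": gap_sigma}
        params.update(overrides)
        return cls(**params)


@dataclass
class FileManifest:
    name: str
    container: str  # zip | json
    n_records: int
    corrupted: bool
    prefix_records: int  # records recoverable after repair
    byte_size: int


@dataclass
class SimLedger:
    """Ground truth of one simulated participant."""

    participant_id: str
    os: str
    os_version: str
    brand: str
    utc_offset_min: int
    start_ms: int
    end_ms: int
    records_by_sensor: dict[str, int] = field(default_factory=dict)
    up_periods_ms: list[tuple[int, int]] = field(default_factory=list)
    gaps_ms: list[tuple[int, int]] = field(default_factory=list)
    gap_draws_s: list[float] = field(default_factory=list)
    files: list[FileManifest] = field(default_factory=list)

    @property
    def records_total(self) -> int:
        return sum(self.records_by_sensor.values())

    @property
    def uptime_fraction(self) -> float:
        up = sum(e - s for s, e in self.up_periods_ms)
        return up / (self.end_ms - self.start_ms)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("participant_id", "os", "os_version", "brand",
                      "utc_offset_min", "start_ms", "end_ms",
                      "records_by_sensor", "up_periods_ms", "gaps_ms",
                      "gap_draws_s")
        }
        d["files"] = [f.__dict__ for f in self.files]
        return d


@dataclass
class SensorStream:
    sensor_name: str
    timestamps_ms: np.ndarray  # int64, sorted
    payload: dict[str, np.ndarray]


@dataclass
class SimResult:
    streams: list[SensorStream]
    ledger: SimLedger


def _up_periods(
    rng: np.random.Generator,
    duration_s: float,
    gp: GapProcess,
    start_local_s: float,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]], list[float]]:
    ups, gaps, draws = [], [], []
    t = 0.0
    mu = math.log(gp.gap_median_s)
    while t < duration_s:
        mean_up = gp.mean_uptime_s
        if gp.night_gap_multiplier != 1.0:
            sod = (start_local_s + t) % 86400
            if sod < 6 * 3600 or sod >= 22 * 3600:
                mean_up /= gp.night_gap_multiplier
        up = rng.exponential(mean_up)
        ups.append((t, min(t + up, duration_s)))
        t += up
        if t >= duration_s:
            break
        g = rng.lognormal(mu, gp.gap_sigma)
        draws.append(float(g))
        gaps.append((t, min(t + g, duration_s)))
        t += g
    return ups, gaps, draws


def _burst_times(u0: float, u1: float, period: float, burst: float, hz: float) -> np.ndarray:
    starts = np.arange(u0, u1, period)
    n_inner = max(1, round(burst * hz))
    offsets = np.arange(n_inner) / hz
    t = (starts[:, None] + offsets[None, :]).ravel()
    return t[t < u1]


def _payload(rng: np.random.Generator, sensor: str, n: int,
             device: tuple[str, str, str]) -> dict[str, np.ndarray]:
    if sensor in ("accelerometer", "gyroscope"):
        scale = 0.5 if sensor == "accelerometer" else 0.1
        z0 = 9.81 if sensor == "accelerometer" else 0.0
        return {
            "x": np.round(rng.normal(0, scale, n), 4),
            "y": np.round(rng.normal(0, scale, n), 4),
            "z": np.round(z0 + rng.normal(0, scale, n), 4),
        }
    if sensor == "location":
        return {
            "latitude": np.round(50.88 + rng.normal(0, 0.01, n), 6),
            "longitude": np.round(4.70 + rng.normal(0, 0.01, n), 6),
        }
    if sensor == "battery":
        return {"level": rng.integers(1, 101, n).astype(float)}
    if sensor == "device":
        os, ver, brand = device
        return {
            "os": np.repeat(os, n),
            "os_version": np.repeat(ver, n),
            "brand": np.repeat(brand, n),
        }
    return {"value": np.round(rng.normal(0, 1, n), 4)}


def simulate_participant(
    registry: SchemaRegistry | None = None,
    os: str = "android",
    days: float = 21.0,
    gap_process: GapProcess | None = None,
    seed: int = 0,
    participant_id: str = "p001",
    start: str = DEFAULT_START,
    burst_hz: float = DEFAULT_BURST_HZ,
    event_rate_per_hour: float = DEFAULT_EVENT_RATE_PER_HOUR,
    sensors: list[str] | None = None,
    os_version: str | None = None,
    brand: str | None = None,
) -> SimResult:
    """Simulate one participant's record stream plus its ground-truth ledger.

    ``sensors`` restricts the schedule to a subset of the registry (the
    full registry is the default study condition).  Reproducibility is
    mandatory: the same (seed, parameters) yield identical output.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if burst_hz <= 0 or event_rate_per_hour < 0:
        raise ValueError("rates must be positive")
    registry = registry if registry is not None else pilot_registry()
    if gap_process is None:
        gap_process = GapProcess.for_os(os)
    rng = np.random.default_rng(seed)
    start_ms, off_min = parse_timestamp(start)
    duration_s = days * 86400.0
    end_ms = start_ms + round(duration_s * 1000)
    if os_version is None:
        os_version = "11" if os == "android" else "15"
    if brand is None:
        brand = _BRANDS[os][0]
    device = (os, os_version, brand)

    ups, gaps, draws = _up_periods(
        rng, duration_s, gap_process, start_ms / 1000.0 + off_min * 60
    )
    ledger = SimLedger(
        participant_id, os, os_version, brand, off_min, start_ms, end_ms,
        up_periods_ms=[(start_ms + round(s * 1000), start_ms + round(e * 1000))
                       for s, e in ups],
        gaps_ms=[(start_ms + round(s * 1000), start_ms + round(e * 1000))
                 for s, e in gaps],
        gap_draws_s=draws,
    )

    wanted = list(sensors) if sensors is not None else list(registry)
    streams: list[SensorStream] = []
    for sensor in sorted(wanted):
        schema = registry[sensor]
        if not schema.supports(os):
            continue
        times: list[np.ndarray] = []
        if schema.mode == "interval":
            for u0, u1 in ups:
                times.append(np.arange(u0, u1, schema.period_s))
        elif schema.mode == "interval_burst":
            for u0, u1 in ups:
                times.append(
                    _burst_times(u0, u1, schema.period_s, schema.burst_s, burst_hz)
                )
        elif schema.mode == "event":
            for u0, u1 in ups:
                n = rng.poisson(event_rate_per_hour * (u1 - u0) / 3600.0)
                times.append(np.sort(rng.uniform(u0, u1, n)))
        elif schema.mode == "daily":
            off_s = off_min * 60
            local0 = start_ms / 1000.0 + off_s
            first_day = math.floor(local0 / 86400)
            last_day = math.floor((local0 + duration_s) / 86400)
            fires = []
            for d in range(first_day, last_day + 1):
                t = d * 86400 + 12 * 3600 - off_s - start_ms / 1000.0
                if 0 <= t < duration_s and any(u0 <= t < u1 for u0, u1 in ups):
                    fires.append(t)
            times.append(np.array(fires))
        t = np.concatenate(times) if times else np.array([])
        ts_ms = start_ms + np.round(t * 1000).astype("int64")
        payload = _payload(rng, sensor, ts_ms.size, device)
        streams.append(SensorStream(sensor, ts_ms, payload))
        ledger.records_by_sensor[sensor] = int(ts_ms.size)
    return SimResult(streams, ledger)


# ---------------------------------------------------------------------------
# App-output writer
# ---------------------------------------------------------------------------

def _render_lines(sim: SimResult) -> tuple[np.ndarray, list[str]]:
    """All records as JSON object strings, merged in timestamp order."""
    pid = sim.ledger.participant_id
    off = sim.ledger.utc_offset_min
    sign = "+" if off >= 0 else "-"
    suffix = f"{sign}{abs(off) // 60:02d}:{abs(off) % 60:02d}"
    all_ts: list[np.ndarray] = []
    all_lines: list[list[str]] = []
    for si, stream in enumerate(sim.streams):
        n = stream.timestamps_ms.size
        if n == 0:
            continue
        local = (stream.timestamps_ms + off * 60_000).astype("datetime64[ms]")
        ts_str = np.datetime_as_string(local)
        keys = list(stream.payload)
        cols = [stream.payload[k] for k in keys]
        sensor = stream.sensor_name
        lines = []
        dumps = json.dumps
        for i in range(n):
            body = {k: (c[i].item() if hasattr(c[i], "item") else c[i])
                    for k, c in zip(keys, cols)}
            lines.append(dumps(
                {"id": f"{pid}-{sensor}-{i:07d}",
                 "timestamp": f"{ts_str[i]}{suffix}",
                 "sensor": sensor, "body": body},
                separators=(",", ":"),
            ))
        all_ts.append(stream.timestamps_ms)
        all_lines.append(lines)
    if not all_ts:
        return np.array([], dtype="int64"), []
    ts = np.concatenate(all_ts)
    order = np.argsort(ts, kind="stable")  # stable: stream order breaks ties
    flat = [line for lines in all_lines for line in lines]
    return ts[order], [flat[o] for o in order]


def write_app_output(
    sim: SimResult,
    outdir: str | Path,
    max_file_mb: float = 5.0,
    zip_files: bool = True,
    corruption_rate: float = 0.0,
    corruption_mode: str = "truncate_tail",
    seed: int = 0,
) -> list[FileManifest]:
    """Write a participant's records as raw app output under ``outdir/<pid>``.

    Records go to sequential JSON files each at most ``max_file_mb``
    binary megabytes; completed files are zipped, the final file stays
    loose JSON.  With ``corruption_rate`` > 0, selected files are emitted
    loose, without their closing bracket, truncated at a seeded element
    boundary plus a few bytes into the next element; the manifest records
    how many records the repaired prefix holds.
    """
    if corruption_mode != "truncate_tail":
        raise ValueError(f"unknown corruption mode {corruption_mode!r}")
    pid = sim.ledger.participant_id
    outdir = Path(outdir) / pid
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {outdir}: {e}") from e
    _, lines = _render_lines(sim)
    cap = int(max_file_mb * 2**20)
    rng = np.random.default_rng(seed)
    manifests: list[FileManifest] = []

    chunks: list[list[str]] = []
    current: list[str] = []
    size = 2
    for line in lines:
        if current and size + len(line) + 1 > cap:
            chunks.append(current)
            current, size = [], 2
        current.append(line)
        size += len(line) + 1
    if current:
        chunks.append(current)

    for idx, chunk in enumerate(chunks):
        stem = f"{pid}_{idx:05d}"
        is_last = idx == len(chunks) - 1
        corrupt = corruption_rate > 0 and rng.random() < corruption_rate and len(chunk) >= 2
        if corrupt:
            m = int(rng.integers(1, len(chunk)))  # records kept after repair
            k = int(rng.integers(1, len(chunk[m])))  # bytes into the next element
            content = ("[" + ",".join(chunk[:m]) + "," + chunk[m][:k]).encode()
            path = outdir / f"{stem}.json"
            path.write_bytes(content)
            manifests.append(
                FileManifest(path.name, "json", len(chunk), True, m, len(content))
            )
            continue
        content = ("[" + ",".join(chunk) + "]").encode()
        if zip_files and not is_last:
            path = outdir / f"{stem}.zip"
            with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
                info = zipfile.ZipInfo(f"{stem}.json", date_time=(2021, 6, 7, 0, 0, 0))
                zf.writestr(info, content)
            manifests.append(
                FileManifest(path.name, "zip", len(chunk), False, len(chunk),
                             path.stat().st_size)
            )
        else:
            path = outdir / f"{stem}.json"
            path.write_bytes(content)
            manifests.append(
                FileManifest(path.name, "json", len(chunk), False, len(chunk),
                             len(content))
            )
    sim.ledger.files = manifests
    return manifests


def simulate_study(
    outdir: str | Path,
    registry: SchemaRegistry | None = None,
    n_participants: int = 5,
    days: float = 3.0,
    os_mix: float = 0.5,
    seed: int = 0,
    corruption_rate: float = 0.0,
    max_file_mb: float = 5.0,
    sensors: list[str] | None = None,
    write_ledger: bool = True,
    **participant_kwargs,
) -> list[SimLedger]:
    """Simulate a cohort and write its raw app output tree.

    ``os_mix`` is the fraction of Android participants (assigned
    deterministically from the seed).  OS versions split evenly between
    the old and new generation within each OS.  A JSON ledger of ground
    truth is written next to the output.
    """
    registry = registry if registry is not None else pilot_registry()
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    ledgers = []
    for i in range(n_participants):
        pid = f"p{i + 1:03d}"
        os = "android" if rng.random() < os_mix else "ios"
        new = rng.random() < 0.5
        os_version = ("11" if new else "10") if os == "android" else ("15" if new else "14")
        brand = _BRANDS[os][int(rng.integers(len(_BRANDS[os])))]
        sub_seed = int(rng.integers(2**31 - 1))
        sim = simulate_participant(
            registry, os=os, days=days, seed=sub_seed, participant_id=pid,
            sensors=sensors, os_version=os_version, brand=brand,
            **participant_kwargs,
        )
        write_app_output(
            sim, outdir, max_file_mb=max_file_mb,
            corruption_rate=corruption_rate, seed=sub_seed,
        )
        ledgers.append(sim.ledger)
    if write_ledger:
        (outdir / "ledger.json").write_text(
            json.dumps([l.to_dict() for l in ledgers], indent=1)
        )
    return ledgers


# ---------------------------------------------------------------------------
# ESM beeps
# ---------------------------------------------------------------------------

def simulate_beeps(
    participants: list[tuple[str, str]],
    days: float = 21.0,
    per_day: int = 10,
    seed: int = 0,
    start: str = DEFAULT_START,
    answer_prob: float = 0.8,
    issue_rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Synthetic beep table: ``per_day`` prompts per participant per day
    between 09:00 and 22:00 local, answered with probability
    ``answer_prob`` within 30 s - 15 min.  The ``app_issue`` answer column
    ("yes" = problem noticed) fires at the per-OS rates observed in
    practice; ``mood`` is a 1-7 filler item.
    """
    issue_rates = issue_rates or DEFAULT_BEEP_ISSUE_RATE
    rng = np.random.default_rng(seed)
    start_ms, off_min = parse_timestamp(start)
    rows = []
    n_days = int(days)
    slot = (22 - 9) * 3600 / per_day
    for pid, os in participants:
        for d in range(n_days):
            for k in range(per_day):
                sched_s = d * 86400 + 9 * 3600 + k * slot + rng.uniform(0, slot)
                sched_ms = start_ms + round(sched_s * 1000)
                answered = rng.random() < answer_prob
                ans_ms = sched_ms + round(rng.uniform(30, 900) * 1000) if answered else None
                issue = "yes" if (answered and rng.random() < issue_rates.get(os, 0)) else "no"
                rows.append(
                    {
                        "beep_id": f"{pid}-b{d:02d}{k:02d}",
                        "participant_id": pid,
                        "scheduled_at": format_timestamp(sched_ms, off_min),
                        "answered_at": (
                            format_timestamp(ans_ms, off_min) if answered else ""
                        ),
                        "app_issue": issue if answered else "",
                        "mood": int(rng.integers(1, 8)) if answered else "",
                        "os": os,
                    }
                )
    return pd.DataFrame(rows)
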