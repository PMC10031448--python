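# Methods

`sensepipe` is the data-processing and data-quality layer for smartphone
studies that combine experience sampling (ESM/EMA) with passive mobile
sensing. This note documents the conventions, models and numerical
choices the package commits to, and what its synthetic test bed does and
does not demonstrate about real data.

## Time conventions

All internal timestamps are UTC with millisecond precision (`int64`
epoch-milliseconds). Each record keeps the device's UTC offset in
minutes, because two operations are local-time concepts: the nightly
exclusion window in gap totals, and daily sensors firing once per local
calendar day. Every interval — 1-second binning epochs, hour buckets,
link windows, gaps — is half-open `[start, end)`. This single convention
makes counts partition exactly (the sum of hourly counts over a day
equals the day's record count, with no double-counted boundaries) and
fixes all tie-breaks: a record exactly at a window's left edge belongs
to it; one exactly at the right edge does not.

## Sampling schema and expected counts

A sensor's acquisition plan is one of four modes: `interval` (one
measurement per period), `interval_burst` (every period, record
continuously for a burst), `event` (fires when something happens) and
`daily`. The registry is a YAML document; two profiles ship with the
package, and the pilot profile is the default. The two profiles disagree
(most visibly on Wi-Fi: every 10 s vs every 10 min), so they are never
merged — choosing one is an explicit configuration decision.

Expected measurements per hour, the denominator of the coverage rate:

| mode           | expected per hour                  |
|----------------|------------------------------------|
| interval       | 3600 / period_s                    |
| interval_burst | (3600 / period_s) · ceil(burst_s)  |
| daily          | 1/24                               |
| event          | undefined                          |

Burst sensors are counted in 1-second-bin units (one unit per started
burst second) because inertial streams are stored binned; for the
default accelerometer plan (1 s of data every 5 s) this gives 720
bins/hour. Sensors the participant's OS does not support have undefined
expectations, not zero — a platform that cannot deliver a sensor is not
a coverage failure. Whether the light sensor is available on iOS is
genuinely ambiguous across sources; the default registry marks it
Android-only, and the `os` list in the YAML makes either choice a
one-line edit.

## JSON repair

The app appends measurement objects to a JSON array on disk and closes
the file at ~5 MB. If the OS kills the app mid-write, the file is left
unterminated, usually with a truncated final element. Repair truncates
after the last byte position at which the prefix is a complete sequence
of top-level array elements, then closes the array. The scanner is
string- and nesting-aware (brackets inside strings do not confuse it)
and each candidate element is re-validated with the stdlib JSON parser,
so the repaired sequence is always a *prefix* of the original element
sequence: at most one partial record is lost, and nothing is ever
invented. Inputs with no recoverable element are reported `unfixable`
and skipped, never raised — mirroring the manual-deletion fallback a
data manager would use. An optional salvage mode additionally drops
unparseable elements mid-array, for files with corruption in the middle
rather than at the tail.

## Import and idempotence

Deduplication is two-level: a sha256 fast path skips files already
imported byte-identically, and `INSERT OR IGNORE` on the `record_id`
primary key makes record-level dedup authoritative (re-uploads and
overlapping archives are harmless). Import is therefore idempotent and
order-independent: importing a batch twice, or in any file permutation,
yields an identical store. Per-file and per-record failures degrade to
counts in the import report; only an unusable store aborts a batch.

## Inertial binning

Within each non-empty second the package stores the sample count,
per-axis means, and the mean per-sample L1 (Manhattan) and L2
(Euclidean) magnitudes. Norms are averaged *per sample*, not taken of
the mean vector: under oscillation the mean vector cancels while motion
energy does not, and the per-sample convention preserves it (two
samples (1,0,0), (−1,0,0) give L2 = 1; the norm of the mean would give
0). Whether to average norms or norm averages was an open choice; the
package commits to per-sample-then-average and documents it here. The
vector-norm inequality `l2 ≤ l1 ≤ √3·l2` survives the averaging and is
enforced as a property test over random streams.

Chunked (incremental) binning merges a chunk's bins into existing rows
by pooled means, `m = (n₁m₁ + n₂m₂)/(n₁+n₂)`, which is algebraically
identical to single-pass binning; results are independent of chunk
boundaries and file order up to floating-point associativity (~1e-12
relative). Raw inertial rows are deleted after binning by default —
they dominate storage by an order of magnitude — with a `--keep-raw`
override.

## Linking

Each beep's window is `[anchor − before, anchor + after)`. The anchor
defaults to the completion time when the beep was answered, else the
schedule time: answers describe the moments before completion, and for
unanswered beeps the schedule is all there is. Both explicit anchors
are available. Records may attach to several overlapping beeps (this is
correct, not a bug: overlapping windows share data); beeps with no
records are kept with empty maps so compliance analyses see them. The
window join runs inside SQLite against the `(participant, timestamp)`
index; only linked rows cross into Python, which is what makes linking
tractable on multi-gigabyte stores.

## Gaps and night clipping

A gap is a maximal span of at least `threshold_s` (default 300 s)
between consecutive reference-sensor timestamps. Two reference choices
are built in — every sensor merged ("any sensor" silence, the default)
and accelerometer-only (a stricter view, since inertial sensors fire
essentially continuously while the app is alive) — selectable per call
and in the CLI. Spans before a participant's first and after their last
record are *censored edges*, reported separately and never counted as
gaps: counting them would inflate totals for late installers and early
dropouts.

Gap totals can exclude a local-time daily window, default
midnight–06:00, because overnight silence is usually the participant
asleep rather than the platform failing. Each gap is clipped against
the window analytically using the participant's recorded UTC offset
(a 23:50–00:20 gap contributes 10 minutes under the default window).
The exclusion window is configurable, including windows that cross
midnight. Gap counts and median durations are summarised per
participant first and only then aggregated by OS, so heavy users do not
dominate. The per-participant export (OS, version class, gap count,
total gap time) is the input table for between-OS comparisons in any
statistics package; version classes split at Android 11 and iOS 15.

## The synthetic generator

The generator exists so every stage is testable against ground truth
without access to any real cohort. It replays the registry through an
alternating renewal process: exponential up-periods, log-normal gap
durations. The log-normal is a deliberate choice — only medians of real
gap durations are typically reportable, and the family's heavy right
tail reproduces the observation that one OS family produces
dramatically longer gaps than the other — with the median as the
location parameter (`μ = ln(median)`) and shape `σ = 1` by default,
exposed as a parameter since the true family is unknown. Defaults:
Android median 453 s (7.55 min), iOS 2841.6 s (47.36 min). The mean
up-time is calibrated so a 21-day run produces the reference gap counts
in expectation (157 Android, 165 iOS): `mean_up = 21·86400/N −
median·e^{σ²/2}`, the renewal-theoretic cycle length minus the mean
gap.

During up-periods, interval sensors fire at their period from the
up-period start; burst sensors sample at 10 Hz inside bursts (devices
deliver 5–50 Hz; 10 Hz is a realistic middle that keeps desk-scale runs
tractable); event sensors fire as Poisson processes at 60/hour (the
order of magnitude of activity/pedometer-style event streams); daily
sensors fire at local noon and are skipped if the app is down. Records
are then serialized in timestamp order into sequential JSON files
capped at 5 binary MB, all but the last zipped; corruption truncates a
seeded file at a seeded element boundary plus a few bytes into the next
element, and the manifest records the recoverable prefix, giving an
exact oracle for repair. A JSON ledger (records per sensor, up/gap
intervals, file manifest) fully determines what ingestion and the
quality layer should recover. Everything derives from one seed;
identical seeds give byte-identical output.

What the generator does **not** emulate: physically realistic inertial
signals (white noise around gravity suffices for pipeline testing),
battery/weather semantics, diurnal behaviour (an optional night
multiplier on gap onset exists but is off by default), clock drift,
timezone changes mid-study, or duplicate uploads with re-serialized
(non-identical) bytes. Passing tests therefore demonstrate the
correctness of the *pipeline* — conservation, idempotence, window
logic, repair, recovery of known missingness — not the field realism of
any particular sensor stream.

## Numerical and reporting choices

- Every printed percentage is `100·count/total` rounded half-up to two
  decimals (`decimal`-based, no binary-float surprises), and is emitted
  next to its numerator/denominator pair so reports are self-auditing.
- Epoch assignment is `floor(t_ms / 1000)`; hour buckets are
  `floor(t_ms / 3_600_000)`.
- Participant-day averages are computed pooled (grand total over total
  participant-days); the per-participant-first variant differs whenever
  observation spans differ, and keys are labelled accordingly.
- Coverage rates are not clipped at 1 — event-adjacent interval sensors
  can over-deliver.
- Degenerate inputs: empty schema documents give empty registries;
  participants with fewer than two reference records yield no gaps plus
  a warning; an empty store yields empty (not missing) outputs.

## Problem sizes

The built-in study conditions used by the test suite and the
reproduction script are 5 participants × 3 days for the full-schema
round trip (~4 million records), 12 participants × 21 days per OS for
gap-process recovery, 200 corrupted files for repair recovery, and 1000
randomized small instances for the brute-force oracle comparisons —
sizes at which every check runs on a laptop in minutes while leaving
the statistics (medians within a few percent, coverage within 3
Monte-Carlo standard errors) well identified.

## Known limitations

- The measurement JSON dialect (`id`/`timestamp`/`sensor`/`body`) is
  the package's own documented fixture format; real deployments with a
  different field layout need only adapt `decode_record`.
- The ESM beep CSV layout is likewise repo-defined, since ESM platforms
  export in many shapes.
- Gap detection granularity is bounded by the reference sensors'
  sampling periods: a gap's endpoints are only known to within one
  period, and injected gaps shorter than threshold + one period may be
  missed.
- SQLite is the storage engine (single file, zero setup, runs the
  window queries server-side); studies needing concurrent writers
  should export to a multi-user database downstream.
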