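import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sensepipe as sp
from conftest import insert_location
from sensepipe.model import HOUR_MS, parse_timestamp
from sensepipe.quality import (
    DEFAULT_NIGHT_WINDOW,
    GapInterval,
    clipped_gap_duration_s,
    detect_gaps,
    expected_counts,
    gaps_from_timestamps,
    os_version_class,
    total_gap_time,
)

H0, _ = parse_timestamp("2021-06-07T10:00:00+00:00")


class TestExpectedCounts:
    @pytest.mark.parametrize(
        "sensor,os,expected",
        [
            ("accelerometer", "android", 720.0),  # one 1-s bin per 5-s burst
            ("light", "android", 600.0),          # 60 bursts x 10 bin-seconds
            ("location", "android", 60.0),
            ("weather", "ios", 1.0),
            ("calendar", "android", 1 / 24),
            ("screen", "android", None),          # event: undefined
            ("screen", "ios", None),              # unsupported OS: undefined
            ("memory", "ios", None),
        ],
    )
    def test_schema_expectations(self, registry, sensor, os, expected):
        assert expected_counts(registry, sensor, os) == expected

    def test_unknown_sensor_raises(self, registry):
        with pytest.raises(KeyError):
            expected_counts(registry, "thermometer", "android")

    def test_rates(self):
        assert sp.coverage_rate(30, 60) == 0.5
        assert sp.coverage_rate(60, 60) == 1.0
        assert sp.coverage_rate(90, 60) == 1.5  # not clipped at 1
        assert sp.coverage_rate(30, None) is None


class TestHourlyCounts:
    def test_sixty_records_in_one_hour(self, store):
        insert_location(store, "p1", H0 + np.arange(60) * 60_000)
        df = sp.hourly_counts(store, ["location"])
        assert len(df) == 1
        assert df["actual"].iloc[0] == 60
        assert df["hour_start_ms"].iloc[0] == H0

    def test_hourly_partition_is_exact(self, store):
        rng = np.random.default_rng(5)
        ts = H0 + rng.integers(0, 24 * HOUR_MS, 500)
        insert_location(store, "p1", ts)
        df = sp.hourly_counts(store, ["location"])
        assert df["actual"].sum() == 500

    def test_empty_store_gives_empty_frame(self, store):
        assert sp.hourly_counts(store).empty

    def test_full_uptime_day_matches_schedule(self, store, registry, gapfree):
        sim = sp.simulate_participant(
            registry, days=1, seed=8, participant_id="p1",
            sensors=["location"], gap_process=gapfree,
        )
        st = sim.streams[0]
        insert_location(store, "p1", st.timestamps_ms)
        df = sp.hourly_counts(store, ["location"])
        assert (df["actual"] == 60).all() and len(df) == 24

    def test_coverage_cells_join_expected(self, store, registry):
        insert_location(store, "p1", H0 + np.arange(30) * 60_000)
        cells = sp.coverage(store, registry, sensors=["location"])
        assert cells["expected"].iloc[0] == 60.0
        assert cells["rate"].iloc[0] == 0.5


class TestPresentation:
    def test_hour_of_day_averaging_and_heatmap(self, store, registry):
        import matplotlib

        matplotlib.use("Agg")
        insert_location(store, "p1", H0 + np.arange(120) * 60_000)
        cells = sp.coverage(store, registry, sensors=["location"])
        from sensepipe.quality import coverage_heatmap, mean_rate_by_hour_of_day

        hod = mean_rate_by_hour_of_day(cells)
        assert set(hod.columns) == {"sensor_name", "hour_of_day", "rate"}
        assert (hod["rate"] == 1.0).all()
        ax = coverage_heatmap(cells)
        assert ax is not None


class TestDetectGaps:
    def test_regular_sampling_has_no_gaps(self):
        assert gaps_from_timestamps(np.array([0, 60_000, 120_000]), 300) == []

    def test_single_long_span(self):
        assert gaps_from_timestamps(np.array([0, 400_000]), 300) == [(0, 400_000)]

    def test_store_detection_with_censored_edges(self, store):
        insert_location(store, "p1", [10_000, 20_000, 500_000])
        res = detect_gaps(store, "p1", 300, "location", observation=(0, 600_000))
        assert [(g.start_ms, g.end_ms) for g in res.gaps] == [(20_000, 500_000)]
        assert res.censored_edges == [(0, 10_000), (500_000, 600_000)]

    def test_under_two_records_warns_and_returns_empty(self, store):
        insert_location(store, "p1", [10_000])
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = detect_gaps(store, "p1", 300, "location")
        assert res.gaps == []

    def test_any_sensor_reference_merges_tables(self, store):
        # location silent for 10 min but battery kept firing: no gap under
        # the any-sensor reference, one gap under location-only reference
        insert_location(store, "p1", [0, 600_000])
        store.insert_records(
            "battery", [(f"b{i}", "p1", i * 100_000, 0, 50.0, None) for i in range(7)]
        )
        assert detect_gaps(store, "p1", 300, "location").gaps != []
        assert detect_gaps(store, "p1", 300, "any_sensor").gaps == []

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), thr=st.integers(10, 600))
    def test_matches_bruteforce_scan_and_threshold_monotonicity(self, seed, thr):
        rng = np.random.default_rng(seed)
        ts = rng.integers(0, 3_000_000, rng.integers(2, 60))
        rng.shuffle(ts)
        got = gaps_from_timestamps(ts, thr)
        srt = sorted(set(int(t) for t in ts))
        brute = [
            (a, b) for a, b in zip(srt, srt[1:]) if b - a >= thr * 1000
        ]
        assert got == brute
        # raising the threshold never adds gaps nor gap time
        wider = gaps_from_timestamps(ts, thr * 2)
        assert len(wider) <= len(got)
        assert sum(b - a for a, b in wider) <= sum(b - a for a, b in got)


class TestNightClipping:
    def test_gap_straddling_midnight_counts_ten_minutes(self):
        """23:50-00:20 local with a 00:00-06:00 exclusion leaves 10 min."""
        base, _ = parse_timestamp("2021-06-08T00:00:00+02:00")
        g = GapInterval("p1", base - 10 * 60_000, base + 20 * 60_000)
        assert clipped_gap_duration_s(g, 120, DEFAULT_NIGHT_WINDOW) == 600.0

    def test_no_exclusion_totals_raw_durations(self):
        gaps = [GapInterval("p1", 0, 400_000), GapInterval("p1", 10**6, 2 * 10**6)]
        df = total_gap_time(gaps, 0, exclude_local=None)
        assert df["total_gap_time_s"].iloc[0] == 400 + 1000
        assert df["n_gaps"].iloc[0] == 2

    def test_gap_entirely_inside_window_contributes_nothing(self):
        base, _ = parse_timestamp("2021-06-08T02:00:00+00:00")
        g = GapInterval("p1", base, base + 3600_000)
        assert clipped_gap_duration_s(g, 0) == 0.0

    def test_offset_shifts_the_window(self):
        # 01:00-02:00 UTC is 03:00-04:00 at +120 min (excluded) but
        # 20:00-21:00 at -300 min (fully counted)
        base, _ = parse_timestamp("2021-06-08T01:00:00+00:00")
        g = GapInterval("p1", base, base + 3600_000)
        assert clipped_gap_duration_s(g, 120) == 0.0
        assert clipped_gap_duration_s(g, -300) == 3600.0

    def test_multiday_gap_clips_every_night(self):
        base, _ = parse_timestamp("2021-06-08T00:00:00+00:00")
        g = GapInterval("p1", base, base + 2 * 86_400_000)
        assert clipped_gap_duration_s(g, 0) == 2 * 86400 - 2 * 6 * 3600

    def test_malformed_window_rejected(self):
        g = GapInterval("p1", 0, 1000)
        with pytest.raises(ValueError):
            clipped_gap_duration_s(g, 0, (0, 90_000))


class TestGapTableExport:
    @pytest.mark.parametrize(
        "os,version,cls",
        [
            ("android", "10", "old"), ("android", "11", "new"),
            ("android", "9", "old"), ("ios", "14", "old"),
            ("ios", "15", "new"), ("ios", "15.2", "new"),
            ("android", "tiramisu?", "unknown"),
        ],
    )
    def test_version_classification(self, os, version, cls):
        assert os_version_class(os, version) == cls

    def test_one_row_per_participant_including_zero_gap(self, store):
        insert_location(store, "p1", [0, 400_000])          # one gap
        insert_location(store, "p2", [0, 60_000, 120_000])  # none
        store.conn.execute(
            "UPDATE participants SET os_version='11' WHERE participant_id='p1'"
        )
        df = sp.export_gap_table(store, exclude_local=None)
        assert len(df) == 2
        row1 = df.set_index("participant_id").loc["p1"]
        assert row1["n_gaps"] == 1 and row1["total_gap_time_s"] == 400
        row2 = df.set_index("participant_id").loc["p2"]
        assert row2["n_gaps"] == 0 and row2["total_gap_time_s"] == 0.0


class TestGapUptimeDuality:
    def test_gap_plus_uptime_plus_edges_covers_observation_span(self, registry):
        """On synthetic data, detected gap time + covered time + censored
        edges partitions the observation span (to sampling granularity)."""
        sim = sp.simulate_participant(
            registry, days=2, seed=13, participant_id="p1", sensors=["location"]
        )
        led = sim.ledger
        store = sp.SenseStore(":memory:", registry)
        insert_location(store, "p1", sim.streams[0].timestamps_ms)
        res = detect_gaps(store, "p1", 300, "location",
                          observation=(led.start_ms, led.end_ms))
        gap_t = sum(g.duration_s for g in res.gaps)
        edge_t = sum((e - s) / 1000 for s, e in res.censored_edges)
        span = (led.end_ms - led.start_ms) / 1000
        covered = span - gap_t - edge_t
        true_up = sum(e - s for s, e in led.up_periods_ms) / 1000
        # covered time approximates true uptime to within one sampling
        # period per up-period plus sub-threshold gaps
        slack = 60 * (len(led.up_periods_ms) + len(led.gaps_ms)) + 300 * len(led.gaps_ms)
        assert abs(covered - true_up) <= slack
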