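import pandas as pd
import pytest

import sensepipe as sp


@pytest.fixture(scope="session")
def registry():
    return sp.pilot_registry()


@pytest.fixture()
def store(registry):
    with sp.SenseStore(":memory:", registry) as s:
        yield s


@pytest.fixture(scope="session")
def gapfree():
    """Gap process that effectively never gaps (for schedule-exact tests)."""
    return sp.GapProcess(mean_uptime_s=1e12, gap_median_s=1.0, gap_sigma=0.1)


def insert_location(store, participant_id, timestamps_ms, utc_offset_min=120,
                    prefix="r"):
    """Insert bare location rows at the given UTC-ms timestamps."""
    rows = [
        (f"{participant_id}-{prefix}{i}", participant_id, int(t),
         utc_offset_min, 50.88, 4.70, None)
        for i, t in enumerate(timestamps_ms)
    ]
    store.insert_records("location", rows)
    store.upsert_participant(participant_id, os="android")
    return rows


@pytest.fixture()
def beep_frame():
    return pd.DataFrame(
        [
            {"beep_id": "b1", "participant_id": "p1",
             "scheduled_at": "2021-06-07T12:00:00+02:00", "answered_at": ""},
            {"beep_id": "b2", "participant_id": "p1",
             "scheduled_at": "2021-06-07T15:00:00+02:00",
             "answered_at": "2021-06-07T15:03:00+02:00"},
        ]
    )
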