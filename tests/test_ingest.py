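import json
import zipfile

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sensepipe as sp
from sensepipe.ingest import DecodeError, decode_record, import_files, repair_json, unpack


def _array(n):
    return json.dumps([{"id": i, "v": i * 2} for i in range(n)]).encode()


class TestRepairJson:
    def test_valid_array_passes_through_unchanged(self):
        raw = b'[{"a": 1}, {"b": 2}]'
        text, out = repair_json(raw)
        assert text == raw.decode()
        assert out.status == "valid"
        assert out.records_recovered == 2
        assert out.bytes_discarded == 0

    def test_truncated_tail_is_dropped_at_element_boundary(self):
        text, out = repair_json(b'[{"a":1},{"b":')
        assert json.loads(text) == [{"a": 1}]
        assert out.status == "fixed"
        assert out.records_recovered == 1

    def test_garbage_is_unfixable(self):
        _, out = repair_json(b"\x00\xffnot json at all")
        assert out.status == "unfixable"
        assert out.records_recovered == 0

    def test_open_bracket_only_is_unfixable(self):
        _, out = repair_json(b"[")
        assert out.status == "unfixable"

    def test_nested_structures_and_strings_with_brackets(self):
        raw = b'[{"s": "a]}","n": [1,2,{"m": 3}]},{"x": "\\"quoted\\""},{"bro'
        text, out = repair_json(raw)
        assert out.status == "fixed"
        assert json.loads(text) == [
            {"s": "a]}", "n": [1, 2, {"m": 3}]},
            {"x": '"quoted"'},
        ]

    def test_salvage_drops_bad_elements_mid_array(self):
        raw = b'[{"a":1},{bad},{"c":3}]'
        _, strict = repair_json(raw)
        assert strict.records_recovered == 1
        text, out = repair_json(raw, salvage=True)
        assert json.loads(text) == [{"a": 1}, {"c": 3}]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(1, 12), cut=st.integers(1, 400))
    def test_truncation_always_recovers_longest_valid_prefix(self, n, cut):
        """Repair of a tail-truncated array equals the longest parseable
        prefix of the original element sequence (independent-parser check)."""
        raw = _array(n)
        cut = min(cut, len(raw) - 1)
        text, out = repair_json(raw[:cut])
        full = json.loads(raw)
        if out.status == "unfixable":
            assert out.records_recovered == 0
            return
        got = json.loads(text)  # independent parse of the repaired text
        assert got == full[: len(got)]
        assert out.records_recovered == len(got)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(blob=st.binary(max_size=120))
    def test_never_raises_on_arbitrary_bytes(self, blob):
        text, out = repair_json(blob)
        assert out.status in ("valid", "fixed", "unfixable")
        if out.status != "unfixable":
            assert isinstance(json.loads(text), list)


class TestUnpack:
    def test_zip_members_in_archive_order(self, tmp_path):
        p = tmp_path / "a.zip"
        with zipfile.ZipFile(p, "w") as zf:
            for i in range(3):
                zf.writestr(f"m{i}.json", f"[{i}]")
        assert unpack(p) == [b"[0]", b"[1]", b"[2]"]

    def test_loose_json_yields_itself(self, tmp_path):
        p = tmp_path / "a.json"
        p.write_bytes(b'[{"x": 1}]')
        assert unpack(p) == [b'[{"x": 1}]']

    def test_container_sniffed_from_content_not_extension(self, tmp_path):
        p = tmp_path / "lying.json"
        with zipfile.ZipFile(p, "w") as zf:
            zf.writestr("inner.json", "[1]")
        assert sp.RawFile.from_path(p).container == "zip"

    def test_garbled_archive_raises_with_path(self, tmp_path):
        p = tmp_path / "broken.zip"
        p.write_bytes(b"PK\x03\x04garbage")
        with pytest.raises(Exception, match="broken.zip"):
            unpack(p)


class TestDecodeRecord:
    def test_accelerometer_object(self, registry):
        rec, known = decode_record(
            {"id": "r1", "timestamp": "2021-06-07T10:00:00.500+02:00",
             "sensor": "accelerometer", "body": {"x": 0.1, "y": -0.2, "z": 9.8}},
            "p1", registry,
        )
        assert known
        assert rec.sensor_name == "accelerometer"
        assert rec.utc_offset_min == 120
        assert rec.timestamp_utc_ms == 1623052800500

    @pytest.mark.parametrize("drop", ["id", "timestamp", "sensor"])
    def test_missing_header_key_is_a_decode_error(self, registry, drop):
        obj = {"id": "r1", "timestamp": "2021-06-07T10:00:00+02:00",
               "sensor": "battery", "body": {"level": 80}}
        del obj[drop]
        with pytest.raises(DecodeError):
            decode_record(obj, "p1", registry)

    def test_nonfinite_inertial_component_is_a_decode_error(self, registry):
        with pytest.raises(DecodeError):
            decode_record(
                {"id": "r1", "timestamp": "2021-06-07T10:00:00+02:00",
                 "sensor": "gyroscope", "body": {"x": 1.0, "y": None, "z": 0.0}},
                "p1", registry,
            )

    def test_unknown_sensor_retained_and_flagged(self, registry):
        rec, known = decode_record(
            {"id": "r1", "timestamp": "2021-06-07T10:00:00+02:00",
             "sensor": "thermometer", "body": {"celsius": 21.5}},
            "p1", registry,
        )
        assert not known
        assert rec.payload == {"celsius": 21.5}


class TestImportFiles:
    @pytest.fixture()
    def batch(self, tmp_path, registry):
        ledgers = sp.simulate_study(
            tmp_path / "raw", registry, n_participants=2, days=1, seed=11,
            sensors=["location", "battery", "weather", "device"],
        )
        return tmp_path / "raw", ledgers

    def test_counts_equal_ledger_exactly(self, batch, store, registry):
        root, ledgers = batch
        rep = import_files(root, store, registry)
        want = {}
        for led in ledgers:
            for s, n in led.records_by_sensor.items():
                want[s] = want.get(s, 0) + n
        assert rep.records_by_sensor == want
        assert rep.files_seen == rep.files_imported + rep.files_unfixable
        assert rep.decode_errors == 0

    def test_idempotent_reimport_leaves_store_unchanged(self, batch, store, registry):
        root, _ = batch
        import_files(root, store, registry)
        fp1 = store.content_fingerprint()
        rep2 = import_files(root, store, registry)
        assert store.content_fingerprint() == fp1
        assert rep2.records_total == 0
        assert rep2.duplicate_files == rep2.files_seen

    def test_order_independence(self, tmp_path, registry):
        """Importing participants' files in any order yields identical content."""
        root = tmp_path / "raw"
        sp.simulate_study(root, registry, n_participants=2, days=1, seed=3,
                          sensors=["location", "battery"])
        fps = []
        for reverse in (False, True):
            with sp.SenseStore(":memory:", registry) as st:
                rep = sp.ImportReport()
                files = sorted(
                    ((d.name, f) for d in root.iterdir() if d.is_dir()
                     for f in d.iterdir()),
                    key=lambda t: t[1].name, reverse=reverse,
                )
                from sensepipe.ingest import import_stream, unpack

                for pid, f in files:
                    for data in unpack(f):
                        import_stream(data, pid, st, registry, rep)
                fps.append(st.content_fingerprint())
        assert fps[0] == fps[1]

    def test_device_records_populate_participants(self, batch, store, registry):
        root, ledgers = batch
        import_files(root, store, registry)
        parts = store.participants()
        assert set(parts["participant_id"]) == {l.participant_id for l in ledgers}
        assert set(parts["os"]) <= {"android", "ios"}

    def test_corrupted_batch_loses_only_truncated_tails(self, tmp_path, registry, store):
        root = tmp_path / "raw"
        ledgers = sp.simulate_study(
            root, registry, n_participants=1, days=1, seed=9,
            corruption_rate=0.5, max_file_mb=0.02,
            sensors=["location", "battery"],
        )
        rep = import_files(root, store, registry)
        led = ledgers[0]
        expect = sum(m.prefix_records for m in led.files)
        assert rep.records_total == expect
        assert rep.files_repaired == sum(m.corrupted for m in led.files)
        assert rep.files_repaired > 0
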