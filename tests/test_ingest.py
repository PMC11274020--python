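"""Message-log parsing, collar mapping, interval binning, day exclusion."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

import herdrank as hr
from herdrank.ingest import CollarMapError, MessageParseError

from conftest import message_csv


class TestParseMessageLog:
    def test_all_three_message_types_retained(self):
        src = message_csv([
            ("A", "2023-08-15T10:01:00Z", 55.42, 8.40, "poll"),
            ("A", "2023-08-15T10:05:00Z", 55.421, 8.401, "warning"),
            ("A", "2023-08-15T10:06:00Z", 55.422, 8.402, "zap"),
        ])
        parsed = hr.parse_message_log(src)
        assert len(parsed) == 3
        assert list(parsed.records["msg_type"]) == ["poll", "warning", "zap"]

    def test_empty_file_with_header(self):
        parsed = hr.parse_message_log(message_csv([]))
        assert len(parsed) == 0 and parsed.rejected == []

    def test_bad_latitude_strict_names_line(self):
        src = message_csv([
            ("A", "2023-08-15T10:01:00Z", 55.42, 8.40, "poll"),
            ("A", "2023-08-15T10:05:00Z", 95.0, 8.40, "poll"),
        ])
        with pytest.raises(MessageParseError, match="line 3"):
            hr.parse_message_log(src)

    def test_lenient_mode_keeps_accounting(self):
        src = message_csv([
            ("A", "2023-08-15T10:01:00Z", 55.42, 8.40, "poll"),
            ("A", "2023-08-15T10:05:00Z", 95.0, 8.40, "poll"),
            ("A", "not-a-time", 55.42, 8.40, "poll"),
            ("A", "2023-08-15T10:20:00", 55.42, 8.40, "poll"),  # no UTC designator
            ("A", "2023-08-15T10:30:00Z", 55.42, 8.40, "ping"),
        ])
        parsed = hr.parse_message_log(src, strict=False)
        assert len(parsed) == 1
        assert len(parsed.rejected) == 4
        assert [ln for ln, _ in parsed.rejected] == [3, 4, 5, 6]

    def test_missing_column_is_an_error(self):
        buf = message_csv([])
        buf = type(buf)("serial,timestamp,lat,lon\nA,2023-08-15T10:01:00Z,55,8\n")
        with pytest.raises(MessageParseError, match="missing columns"):
            hr.parse_message_log(buf)

    def test_write_read_round_trip(self, tmp_path, small_sim):
        path = tmp_path / "messages.csv"
        hr.write_message_log(small_sim.messages, path)
        parsed = hr.parse_message_log(path)
        assert len(parsed) == len(small_sim.messages)
        np.testing.assert_allclose(
            parsed.records["lat"], small_sim.messages["lat"], atol=1e-8
        )


class TestCollarMap:
    def test_replaced_collar_resolves_to_one_animal(self):
        cmap = hr.CollarMap(pd.DataFrame({
            "serial": ["A", "B"],
            "cow_id": ["Cow07", "Cow07"],
            "valid_from": [date(2023, 8, 15), date(2023, 8, 18)],
            "valid_to": [date(2023, 8, 17), date(2023, 10, 15)],
        }))
        src = message_csv([
            ("A", "2023-08-16T10:00:00Z", 55.42, 8.40, "poll"),
            ("B", "2023-08-20T10:00:00Z", 55.42, 8.40, "poll"),
        ])
        mapped = hr.apply_collar_map(hr.parse_message_log(src).records, cmap)
        assert list(mapped.records["cow_id"]) == ["Cow07", "Cow07"]
        assert len(mapped.records) == 2  # record count preserved

    def test_identity_map_keeps_distinct_ids(self):
        serials = [f"S{i:02d}" for i in range(17)]
        cmap = hr.CollarMap.identity(serials)
        rows = [(s, "2023-08-15T10:00:00Z", 55.42, 8.40, "poll") for s in serials]
        mapped = hr.apply_collar_map(
            hr.parse_message_log(message_csv(rows)).records, cmap
        )
        assert mapped.records["cow_id"].nunique() == 17

    def test_record_outside_window_raises_with_serial_and_date(self):
        cmap = hr.CollarMap(pd.DataFrame({
            "serial": ["A"], "cow_id": ["Cow01"],
            "valid_from": [date(2023, 8, 15)], "valid_to": [date(2023, 8, 20)],
        }))
        src = message_csv([("A", "2023-09-01T10:00:00Z", 55.42, 8.40, "poll")])
        with pytest.raises(CollarMapError, match="'A'"):
            hr.apply_collar_map(hr.parse_message_log(src).records, cmap)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(CollarMapError, match="overlap"):
            hr.CollarMap(pd.DataFrame({
                "serial": ["A", "B"], "cow_id": ["Cow01", "Cow01"],
                "valid_from": [date(2023, 8, 15), date(2023, 8, 18)],
                "valid_to": [date(2023, 8, 19), date(2023, 9, 1)],
            }))

    def test_serial_owned_by_two_animals_rejected(self):
        with pytest.raises(CollarMapError, match="more than one animal"):
            hr.CollarMap(pd.DataFrame({
                "serial": ["A", "A"], "cow_id": ["Cow01", "Cow02"],
                "valid_from": [date(2023, 8, 15), date(2023, 9, 15)],
                "valid_to": [date(2023, 8, 19), date(2023, 10, 1)],
            }))


class TestBin15Min:
    def _mapped(self, rows):
        parsed = hr.parse_message_log(message_csv(rows))
        cmap = hr.CollarMap.identity(parsed.records["serial"].unique())
        return hr.apply_collar_map(parsed.records, cmap).records

    def test_median_of_two_fixes(self):
        recs = self._mapped([
            ("A", "2023-08-15T00:03:00Z", 55.40, 8.40, "poll"),
            ("A", "2023-08-15T00:11:00Z", 55.42, 8.42, "poll"),
        ])
        out = hr.bin_15min(recs)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["interval_index"] == 0
        assert row["lat_med"] == pytest.approx(55.41)
        assert row["n_messages"] == 2

    def test_single_message_interval(self):
        out = hr.bin_15min(self._mapped(
            [("A", "2023-08-15T07:59:59Z", 55.40, 8.40, "poll")]
        ))
        assert len(out) == 1 and out.iloc[0]["n_messages"] == 1
        assert out.iloc[0]["interval_index"] == 31  # 07:45-08:00

    def test_boundary_belongs_to_later_interval(self):
        out = hr.bin_15min(self._mapped(
            [("A", "2023-08-15T00:15:00Z", 55.40, 8.40, "poll")]
        ))
        assert out.iloc[0]["interval_index"] == 1

    def test_binning_is_idempotent(self, small_intervals):
        # rebuild one record per existing interval at the interval start
        iv = small_intervals
        ts = (
            pd.to_datetime(iv["day"].astype(str)).dt.tz_localize("UTC")
            + pd.to_timedelta(iv["interval_index"] * 900, unit="s")
        )
        recs = pd.DataFrame({
            "cow_id": iv["cow_id"], "timestamp": ts,
            "lat": iv["lat_med"], "lon": iv["lon_med"], "msg_type": "poll",
        })
        again = hr.bin_15min(recs)
        pd.testing.assert_frame_equal(
            again[["cow_id", "day", "interval_index", "lat_med", "lon_med"]],
            iv[["cow_id", "day", "interval_index", "lat_med", "lon_med"]],
        )

    def test_empty_input(self):
        out = hr.bin_15min(pd.DataFrame(columns=["cow_id", "timestamp", "lat", "lon"]))
        assert len(out) == 0


class TestExcludeDays:
    def _intervals(self, day_cows):
        rows = []
        for day, cows in day_cows.items():
            for c in cows:
                rows.append({"cow_id": c, "day": date.fromisoformat(day),
                             "interval_index": 0, "lat_med": 55.4,
                             "lon_med": 8.4, "n_messages": 1})
        return pd.DataFrame(rows)

    def test_days_below_threshold_excluded(self):
        herd = [f"C{i}" for i in range(17)]
        iv = self._intervals({
            "2023-08-15": herd, "2023-08-16": herd[:16],
            "2023-08-17": herd, "2023-08-18": herd[:10],
            "2023-08-19": herd[:16],
        })
        kept, report = hr.exclude_days(iv, required_cows=17)
        excluded = [str(e["day"]) for e in report.excluded_days]
        assert excluded == ["2023-08-16", "2023-08-18", "2023-08-19"]
        assert sorted(str(d) for d in report.kept_days) == ["2023-08-15", "2023-08-17"]
        assert set(kept["day"]) == {date(2023, 8, 15), date(2023, 8, 17)}

    def test_all_days_complete(self):
        herd = [f"C{i}" for i in range(5)]
        iv = self._intervals({"2023-08-15": herd, "2023-08-16": herd})
        kept, report = hr.exclude_days(iv)
        assert report.excluded_days == [] and len(kept) == len(iv)

    def test_threshold_one_keeps_every_nonempty_day(self):
        iv = self._intervals({"2023-08-15": ["C0"], "2023-08-16": ["C0", "C1"]})
        kept, report = hr.exclude_days(iv, required_cows=1)
        assert report.excluded_days == []
        assert kept["day"].nunique() == 2

    def test_report_serialises(self):
        iv = self._intervals({"2023-08-15": ["C0", "C1"], "2023-08-16": ["C0"]})
        _, report = hr.exclude_days(iv, required_cows=2)
        text = report.to_json()
        assert "2023-08-16" in text and "cows_registered" in text
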