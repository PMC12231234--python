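"""CTD/ADCP reading, QC, burst averaging, and daily aggregation."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefmon import mooring_sim, timeseries_io as tio
from reefmon.types import EmptyInputError, FormatError

from ._oracles import naive_burst_means
from .conftest import make_ctd_records


CTD_HEADER = "timestamp,temperature_C,salinity_PSU,station,deployment\n"


class TestReadCtd:
    def test_well_formed_rows_parsed_in_timestamp_order(self, tmp_path):
        p = tmp_path / "ctd.csv"
        p.write_text(
            CTD_HEADER
            + "2021-06-01T00:00:10Z,30.1,39.0,A,d1\n"
            + "2021-06-01T00:00:00Z,30.0,39.1,A,d1\n"
            + "2021-06-01T00:00:20Z,30.2,39.2,A,d1\n"
        )
        df = tio.read_ctd(p)
        assert len(df) == 3
        assert df["timestamp"].is_monotonic_increasing
        assert df["temperature_c"].tolist() == [30.0, 30.1, 30.2]

    def test_out_of_range_temperature_dropped(self, tmp_path, caplog):
        p = tmp_path / "ctd.csv"
        p.write_text(
            CTD_HEADER
            + "2021-06-01T00:00:00Z,30.0,39.0,A,d1\n"
            + "2021-06-01T00:00:10Z,99.9,39.0,A,d1\n"
            + "2021-06-01T00:00:20Z,30.1,39.0,A,d1\n"
        )
        with caplog.at_level("INFO", logger="reefmon.timeseries_io"):
            df = tio.read_ctd(p)
        assert len(df) == 2
        assert any("dropped 1" in m for m in caplog.messages)

    def test_bad_header_is_format_error(self, tmp_path):
        p = tmp_path / "ctd.csv"
        p.write_text("time,temp\n1,2\n")
        with pytest.raises(FormatError):
            tio.read_ctd(p)

    def test_all_rows_invalid_is_empty_input_error(self, tmp_path):
        p = tmp_path / "ctd.csv"
        p.write_text(CTD_HEADER + "2021-06-01T00:00:00Z,99.9,39.0,A,d1\n")
        with pytest.raises(EmptyInputError):
            tio.read_ctd(p)

    def test_synthetic_file_round_trips_with_generator_count(self, tmp_path, short_scenario):
        ledger = mooring_sim.generate_files(short_scenario, tmp_path)
        df = tio.read_ctd(tmp_path / "ctd_A.csv")
        assert len(df) == ledger.record_counts["ctd_A"]
        back = tmp_path / "back.csv"
        tio.write_ctd(df, back)
        df2 = tio.read_ctd(back)
        pd.testing.assert_frame_equal(df, df2, check_exact=False, rtol=0, atol=1e-9)


class TestBurstAverage:
    def test_constant_samples_yield_their_value(self):
        rows = [(f"2021-06-01T00:00:{s:02d}Z", 30.0, 39.0, "A", "d1") for s in range(10)]
        out = tio.burst_average(make_ctd_records(rows))
        assert len(out) == 1
        assert out.loc[0, "temperature_mean"] == 30.0
        assert out.loc[0, "n_samples"] == 10

    def test_two_samples_average(self):
        rows = [
            ("2021-06-01T00:10:00Z", 29.0, 39.0, "A", "d1"),
            ("2021-06-01T00:20:00Z", 31.0, 39.0, "A", "d1"),
        ]
        out = tio.burst_average(make_ctd_records(rows))
        assert out.loc[0, "temperature_mean"] == 30.0
        assert out.loc[0, "n_samples"] == 2
        assert out.loc[0, "burst_start"] == pd.Timestamp("2021-06-01T00:00:00Z")

    def test_random_placement_matches_brute_force_group_by(self, rng):
        base = dt.datetime(2021, 6, 1, tzinfo=dt.timezone.utc)
        rows, samples = [], []
        for _ in range(500):
            ts = base + dt.timedelta(seconds=int(rng.integers(0, 86400)))
            v = float(rng.uniform(25, 33))
            rows.append((ts.isoformat(), v, 39.0, "A", "d1"))
            samples.append((ts, v))
        out = tio.burst_average(make_ctd_records(rows))
        expected = naive_burst_means(samples)
        got = {ts.to_pydatetime(): v for ts, v in zip(out["burst_start"], out["temperature_mean"])}
        assert got.keys() == expected.keys()
        for k in expected:
            assert got[k] == pytest.approx(expected[k], abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(perm_seed=st.integers(0, 2**20))
    def test_invariant_to_sample_ordering(self, perm_seed):
        r = np.random.default_rng(perm_seed)
        n = 40
        ts = pd.to_datetime("2021-06-01", utc=True) + pd.to_timedelta(
            r.integers(0, 6 * 3600, n), unit="s"
        )
        df = pd.DataFrame(
            {
                "timestamp": ts,
                "temperature_c": r.uniform(25, 33, n),
                "salinity_psu": r.uniform(38, 40, n),
                "station": "A",
                "deployment": "d1",
            }
        )
        shuffled = df.sample(frac=1, random_state=int(perm_seed) % 2**31).reset_index(drop=True)
        a = tio.burst_average(df).reset_index(drop=True)
        b = tio.burst_average(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_overlapping_deployments_average_with_equal_weight(self):
        rows = [
            ("2021-06-01T00:05:00Z", 30.0, 39.0, "A", "d1"),
            ("2021-06-01T00:10:00Z", 30.0, 39.0, "A", "d1"),
            ("2021-06-01T00:15:00Z", 31.0, 39.0, "A", "d2"),
        ]
        out = tio.burst_average(make_ctd_records(rows))
        # d1 mean 30.0, d2 mean 31.0 -> equal-weight merge 30.5
        assert out.loc[0, "temperature_mean"] == pytest.approx(30.5)

    def test_station_duplicated_as_second_deployment_is_a_no_op(self, rng):
        n = 60
        ts = pd.to_datetime("2021-06-01", utc=True) + pd.to_timedelta(
            rng.integers(0, 86400, n), unit="s"
        )
        one = pd.DataFrame(
            {
                "timestamp": ts,
                "temperature_c": rng.uniform(25, 33, n),
                "salinity_psu": rng.uniform(38, 40, n),
                "station": "A",
                "deployment": "d1",
            }
        )
        dup = pd.concat([one, one.assign(deployment="d2")], ignore_index=True)
        a = tio.reduce_ctd(one)
        b = tio.reduce_ctd(dup)
        pd.testing.assert_frame_equal(a, b)


class TestDailyAggregate:
    def _bursts(self, rows):
        df = pd.DataFrame(
            rows, columns=["burst_start", "station", "temperature_mean", "salinity_mean", "n_samples"]
        )
        df["burst_start"] = pd.to_datetime(df["burst_start"], utc=True)
        return df

    def test_single_station_mean_max_min(self):
        rows = [
            ("2021-06-01T04:00:00Z", "A", 28.0, 39.0, 10),
            ("2021-06-01T05:00:00Z", "A", 29.0, 39.0, 10),
            ("2021-06-01T06:00:00Z", "A", 30.0, 39.0, 10),
        ]
        out = tio.daily_aggregate(self._bursts(rows))
        assert len(out) == 1
        assert out.loc[0, "st_mean"] == 29.0
        assert out.loc[0, "st_max"] == 30.0
        assert out.loc[0, "st_min"] == 28.0
        assert out.loc[0, "stations_present"] == "A"

    def test_identical_stations_match_single_station(self):
        rows_a = [
            ("2021-06-01T04:00:00Z", "A", 28.0, 39.0, 10),
            ("2021-06-01T05:00:00Z", "A", 30.0, 39.0, 10),
        ]
        rows_b = [(t, "B", v, s, n) for t, _, v, s, n in rows_a]
        solo = tio.daily_aggregate(self._bursts(rows_a))
        both = tio.daily_aggregate(self._bursts(rows_a + rows_b))
        for col in ("st_mean", "st_max", "st_min", "salinity_mean"):
            assert both.loc[0, col] == solo.loc[0, col]
        assert both.loc[0, "stations_present"] == "A,B"

    @pytest.mark.parametrize("merge", ["mean", "pool"])
    def test_two_random_stations_match_brute_force(self, merge, rng):
        rows = []
        for station in ("A", "B"):
            for d in range(3):
                for h in range(0, 24, 2):
                    rows.append(
                        (
                            f"2021-06-{d + 1:02d}T{h:02d}:00:00Z",
                            station,
                            float(rng.uniform(26, 33)),
                            float(rng.uniform(38.5, 39.5)),
                            10,
                        )
                    )
        bursts = self._bursts(rows)
        out = tio.daily_aggregate(bursts, merge=merge).set_index("date")
        # brute force with plain dicts (local day = UTC+3)
        by_day_station: dict = {}
        for ts, station, v in zip(bursts["burst_start"], bursts["station"], bursts["temperature_mean"]):
            day = (ts + pd.Timedelta(hours=3)).date()
            by_day_station.setdefault(day, {}).setdefault(station, []).append(float(v))
        for day, per_station in by_day_station.items():
            row = out.loc[pd.Timestamp(day)]
            if merge == "pool":
                allv = [v for vs in per_station.values() for v in vs]
                exp = (sum(allv) / len(allv), max(allv), min(allv))
            else:
                means = [sum(vs) / len(vs) for vs in per_station.values()]
                exp = (
                    sum(means) / len(means),
                    max(max(vs) for vs in per_station.values()),
                    min(min(vs) for vs in per_station.values()),
                )
            assert row["st_mean"] == pytest.approx(exp[0], abs=1e-12)
            assert row["st_max"] == pytest.approx(exp[1], abs=1e-12)
            assert row["st_min"] == pytest.approx(exp[2], abs=1e-12)

    def test_min_le_mean_le_max_everywhere(self, short_ctd):
        ctd, _ = short_ctd
        daily = tio.reduce_ctd(pd.concat(ctd.values(), ignore_index=True))
        assert (daily["st_min"] <= daily["st_mean"] + 1e-12).all()
        assert (daily["st_mean"] <= daily["st_max"] + 1e-12).all()


class TestReadAdcp:
    def _write(self, tmp_path, rows):
        p = tmp_path / "adcp.csv"
        p.write_text(
            "timestamp,station,cell_index,height_m,speed_ms,direction_deg\n"
            + "".join(",".join(map(str, r)) + "\n" for r in rows)
        )
        return p

    def test_full_profile_parsed_intact(self, tmp_path):
        rows = [
            ("2021-06-01T00:00:00Z", "A", k, 0.45 + 0.5 * k, 0.05, 120.0) for k in range(1, 14)
        ]
        df = tio.read_adcp(self._write(tmp_path, rows))
        assert len(df) == 13
        assert df["cell_index"].tolist() == list(range(1, 14))

    def test_excess_cells_rejected(self, tmp_path):
        rows = [
            ("2021-06-01T00:00:00Z", "B", k, 0.45 + 0.5 * k, 0.05, 120.0) for k in range(1, 18)
        ]
        with pytest.raises(FormatError, match="cell index"):
            tio.read_adcp(self._write(tmp_path, rows))

    def test_direction_normalized_to_half_open_circle(self, tmp_path):
        rows = [("2021-06-01T00:00:00Z", "A", 1, 0.95, 0.05, 360.0)]
        df = tio.read_adcp(self._write(tmp_path, rows))
        assert df.loc[0, "direction_deg"] == 0.0

    def test_synthetic_file_matches_generator_counts(self, tmp_path, short_scenario):
        ledger = mooring_sim.generate_files(short_scenario, tmp_path)
        df = tio.read_adcp(tmp_path / "adcp_B.csv")
        assert len(df) == ledger.record_counts["adcp_B_rows"]
        assert df["timestamp"].nunique() == ledger.record_counts["adcp_B_ensembles"]
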