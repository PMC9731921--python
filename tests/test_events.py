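"""Event filtering, effort accounting, and detection-matrix construction."""
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from camtrap_community import events as ev


def _df(rows):
    return pd.DataFrame(rows, columns=["station_id", "species", "timestamp"])


class TestIndependenceFilter:
    def test_window_rule_on_mixed_streams(self, events_table):
        kept = ev.filter_independent_events(events_table, window_minutes=30)
        leopard_st1 = kept[
            (kept.species == "leopard") & (kept.station_id == "ST01")
        ]["timestamp"].dt.strftime("%H:%M")
        assert list(leopard_st1) == ["10:00", "10:31"]
        # cross-station and cross-species streams are untouched
        assert (kept.species == "jackal").sum() == 1
        assert ((kept.species == "leopard") & (kept.station_id == "ST02")).sum() == 1

    def test_single_record_kept(self):
        kept = ev.filter_independent_events(
            _df([("A", "x", "2020-01-01T00:00")])
        )
        assert len(kept) == 1

    def test_minute_spaced_stream_brute_force(self):
        """Oracle: a literal scan of a 1-min-spaced stream keeps t=0,30,60,90."""
        times = [
            (pd.Timestamp("2020-01-01 08:00") + pd.Timedelta(minutes=m))
            for m in range(100)
        ]

        def brute_force(ts, window):
            kept, last = [], None
            for t in sorted(ts):
                if last is None or t - last >= window:
                    kept.append(t)
                    last = t
            return kept

        expected = brute_force(times, pd.Timedelta(minutes=30))
        assert len(expected) == 4
        df = _df([("A", "x", t.isoformat()) for t in times])
        kept = ev.filter_independent_events(df, window_minutes=30)
        assert list(kept["timestamp"]) == expected

    def test_unparseable_timestamp_dropped(self, caplog):
        df = _df(
            [("A", "x", "2020-01-01T10:00"), ("A", "x", "not a time")]
        )
        with caplog.at_level("WARNING"):
            kept = ev.filter_independent_events(df)
        assert len(kept) == 1
        assert "unparseable" in caplog.text

    def test_idempotent(self, events_table):
        once = ev.filter_independent_events(events_table, 30)
        twice = ev.filter_independent_events(once, 30)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        offsets=st.lists(
            st.integers(min_value=0, max_value=600), min_size=1, max_size=40
        ),
        w1=st.integers(min_value=1, max_value=120),
        w2=st.integers(min_value=1, max_value=120),
    )
    def test_wider_window_never_keeps_more(self, offsets, w1, w2):
        base = pd.Timestamp("2020-01-01")
        df = _df(
            [("A", "x", (base + pd.Timedelta(minutes=m)).isoformat()) for m in offsets]
        )
        lo, hi = sorted((w1, w2))
        assert len(ev.filter_independent_events(df, hi)) <= len(
            ev.filter_independent_events(df, lo)
        )


class TestEffort:
    @staticmethod
    def _deployment(n_nights, malfunction=()):
        start = date(2020, 3, 1)
        return pd.DataFrame(
            [
                {
                    "station_id": "ST01",
                    "start_date": start.isoformat(),
                    "end_date": (start + timedelta(days=n_nights)).isoformat(),
                    "malfunction_nights": ";".join(d.isoformat() for d in malfunction),
                }
            ]
        )

    def test_no_malfunctions(self):
        effort = ev.compute_effort(self._deployment(31))
        assert effort.total_trap_nights == 31

    def test_malfunction_nights_subtracted(self):
        bad = [date(2020, 3, 5), date(2020, 3, 6)]
        effort = ev.compute_effort(self._deployment(31, bad))
        assert effort.total_trap_nights == 29

    def test_survey_scale_arithmetic(self):
        """62 stations x 31 nights with 124 lost nights is exactly 1798."""
        start = date(2020, 3, 1)
        rows = []
        for j in range(62):
            lost = [start, start + timedelta(days=1)] if j < 62 else []
            rows.append(
                {
                    "station_id": f"ST{j:02d}",
                    "start_date": start.isoformat(),
                    "end_date": (start + timedelta(days=31)).isoformat(),
                    "malfunction_nights": ";".join(d.isoformat() for d in lost),
                }
            )
        effort = ev.compute_effort(pd.DataFrame(rows))
        assert effort.total_trap_nights == 62 * 31 - 124 == 1798

    def test_malfunction_outside_deployment_ignored(self):
        with pytest.warns(UserWarning, match="outside"):
            effort = ev.compute_effort(
                self._deployment(10, [date(2021, 1, 1)])
            )
        assert effort.total_trap_nights == 10


class TestRatesAndOccupancy:
    def test_trapping_rate_arithmetic(self):
        assert ev.trapping_rate(15, 200) == pytest.approx(7.5)
        assert ev.trapping_rate(0, 200) == 0.0
        with pytest.raises(ValueError):
            ev.trapping_rate(3, 0)

    def test_naive_occupancy_values(self):
        stations = [f"S{i}" for i in range(62)]
        rows = [("sp", s, "2020-01-01T00:00") for s in stations[:45]]
        df = pd.DataFrame(rows, columns=["species", "station_id", "timestamp"])
        occ = ev.naive_occupancy(df, stations)
        assert occ["sp"] == pytest.approx(45 / 62)
        assert round(occ["sp"], 2) == 0.73
        rows = [("all", s, "2020-01-01T00:00") for s in stations]
        occ = ev.naive_occupancy(
            pd.DataFrame(rows, columns=["species", "station_id", "timestamp"]),
            stations,
        )
        assert occ["all"] == 1.0


class TestDetectionMatrix:
    @staticmethod
    def _effort(n_nights=10):
        dep = pd.DataFrame(
            [
                {
                    "station_id": "ST01",
                    "start_date": "2020-03-01",
                    "end_date": (date(2020, 3, 1) + timedelta(days=n_nights)).isoformat(),
                    "malfunction_nights": "",
                }
            ]
        )
        return ev.compute_effort(dep)

    def test_same_night_events_collapse(self):
        df = _df(
            [
                ("ST01", "x", "2020-03-02T01:00"),
                ("ST01", "x", "2020-03-02T05:00"),
                ("ST01", "x", "2020-03-02T23:00"),
            ]
        )
        det = ev.build_detection_matrix(df, self._effort())
        assert det.y[0, 0] == 1

    def test_distinct_nights_counted(self):
        df = _df(
            [
                ("ST01", "x", "2020-03-01T12:00"),
                ("ST01", "x", "2020-03-05T12:00"),
                ("ST01", "x", "2020-03-09T12:00"),
            ]
        )
        det = ev.build_detection_matrix(df, self._effort())
        assert det.y[0, 0] == 3

    def test_event_outside_effort_excluded(self):
        df = _df(
            [
                ("ST01", "x", "2020-03-02T01:00"),
                ("ST01", "x", "2021-01-01T01:00"),
            ]
        )
        with pytest.warns(UserWarning, match="outside the effort"):
            det = ev.build_detection_matrix(df, self._effort())
        assert det.y.sum() == 1

    def test_counts_bounded_by_effort_on_synthetic_events(self, small_study):
        from camtrap_community import default_activity_specs, simulate_capture_events

        truth, _ = small_study
        events = simulate_capture_events(
            truth.design, default_activity_specs(truth), truth
        )
        dep = pd.DataFrame(
            [
                {
                    "station_id": sid,
                    "start_date": truth.design.start_date.isoformat(),
                    "end_date": (
                        truth.design.start_date
                        + timedelta(days=truth.design.n_occasions)
                    ).isoformat(),
                    "malfunction_nights": ";".join(
                        d.isoformat()
                        for d in sorted(
                            set(
                                truth.design.start_date + timedelta(days=k)
                                for k in range(truth.design.n_occasions)
                            )
                            - set(truth.active_nights[j])
                        )
                    ),
                }
                for j, sid in enumerate(truth.stations)
            ]
        )
        effort = ev.compute_effort(dep)
        det = ev.build_detection_matrix(events, effort)
        assert np.all(det.y <= det.K[None, :])
        assert np.all(det.y.sum(axis=1) >= 1)

    def test_matrix_round_trip(self, small_study, tmp_path):
        _, det = small_study
        path = tmp_path / "dm.csv"
        det.to_csv(path)
        back = ev.DetectionData.from_csv(path)
        assert back.species == det.species
        assert np.array_equal(back.y, det.y)
        assert np.array_equal(back.K, det.K)


class TestSummaries:
    def test_elevation_range_per_species(self):
        df = pd.DataFrame(
            {
                "species": ["deer", "deer", "tiger"],
                "elevation_m": [418.0, 2547.0, 2511.0],
            }
        )
        rng = ev.species_elevation_range(df)
        assert tuple(rng.loc["deer"]) == (418.0, 2547.0)
        assert tuple(rng.loc["tiger"]) == (2511.0, 2511.0)

    def test_conservation_tagging(self):
        summaries = pd.DataFrame({"species": ["tiger", "deer", "mystery"]})
        lookup = {"tiger": "EN", "deer": "LC"}
        with pytest.warns(UserWarning, match="missing"):
            tagged = ev.tag_conservation_status(summaries, lookup)
        assert list(tagged["iucn_status"]) == ["EN", "LC", "unknown"]
        assert tagged.attrs["n_threatened"] == 1

    def test_empty_lookup_all_unknown(self):
        summaries = pd.DataFrame({"species": ["a", "b"]})
        with pytest.warns(UserWarning):
            tagged = ev.tag_conservation_status(summaries, {})
        assert set(tagged["iucn_status"]) == {"unknown"}
        assert tagged.attrs["n_threatened"] == 0

    def test_summary_table_rounding(self):
        df = pd.DataFrame(
            {
                "station_id": ["ST01"] * 15,
                "species": ["deer"] * 15,
                "timestamp": pd.date_range("2020-03-01", periods=15, freq="D").astype(str),
                "elevation_m": np.linspace(418, 2547, 15),
            }
        )
        dep = pd.DataFrame(
            [
                {
                    "station_id": "ST01",
                    "start_date": "2020-03-01",
                    "end_date": "2020-09-17",  # 200 nights
                    "malfunction_nights": "",
                }
            ]
        )
        effort = ev.compute_effort(dep)
        assert effort.total_trap_nights == 200
        table = ev.species_summary_table(df, effort)
        row = table.iloc[0]
        assert row["trapping_rate"] == 7.5  # 15 events / 200 TN x 100
        assert row["naive_occupancy"] == 1.0
        assert (row["elev_min_m"], row["elev_max_m"]) == (418.0, 2547.0)
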