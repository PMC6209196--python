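"""Fix ingestion, 30-min thinning, step metrics, camera days, and centroids."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wolfsnow import telemetry

UTC = dt.timezone.utc


def _fix_frame(rows):
    df = pd.DataFrame(rows, columns=telemetry.FIX_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def _fx(wolf, ts, e=0.0, n=0.0):
    return (wolf, ts, e, n, 56.4, -111.1)


class TestReadFixes:
    HEADER = "wolf_id,timestamp,easting,northing,lat,lon\n"

    def test_well_formed(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(self.HEADER + "\n".join(
            f"W1,2014-01-05T0{h}:00:00+00:00,100,200,56.4,-111.1" for h in range(3)
        ))
        out = telemetry.read_fixes(p)
        assert len(out) == 3
        assert list(out.columns) == telemetry.FIX_COLUMNS

    def test_duplicate_dropped(self, tmp_path):
        p = tmp_path / "t.csv"
        row = "W1,2014-01-05T01:00:00+00:00,100,200,56.4,-111.1"
        p.write_text(self.HEADER + row + "\n" + row)
        assert len(telemetry.read_fixes(p)) == 1

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("wolf_id,timestamp,easting,lat,lon\nW1,2014-01-05T01:00:00+00:00,1,2,3\n")
        with pytest.raises(ValueError, match="northing"):
            telemetry.read_fixes(p)

    def test_bad_timestamp_reports_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(self.HEADER
                     + "W1,2014-01-05T01:00:00+00:00,1,2,56,-111\n"
                     + "W1,not-a-time,1,2,56,-111\n")
        with pytest.raises(ValueError, match="row 1"):
            telemetry.read_fixes(p)


class TestThinning:
    def test_ten_minute_data_thins_to_half_hour(self):
        times = ["2014-01-05T08:00", "2014-01-05T08:10", "2014-01-05T08:20",
                 "2014-01-05T08:30", "2014-01-05T08:40", "2014-01-05T08:50",
                 "2014-01-05T09:00"]
        fixes = _fix_frame([_fx("W1", t) for t in times])
        out = telemetry.thin_to_interval(fixes, 30)
        kept = [t.strftime("%H:%M") for t in out["timestamp"]]
        assert kept == ["08:00", "08:30", "09:00"]

    def test_thirty_minute_data_unchanged(self):
        times = ["2014-01-05T08:00", "2014-01-05T08:30", "2014-01-05T09:00"]
        fixes = _fix_frame([_fx("W1", t) for t in times])
        out = telemetry.thin_to_interval(fixes, 30)
        pd.testing.assert_frame_equal(out, fixes)

    def test_idempotent(self):
        times = [f"2014-01-05T08:{m:02d}" for m in range(0, 60, 10)]
        fixes = _fix_frame([_fx("W1", t) for t in times])
        once = telemetry.thin_to_interval(fixes, 30)
        twice = telemetry.thin_to_interval(once, 30)
        pd.testing.assert_frame_equal(once, twice)

    def test_nearest_grid_assignment_brute_force(self):
        """A fix at every offset 0-29 min joins the slot a brute-force
        nearest-grid rule predicts (midpoint ties to the earlier slot).

        An on-grid competitor sits at :00 only. If the probe fix is assigned
        to the :00 slot it loses to the competitor (1 row survives); if it is
        assigned to the :30 slot both survive (2 rows).
        """
        base = pd.Timestamp("2014-01-05T08:00:00", tz="UTC")
        for off in range(1, 30):
            both = _fix_frame([
                _fx("W1", base.isoformat(), e=2.0),
                _fx("W1", (base + pd.Timedelta(minutes=off)).isoformat(), e=1.0),
            ])
            thinned = telemetry.thin_to_interval(both, 30)
            expected_rows = 1 if off <= 15 else 2  # brute force: min(|off-0|,|off-30|), tie earlier
            assert len(thinned) == expected_rows, f"offset {off}"

    def test_14_and_16_split_across_slots(self):
        fixes = _fix_frame([
            _fx("W1", "2014-01-05T08:14", e=14.0),
            _fx("W1", "2014-01-05T08:16", e=16.0),
        ])
        out = telemetry.thin_to_interval(fixes, 30)
        assert len(out) == 2  # :14 -> :00 slot, :16 -> :30 slot


class TestSteps:
    def test_speed_arithmetic(self):
        fixes = _fix_frame([
            _fx("W1", "2014-01-05T08:00", e=0.0),
            _fx("W1", "2014-01-05T08:30", e=900.0),
        ])
        out = telemetry.compute_steps(fixes, classify_day_night=False)
        assert len(out) == 1
        assert out["speed_m_min"].iloc[0] == pytest.approx(30.0)

    def test_zero_distance_zero_speed(self):
        fixes = _fix_frame([
            _fx("W1", "2014-01-05T08:00", e=5.0, n=5.0),
            _fx("W1", "2014-01-05T08:30", e=5.0, n=5.0),
        ])
        out = telemetry.compute_steps(fixes, classify_day_night=False)
        assert out["speed_m_min"].iloc[0] == 0.0

    def test_collinear_fixes(self):
        fixes = _fix_frame([
            _fx("W1", "2014-01-05T08:00", e=0.0),
            _fx("W1", "2014-01-05T08:30", e=300.0),
            _fx("W1", "2014-01-05T09:00", e=600.0),
        ])
        out = telemetry.compute_steps(fixes, classify_day_night=False)
        assert list(out["speed_m_min"]) == pytest.approx([10.0, 10.0])

    def test_out_of_band_interval_dropped(self):
        fixes = _fix_frame([
            _fx("W1", "2014-01-05T08:00", e=0.0),
            _fx("W1", "2014-01-05T08:30", e=300.0),
            _fx("W1", "2014-01-05T10:30", e=600.0),  # 2-h gap: no step spans it
        ])
        out = telemetry.compute_steps(fixes, classify_day_night=False)
        assert len(out) == 1

    def test_single_fix_wolf_no_steps(self):
        fixes = _fix_frame([_fx("W1", "2014-01-05T08:00")])
        out = telemetry.compute_steps(fixes, classify_day_night=False)
        assert len(out) == 0

    def test_step_count_invariant(self, track_sim):
        """Steps per wolf = retained fixes - 1 - out-of-band gaps (here none)."""
        thinned = telemetry.thin_to_interval(track_sim.fixes)
        steps = telemetry.compute_steps(thinned, classify_day_night=False)
        for wolf, grp in thinned.groupby("wolf_id"):
            assert (steps["wolf_id"] == wolf).sum() == len(grp) - 1


class TestCameraDay:
    @pytest.mark.parametrize(
        "local_time,expected_shift",
        [((11, 59, 0), 0), ((12, 1, 0), 1), ((12, 0, 0), 0), ((23, 59, 59), 1), ((0, 0, 0), 0)],
    )
    def test_noon_rule(self, local_time, expected_shift):
        h, m, s = local_time
        # build UTC timestamp whose local (UTC-7) clock shows Jan 5 h:m:s
        local = dt.datetime(2014, 1, 5, h, m, s, tzinfo=dt.timezone(dt.timedelta(hours=-7)))
        got = telemetry.assign_camera_day(local.astimezone(UTC), tz_offset_hours=-7)
        assert got == dt.date(2014, 1, 5) + dt.timedelta(days=expected_shift)

    def test_vectorized_matches_scalar(self, track_sim):
        ts = track_sim.fixes["timestamp"].iloc[:200]
        vec = telemetry.camera_days(ts)
        scalar = [telemetry.assign_camera_day(t) for t in ts]
        assert list(vec) == scalar

    def test_camera_day_monotone_per_wolf(self, track_sim):
        fixes = track_sim.fixes
        days = telemetry.camera_days(fixes["timestamp"])
        for _, grp in days.groupby(fixes["wolf_id"]):
            assert (pd.Series(grp.values).diff().dropna() >= dt.timedelta(0)).all()


class TestCentroids:
    def test_mean_of_two(self):
        fixes = _fix_frame([
            _fx("W1", "2014-01-05T08:00", e=0.0, n=0.0),
            _fx("W1", "2014-01-05T08:30", e=100.0, n=0.0),
        ])
        out = telemetry.daily_centroids(fixes)
        assert out["easting"].iloc[0] == 50.0
        assert out["n_fixes"].iloc[0] == 2

    def test_single_fix(self):
        fixes = _fix_frame([_fx("W1", "2014-01-05T08:00", e=123.0, n=456.0)])
        out = telemetry.daily_centroids(fixes)
        assert (out["easting"].iloc[0], out["northing"].iloc[0]) == (123.0, 456.0)

    def test_symmetric_cloud(self):
        rows = []
        for i in range(24):
            ang = 2 * np.pi * i / 24
            rows.append(_fx("W1", f"2014-01-05T{i % 12:02d}:00",
                            e=500 + 100 * np.cos(ang), n=500 + 100 * np.sin(ang)))
        out = telemetry.daily_centroids(_fix_frame(rows))
        assert out["easting"].iloc[0] == pytest.approx(500.0)
        assert out["northing"].iloc[0] == pytest.approx(500.0)

    def test_centroid_within_bounding_box(self, track_sim):
        fixes = track_sim.fixes.assign(camera_day=telemetry.camera_days(track_sim.fixes["timestamp"]))
        cents = telemetry.daily_centroids(track_sim.fixes)
        merged = cents.merge(
            fixes.groupby(["wolf_id", "camera_day"]).agg(
                emin=("easting", "min"), emax=("easting", "max"),
                nmin=("northing", "min"), nmax=("northing", "max"),
            ).reset_index(),
            on=["wolf_id", "camera_day"],
        )
        assert ((merged["easting"] >= merged["emin"]) & (merged["easting"] <= merged["emax"])).all()
        assert ((merged["northing"] >= merged["nmin"]) & (merged["northing"] <= merged["nmax"])).all()


def test_thinning_yields_30min_mean_interval(track_sim):
    thinned = telemetry.thin_to_interval(track_sim.fixes)
    steps = telemetry.compute_steps(thinned, classify_day_night=False)
    assert steps["interval_min"].mean() == pytest.approx(30.0, abs=0.5)
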