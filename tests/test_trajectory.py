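"""Reinterpolation, kinematic descriptors, and solar annotation tests."""

import math

import numpy as np
import pandas as pd
import pytest

from sofpipe.trajectory import (annotate_daynight, reinterpolate,
                                smoothed_speed, solar_elevation,
                                step_lengths, turn_angle_csl)


class TestReinterpolate:
    def test_regular_track_unchanged(self, track_factory):
        xy = np.column_stack([np.arange(10) * 0.4, np.arange(10) * 0.1])
        tr = track_factory(xy)
        out = reinterpolate(tr, interval=60)
        np.testing.assert_allclose(out.xy, xy, atol=1e-12)

    def test_midpoint_inserted(self, track_factory):
        t = pd.to_datetime(["2012-10-15T08:00:00Z", "2012-10-15T08:02:00Z"])
        df = pd.DataFrame({"timestamp": t, "x": [0.0, 1.0], "y": [0.0, 2.0]})
        from sofpipe.trajectory import Track
        tr = Track("a", df, colony=(17.93, -33.05))
        out = reinterpolate(tr, interval=60)
        np.testing.assert_allclose(out.xy[1], [0.5, 1.0])

    def test_endpoints_conserved(self, track_factory):
        rng = np.random.default_rng(0)
        secs = np.cumsum(rng.integers(30, 120, 40))
        t = pd.Timestamp("2012-10-15T08:00:00Z") \
            + pd.to_timedelta(secs, unit="s")
        xy = rng.normal(0, 5, (40, 2)).cumsum(axis=0)
        from sofpipe.trajectory import Track
        tr = Track("a", pd.DataFrame({"timestamp": t, "x": xy[:, 0],
                                      "y": xy[:, 1]}),
                   colony=(17.93, -33.05))
        out = reinterpolate(tr, interval=60)
        # every output fix equals brute-force linear interpolation
        sec0 = tr.seconds
        for k in range(len(out)):
            s = out.seconds[k] + (sec0[0] - sec0[0])
            s_abs = (out.fixes["timestamp"].iloc[k]
                     - tr.fixes["timestamp"].iloc[0]).total_seconds()
            j = np.searchsorted(sec0, s_abs, side="right") - 1
            j = min(j, len(sec0) - 2)
            w = (s_abs - sec0[j]) / (sec0[j + 1] - sec0[j])
            exp = tr.xy[j] * (1 - w) + tr.xy[j + 1] * w
            np.testing.assert_allclose(out.xy[k], exp, atol=1e-9)

    def test_gap_splits_into_bursts(self, track_factory):
        secs = np.concatenate([np.arange(0, 300, 60),
                               np.arange(2000, 2300, 60)])
        t = pd.Timestamp("2012-10-15T08:00:00Z") \
            + pd.to_timedelta(secs, unit="s")
        from sofpipe.trajectory import Track
        tr = Track("a", pd.DataFrame({
            "timestamp": t, "x": np.arange(len(secs), dtype=float),
            "y": np.zeros(len(secs))}), colony=(17.93, -33.05))
        out = reinterpolate(tr, interval=60, max_gap=600)
        assert out.fixes["burst"].nunique() == 2
        # no fix interpolated inside the gap
        s = out.seconds
        assert not np.any((s > 300) & (s < 1980))

    def test_too_short_rejected(self):
        from sofpipe.trajectory import Track
        t = pd.to_datetime(["2012-10-15T08:00:00Z",
                            "2012-10-15T08:00:30Z"])
        tr = Track("a", pd.DataFrame({"timestamp": t, "x": [0.0, 0.1],
                                      "y": [0.0, 0.0]}),
                   colony=(17.93, -33.05))
        with pytest.raises(ValueError):
            reinterpolate(tr, interval=60)


class TestSmoothedSpeed:
    def test_constant_velocity(self, track_factory):
        xy = np.column_stack([np.arange(20) * 0.5, np.zeros(20)])
        sp = smoothed_speed(track_factory(xy))
        np.testing.assert_allclose(sp, 30.0)

    def test_symmetric_window_hand_value(self, track_factory):
        # step speeds (1,1,1,9,1,1,1) km/h at 1-min steps; the window at
        # the fix on either side of the fast step holds (1,1,9,1) km/h
        steps_kmh = np.array([1, 1, 1, 9, 1, 1, 1], dtype=float)
        xy = np.zeros((8, 2))
        xy[1:, 0] = np.cumsum(steps_kmh / 60.0)
        sp = smoothed_speed(track_factory(xy))
        assert sp[3] == pytest.approx(12 / 4)
        assert sp[4] == pytest.approx(12 / 4)

    def test_interior_matches_naive_mean(self, track_factory):
        rng = np.random.default_rng(1)
        xy = rng.normal(0, 0.3, (50, 2)).cumsum(axis=0)
        tr = track_factory(xy)
        sp = smoothed_speed(tr)
        step_sp = step_lengths(tr) * 60.0
        for i in range(2, 48):
            assert sp[i] == pytest.approx(step_sp[i - 2:i + 2].mean())

    def test_time_reversal_invariance(self, track_factory):
        rng = np.random.default_rng(2)
        xy = rng.normal(0, 0.3, (40, 2)).cumsum(axis=0)
        sp = smoothed_speed(track_factory(xy))
        sp_rev = smoothed_speed(track_factory(xy[::-1]))
        np.testing.assert_allclose(sp, sp_rev[::-1], atol=1e-7)


def oracle_turn_angle(xy, i, r):
    """Brute-force oracle: scan outward, apply the law of cosines."""
    p = xy[i]
    back = None
    for j in range(i - 1, -1, -1):
        if np.hypot(*(xy[j] - p)) >= r:
            back = xy[j]
            break
    if back is None:
        return np.nan
    fwd = None
    last_in = None
    for j in range(i + 1, len(xy)):
        d = np.hypot(*(xy[j] - p))
        if d < r:
            last_in = xy[j]
        else:
            fwd = last_in if last_in is not None else xy[j]
            break
    if fwd is None:
        return np.nan
    a = np.hypot(*(back - p))
    b = np.hypot(*(fwd - p))
    c = np.hypot(*(fwd - back))
    cosang = np.clip((a * a + b * b - c * c) / (2 * a * b), -1, 1)
    return math.pi - math.acos(cosang)


class TestTurnAngleCSL:
    def test_collinear_zero(self, track_factory):
        xy = np.column_stack([np.arange(15) * 0.3, np.arange(15) * 0.1])
        ang = turn_angle_csl(track_factory(xy))
        interior = ang[~np.isnan(ang)]
        np.testing.assert_allclose(interior, 0.0, atol=1e-7)

    def test_exact_reversal_pi(self, track_factory):
        out = np.arange(8) * 0.5
        xy = np.column_stack([np.concatenate([out, out[-2::-1]]),
                              np.zeros(15)])
        ang = turn_angle_csl(track_factory(xy))
        assert ang[7] == pytest.approx(math.pi)

    def test_matches_law_of_cosines_oracle(self, track_factory):
        rng = np.random.default_rng(5)
        xy = rng.normal(0, 0.4, (60, 2)).cumsum(axis=0)
        tr = track_factory(xy)
        r = float(np.median(step_lengths(tr)))
        ang = turn_angle_csl(tr)
        for i in range(60):
            exp = oracle_turn_angle(xy, i, r)
            if np.isnan(exp):
                assert np.isnan(ang[i])
            else:
                assert ang[i] == pytest.approx(exp, abs=1e-9)

    def test_rigid_motion_invariance(self, track_factory):
        rng = np.random.default_rng(6)
        xy = rng.normal(0, 0.4, (40, 2)).cumsum(axis=0)
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        xy2 = xy @ rot.T + np.array([55.0, -20.0])
        a1 = turn_angle_csl(track_factory(xy))
        a2 = turn_angle_csl(track_factory(xy2))
        np.testing.assert_allclose(a1, a2, atol=1e-9, equal_nan=True)


def spencer_solar_elevation(ts, lon, lat):
    """Independent low-precision solar oracle (Fourier-series declination
    and equation of time), good to a fraction of a degree."""
    t = pd.DatetimeIndex(ts).tz_convert("UTC")
    doy = t.dayofyear.to_numpy()
    frac_h = (t.hour + t.minute / 60 + t.second / 3600).to_numpy()
    g = 2 * math.pi / 365 * (doy - 1 + (frac_h - 12) / 24)
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    eqt = 229.18 * (0.000075 + 0.001868 * np.cos(g)
                    - 0.032077 * np.sin(g) - 0.014615 * np.cos(2 * g)
                    - 0.040849 * np.sin(2 * g))  # minutes
    tst = frac_h * 60 + eqt + 4 * np.asarray(lon)
    ha = np.radians(tst / 4 - 180)
    lat_r = np.radians(np.asarray(lat))
    cosz = (np.sin(lat_r) * np.sin(decl)
            + np.cos(lat_r) * np.cos(decl) * np.cos(ha))
    return 90 - np.degrees(np.arccos(np.clip(cosz, -1, 1)))


class TestDayNight:
    def test_local_noon_is_day_midnight_is_night(self, track_factory):
        # solar noon at 17.93 E is ~10:48 UTC
        xy = np.array([[0.0, 0.0], [0.1, 0.0]])
        tr_day = track_factory(xy, start="2012-10-15T10:48:00Z")
        tr_night = track_factory(xy, start="2012-10-15T22:48:00Z")
        assert annotate_daynight(tr_day).all()
        assert not annotate_daynight(tr_night).any()

    def test_agreement_with_independent_oracle(self):
        rng = np.random.default_rng(9)
        n = 1000
        ts = (pd.Timestamp("2012-01-01", tz="UTC")
              + pd.to_timedelta(rng.uniform(0, 365 * 24 * 3600, n),
                                unit="s"))
        lon = rng.uniform(-180, 180, n)
        lat = rng.uniform(-60, 60, n)
        el = solar_elevation(ts, lon, lat)
        el_oracle = spencer_solar_elevation(ts, lon, lat)
        sel = np.abs(el_oracle) > 0.5
        assert np.all((el[sel] > 0) == (el_oracle[sel] > 0))
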