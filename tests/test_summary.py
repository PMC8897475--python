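"""Mixed-model summaries and derived diel quantities."""

import numpy as np
import pandas as pd
import pytest

from sofpipe.summary import (diel_shift, delta_sst, habitat_use_summary,
                             majority_tactic, mixed_mean_ci,
                             tactic_proportions)


class TestMixedMeanCI:
    def test_identical_values_zero_width(self):
        m, lo, hi = mixed_mean_ci(np.full(20, 3.7),
                                  np.repeat(["a", "b"], 10))
        assert m == lo == hi == 3.7

    def test_single_individual_reduces_to_sample_mean(self):
        rng = np.random.default_rng(0)
        v = rng.normal(5, 1, 40)
        m, lo, hi = mixed_mean_ci(v, np.full(40, "a"))
        assert m == pytest.approx(v.mean())

    def test_balanced_two_level_se_matches_closed_form(self):
        """Balanced one-way random-effects design: SE of the grand mean
        is sqrt(sigma_b^2/m + sigma_e^2/(m*n)) (textbook closed form)."""
        rng = np.random.default_rng(1)
        m_groups, n_per = 12, 30
        sigma_b, sigma_e = 2.0, 1.0
        b = rng.normal(0, sigma_b, m_groups)
        vals, ids = [], []
        for g in range(m_groups):
            vals.extend(10 + b[g] + rng.normal(0, sigma_e, n_per))
            ids.extend([f"g{g}"] * n_per)
        mean, lo, hi = mixed_mean_ci(np.array(vals), np.array(ids))
        se_est = (hi - lo) / (2 * 1.959964)
        # closed form with the REALIZED variance components
        s2b = np.var(b, ddof=1)
        se_true = np.sqrt(s2b / m_groups
                          + sigma_e ** 2 / (m_groups * n_per))
        assert se_est == pytest.approx(se_true, rel=0.25)

    def test_mean_close_to_grand_truth(self):
        rng = np.random.default_rng(2)
        ids = np.repeat([f"g{i}" for i in range(10)], 25)
        vals = rng.normal(42.0, 3.0, 250)
        mean, lo, hi = mixed_mean_ci(vals, ids,
                                     year=np.tile([2012, 2013], 125))
        assert mean == pytest.approx(42.0, abs=1.0)
        assert lo < mean < hi


class TestDielShift:
    def _frame(self, birds):
        rows = []
        for b, (d, n) in birds.items():
            for v in d:
                rows.append({"individual_id": b, "year": 2012,
                             "period": "day_forage", "dist_shore": v})
            for v in n:
                rows.append({"individual_id": b, "year": 2012,
                             "period": "night_rest", "dist_shore": v})
        return pd.DataFrame(rows)

    def test_identical_day_night_zero_shift(self):
        df = self._frame({"a": ([30, 40], [30, 40]),
                          "b": ([20, 30], [20, 30])})
        shifts, (mean, lo, hi) = diel_shift(df)
        assert (shifts == 0).all()

    def test_positive_means_farther_offshore_at_night(self):
        df = self._frame({"a": ([30.0], [45.0]), "b": ([20.0], [30.0])})
        shifts, _ = diel_shift(df)
        assert shifts["a"] == pytest.approx(15.0)
        assert shifts["b"] == pytest.approx(10.0)

    def test_bird_missing_one_period_excluded(self):
        df = self._frame({"a": ([30.0], [45.0]), "b": ([20.0], [])})
        shifts, _ = diel_shift(df)
        assert list(shifts.index) == ["a"]

    def test_known_generative_shift_recovered(self, pipeline_results):
        """End-to-end: the cohort's realized generative shift lies inside
        the estimate's 95% CI."""
        from sofpipe.trajectory import solar_elevation
        res = pipeline_results
        bundle = res["bundle"]
        pos = pd.concat([t.fixes.assign(trip_id=t.trip_id)
                         for t in bundle["gannet_tracks"]])
        m = bundle["fix_truth"].merge(
            pos[["trip_id", "timestamp", "x", "lon", "lat"]],
            on=["trip_id", "timestamp"])
        m["is_day"] = solar_elevation(m["timestamp"], m["lon"],
                                      m["lat"]) > 0
        sea = bundle["trip_truth"].loc[
            bundle["trip_truth"]["tactic"] == "rest_at_sea",
            "individual_id"].unique()
        truths = []
        for b in sea:
            sub = m[m["individual_id"] == b]
            d = sub[(sub["state"] == "forage") & sub["is_day"]]["x"]
            n = sub[(sub["state"] == "rest") & ~sub["is_day"]]["x"]
            if len(d) and len(n):
                truths.append(n.mean() - d.mean())
        true_shift = float(np.mean(truths))
        mean, lo, hi = res["summary"]["shift_ci"]
        assert lo <= true_shift <= hi


class TestDeltaSST:
    def test_table_difference(self):
        locs = pd.DataFrame({
            "individual_id": ["a"] * 20 + ["b"] * 20,
            "year": 2012,
            "group": (["day_forage_rest_at_sea"] * 10
                      + ["night_rest_rest_at_sea"] * 10) * 2,
            "sst": ([16.6] * 10 + [16.9] * 10) * 2})
        summ = habitat_use_summary(locs, ["sst"])
        assert delta_sst(summ) == pytest.approx(0.3, abs=1e-9)

    @pytest.mark.parametrize("day,night,expected",
                             [(16.6, 16.6, 0.0), (17.5, 15.0, -2.5)])
    def test_sign_convention(self, day, night, expected):
        locs = pd.DataFrame({
            "individual_id": ["a"] * 20 + ["b"] * 20,
            "year": 2012,
            "group": (["day_forage_rest_at_sea"] * 10
                      + ["night_rest_rest_at_sea"] * 10) * 2,
            "sst": ([day] * 10 + [night] * 10) * 2})
        summ = habitat_use_summary(locs, ["sst"])
        assert delta_sst(summ) == pytest.approx(expected, abs=1e-9)


class TestTacticProportions:
    def test_printed_bird_counts(self):
        """142 of 197 birds at sea gives the reported 72% (72.08 exact)."""
        tactics = pd.Series(["rest_at_sea"] * 142
                            + ["rest_at_colony"] * 55)
        out = tactic_proportions(tactics)
        assert round(out["rest_at_sea_pct"]) == 72
        assert out["rest_at_sea_pct"] == pytest.approx(100 * 142 / 197)

    def test_single_tactic(self):
        out = tactic_proportions(pd.Series(["rest_at_sea"] * 7))
        assert out["rest_at_sea_pct"] == 100.0
        assert out["rest_at_colony_pct"] == 0.0

    def test_quarter(self):
        out = tactic_proportions(pd.Series(["rest_at_colony"]
                                           + ["rest_at_sea"] * 3))
        assert out["rest_at_colony_pct"] == 25.0

    def test_percentages_sum_to_hundred(self):
        out = tactic_proportions(pd.Series(
            ["rest_at_sea", "rest_at_colony", None, "rest_at_sea"]))
        assert out["rest_at_sea_pct"] + out["rest_at_colony_pct"] == 100.0
        assert out["n_unassigned"] == 1

    def test_majority_rule_over_trips(self):
        trips = pd.DataFrame({
            "individual_id": ["a", "a", "a", "b", "b", "c"],
            "tactic": ["rest_at_sea", "rest_at_sea", "rest_at_colony",
                       "rest_at_colony", "rest_at_colony", None]})
        bird = majority_tactic(trips)
        assert bird["a"] == "rest_at_sea"
        assert bird["b"] == "rest_at_colony"
        assert bird["c"] is None


class TestHabitatUseSummary:
    def test_structure_and_raw_ranges(self):
        rng = np.random.default_rng(3)
        locs = pd.DataFrame({
            "individual_id": np.repeat(["a", "b", "c"], 30),
            "year": 2012,
            "group": "day_forage_rest_at_sea",
            "dist_shore": rng.uniform(10, 80, 90)})
        summ = habitat_use_summary(locs, ["dist_shore"])
        row = summ.table.loc[("day_forage_rest_at_sea", "dist_shore")]
        assert row["min"] <= row["mean"] <= row["max"]
        assert row["ci_lo"] <= row["mean"] <= row["ci_hi"]
        assert row["n_birds"] == 3
        assert row["n_locations"] == 90
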