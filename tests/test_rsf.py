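"""Weighted mixed RSF core: screening, fitting, prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from sofpipe import rsf
from sofpipe.geo_env import Grid
from sofpipe.synthetic_data import seal_recovery_dataset


def logistic_table(rng, beta, n=800, n_ind=4, weight=1000.0):
    """Use-availability-style table from a known logistic model."""
    x = rng.normal(0, 1, (n, len(beta)))
    eta = x @ np.asarray(beta)
    y = rng.random(n) < expit(eta)
    df = pd.DataFrame(x, columns=[f"c{j}" for j in range(len(beta))])
    df["case"] = y.astype(int)
    df["weight"] = np.where(y, 1.0, weight)
    df["individual_id"] = rng.integers(0, n_ind, n).astype(str)
    return df


def ua_null_table(rng, n_used=150, ratio=5, n_ind=4, p=2):
    """Use-availability rows with no selection (used = available law)."""
    rows = []
    for i in range(n_ind):
        used = rng.normal(0, 1, (n_used, p))
        avail = rng.normal(0, 1, (n_used * ratio, p))
        for arr, case in ((used, 1), (avail, 0)):
            df = pd.DataFrame(arr, columns=[f"c{j}" for j in range(p)])
            df["case"] = case
            df["weight"] = 1.0 if case else 1000.0
            df["individual_id"] = f"i{i}"
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestScreenCollinearity:
    def test_orthogonal_covariates_unit_vif(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"a": rng.normal(size=2000),
                          "b": rng.normal(size=2000)})
        rep = rsf.screen_collinearity(t, ["a", "b"], r_max=0.6)
        assert rep.vif.max() < 1.05
        assert rep.passed

    def test_duplicated_covariate_fails(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=500)
        t = pd.DataFrame({"a": a, "b": a.copy()})
        rep = rsf.screen_collinearity(t, ["a", "b"], r_max=0.61)
        assert abs(rep.corr.loc["a", "b"]) == pytest.approx(1.0)
        assert not rep.passed

    def test_vif_matches_closed_form(self):
        """x2 = x1 + noise with R^2 = 0.75 gives VIF ~ 4."""
        rng = np.random.default_rng(2)
        vifs = []
        for _ in range(100):
            x1 = rng.normal(size=400)
            # var(x2) = 1 + sigma^2; R^2 = 1/(1+sigma^2) = 0.75
            x2 = x1 + rng.normal(0, np.sqrt(1 / 3), 400)
            t = pd.DataFrame({"x1": x1, "x2": x2})
            rep = rsf.screen_collinearity(t, ["x1", "x2"], r_max=0.99)
            vifs.append(rep.vif["x2"])
        assert np.mean(vifs) == pytest.approx(4.0, abs=0.3)

    def test_constant_covariate_rejected(self):
        t = pd.DataFrame({"a": np.ones(100),
                          "b": np.random.default_rng(0).normal(size=100)})
        with pytest.raises(ValueError):
            rsf.screen_collinearity(t, ["a", "b"], r_max=0.6)


class TestFitWeightedRSF:
    def test_single_individual_equals_plain_weighted_glm(self):
        """With no random structure the fit reduces to weighted logistic
        regression (statsmodels GLM as the independent oracle)."""
        rng = np.random.default_rng(3)
        t = logistic_table(rng, [0.8, -0.5], n=2000, n_ind=1)
        model = rsf.fit_weighted_rsf(t, ["c0", "c1"])
        X = sm.add_constant(
            model.standardizer.transform(t)[["c0", "c1"]])
        oracle = sm.GLM(t["case"], X, family=sm.families.Binomial(),
                        freq_weights=t["weight"]).fit()
        np.testing.assert_allclose(model.result.beta[1:],
                                   oracle.params[["c0", "c1"]], atol=1e-4)

    def test_null_coefficients_covered_by_ci(self):
        """Selection-free 5:1 use-availability data: the 95% CIs cover 0
        in >= 90% of replicates."""
        rng = np.random.default_rng(4)
        cover = []
        for _ in range(50):
            t = ua_null_table(rng)
            m = rsf.fit_weighted_rsf(t, ["c0", "c1"], maxfev=25)
            lo, hi = m.result.ci()
            cover.extend((lo[1:] <= 0.0) & (0.0 <= hi[1:]))
        assert np.mean(cover) >= 0.90

    def test_sigma0_never_estimated(self):
        rng = np.random.default_rng(5)
        t = logistic_table(rng, [0.5], n=800, n_ind=4)
        m = rsf.fit_weighted_rsf(t, ["c0"], sigma0_sq=1e6)
        assert m.result.variances["individual:intercept"] == 1e6

    def test_weight_stability_above_thousand(self):
        """Multiplying W by 10 moves covariate coefficients < 0.02."""
        rng = np.random.default_rng(6)
        t1 = logistic_table(rng, [0.7, -0.4], n=4000, n_ind=4,
                            weight=1000.0)
        t2 = t1.copy()
        t2.loc[t2["case"] == 0, "weight"] = 10000.0
        m1 = rsf.fit_weighted_rsf(t1, ["c0", "c1"], maxfev=30)
        m2 = rsf.fit_weighted_rsf(t2, ["c0", "c1"], maxfev=30)
        assert np.abs(m1.result.beta[1:] - m2.result.beta[1:]).max() < 0.02

    def test_recovers_generative_selection(self, sim_cfg, env):
        """One replicate of the seal-generator recovery design."""
        used, avail, truth = seal_recovery_dataset(sim_cfg, env, seed=31,
                                                   n_seals=6,
                                                   fixes_per_seal=400)
        table = rsf.build_table(used, avail,
                                ["bathymetry", "slope", "dist_colony"])
        m = rsf.fit_weighted_rsf(table,
                                 ["bathymetry", "slope", "dist_colony"],
                                 maxfev=40)
        assert m.converged
        for cov, b_raw in truth["beta_raw"].items():
            sd_gen = (abs(sim_cfg.seal_beta_true[cov] / b_raw)
                      if b_raw else None)
            est_raw = m.beta_raw_scale[cov]
            if sd_gen:
                assert est_raw * sd_gen == pytest.approx(
                    sim_cfg.seal_beta_true[cov], abs=0.2)


class TestPredictScores:
    def _toy_model(self, env):
        rng = np.random.default_rng(7)
        n = 400
        t = pd.DataFrame({
            "bathymetry": rng.normal(-200, 80, n),
            "slope": rng.normal(0.5, 0.2, n),
            "case": rng.integers(0, 2, n),
            "weight": 1.0,
            "individual_id": rng.integers(0, 3, n).astype(str)})
        return rsf.fit_weighted_rsf(t, ["bathymetry", "slope"], maxfev=15)

    def test_pixelwise_hand_computation(self, env):
        m = self._toy_model(env)
        scores = rsf.predict_scores(m, env)
        rng = np.random.default_rng(8)
        sea = np.argwhere(env.sea_mask)
        pick = sea[rng.integers(0, len(sea), 100)]
        b = m.result.beta
        for r, c in pick:
            x1 = (env.layers["bathymetry"].values[r, c]
                  - m.standardizer.means["bathymetry"]) \
                / m.standardizer.sds["bathymetry"]
            x2 = (env.layers["slope"].values[r, c]
                  - m.standardizer.means["slope"]) \
                / m.standardizer.sds["slope"]
            assert scores.values[r, c] == pytest.approx(
                np.exp(b[1] * x1 + b[2] * x2))

    def test_land_masked(self, env):
        m = self._toy_model(env)
        scores = rsf.predict_scores(m, env)
        assert np.isnan(scores.values[env.land_mask]).all()

    def test_missing_covariate_named_in_error(self, env):
        m = self._toy_model(env)
        m.covariates = ["bathymetry", "nonexistent"]
        with pytest.raises(KeyError, match="nonexistent"):
            rsf.predict_scores(m, env)

    def test_monotone_in_signed_covariate(self, env):
        """Negative coefficient: score non-increasing along a transect of
        increasing covariate with the other held fixed."""
        m = self._toy_model(env)
        b = m.result.beta
        grid = np.linspace(-500, -50, 20)
        s = np.exp(b[1] * m.standardizer.transform_array("bathymetry",
                                                         grid))
        diffs = np.diff(s)
        assert (diffs <= 0).all() if b[1] < 0 else (diffs >= 0).all()


class TestStandardizationRoundTrip:
    def test_raw_scale_prediction_equivalence(self):
        rng = np.random.default_rng(9)
        t = logistic_table(rng, [0.6], n=1500, n_ind=3)
        t["c0"] = t["c0"] * 12.0 + 40.0   # un-standardized units
        m = rsf.fit_weighted_rsf(t, ["c0"], maxfev=25)
        raw = np.linspace(10, 70, 11)
        eta_std = m.result.beta[1] * m.standardizer.transform_array(
            "c0", raw)
        eta_raw = m.beta_raw_scale["c0"] * (raw
                                            - m.standardizer.means["c0"])
        np.testing.assert_allclose(eta_std, eta_raw, atol=1e-10)
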