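"""Diel habitat-use model: daytime foraging vs nighttime resting.

For birds that stay at sea overnight, each daytime foraging fix (y = 1)
and nighttime resting fix (y = 0) is a Bernoulli trial whose probability
depends on the period-matched seal-occurrence index, sea-surface
temperature and the two fisheries-catch covariates.  Each predictor may
enter linearly or through a natural cubic spline with 4 degrees of
freedom; all 2^4 form combinations are fitted as a mixed logistic model
with random intercepts for individual and year (variances estimated), and
the model with the smallest small-sample-corrected AIC wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .mixedlogit import MixedLogitResult, RandomTerm, fit_mixed_logit
from .rsf import Standardizer

DIEL_COVARIATES = ("seal_index", "sst", "purse", "trawl")


def natural_spline_basis(x, df: int = 4, knots: np.ndarray | None = None,
                         boundary: tuple[float, float] | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Knots default to the data range (boundary) plus ``df - 1`` interior
    knots at evenly spaced quantiles; the basis is linear beyond the
    boundary knots and its second derivative vanishes there.  Returns the
    basis matrix and the full knot vector (for reuse at prediction time).
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("df must be >= 2")
    if knots is None:
        if np.nanstd(x) == 0:
            raise ValueError("x is constant; spline basis undefined")
        if boundary is None:
            boundary = (float(np.nanmin(x)), float(np.nanmax(x)))
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior = np.quantile(x[np.isfinite(x)], probs)
        knots = np.concatenate([[boundary[0]], interior, [boundary[1]]])
    knots = np.asarray(knots, dtype=float)
    K = len(knots)

    def d(k):
        num = (np.maximum(x - knots[k], 0.0) ** 3
               - np.maximum(x - knots[K - 1], 0.0) ** 3)
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    dK2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK2)
    basis = np.column_stack(cols)
    assert basis.shape[1] == df
    return basis, knots


def aicc(loglik: float, k_params: int, n_obs: int) -> float:
    """AIC corrected for finite samples: -2l + 2k + 2k(k+1)/(n-k-1)."""
    if n_obs <= k_params + 1:
        raise ValueError("n_obs must exceed k_params + 1")
    return (-2.0 * loglik + 2.0 * k_params
            + 2.0 * k_params * (k_params + 1) / (n_obs - k_params - 1))


def build_diel_table(day_forage: pd.DataFrame, night_rest: pd.DataFrame
                     ) -> pd.DataFrame:
    """Stack period-matched fixes into the diel response table.

    Both inputs carry the covariate columns plus individual_id and year;
    rows with missing covariates are dropped and counted.
    """
    d = day_forage.copy()
    d["y"] = 1
    r = night_rest.copy()
    r["y"] = 0
    cols = ["y", "individual_id", "year"] + list(DIEL_COVARIATES)
    table = pd.concat([d[cols], r[cols]], ignore_index=True)
    n0 = len(table)
    table = table.dropna(subset=list(DIEL_COVARIATES)).reset_index(drop=True)
    table.attrs["n_dropped"] = n0 - len(table)
    return table


@dataclass
class DielModel:
    """One fitted candidate of the diel model set."""

    forms: dict[str, str]              # covariate -> 'linear' | 'spline'
    result: MixedLogitResult
    standardizer: Standardizer
    knots: dict[str, np.ndarray]       # per spline covariate (std scale)
    covariates: list[str]
    aicc: float
    rank: int = 0
    col_slices: dict[str, slice] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.result.converged

    def linear_predictor(self, covariate: str, grid_std: np.ndarray):
        """eta and its variance along one covariate, others at their mean.

        Other covariates sit at standardized 0; spline columns of other
        covariates are evaluated at 0 as well.
        """
        p = len(self.result.beta)
        n = len(grid_std)
        D = np.zeros((n, p))
        D[:, 0] = 1.0
        for name in self.covariates:
            sl = self.col_slices[name]
            if name == covariate:
                if self.forms[name] == "spline":
                    basis, _ = natural_spline_basis(
                        grid_std, df=sl.stop - sl.start,
                        knots=self.knots[name])
                    D[:, sl] = basis
                else:
                    D[:, sl.start] = grid_std
            else:
                if self.forms[name] == "spline":
                    basis, _ = natural_spline_basis(
                        np.zeros(n), df=sl.stop - sl.start,
                        knots=self.knots[name])
                    D[:, sl] = basis
                else:
                    D[:, sl.start] = 0.0
        eta = D @ self.result.beta
        var = np.einsum("ij,jk,ik->i", D, self.result.beta_cov, D)
        return eta, var


def _design_for_forms(table_std: pd.DataFrame, forms: dict[str, str],
                      covariates, spline_df: int = 4,
                      knots: dict[str, np.ndarray] | None = None):
    cols = [np.ones((len(table_std), 1))]
    names = ["intercept"]
    slices = {}
    used_knots = {}
    pos = 1
    for name in covariates:
        x = table_std[name].to_numpy(float)
        if forms[name] == "spline":
            basis, kn = natural_spline_basis(
                x, df=spline_df,
                knots=None if knots is None else knots.get(name))
            cols.append(basis)
            names += [f"{name}_ns{j+1}" for j in range(spline_df)]
            slices[name] = slice(pos, pos + spline_df)
            used_knots[name] = kn
            pos += spline_df
        else:
            cols.append(x[:, None])
            names.append(name)
            slices[name] = slice(pos, pos + 1)
            pos += 1
    return np.hstack(cols), names, slices, used_knots


def fit_diel_candidates(table: pd.DataFrame, seed: int = 0,
                        covariates=DIEL_COVARIATES, spline_df: int = 4,
                        maxfev: int = 40) -> list[DielModel]:
    """Fit all linear-vs-spline form combinations, ranked by AICc.

    Mixed logistic models with random intercepts for individual and year
    (variances estimated by Laplace approximation, no use-availability
    weights).  The variance components are estimated once, on the
    all-linear candidate, and held at those values while the 2^p form
    combinations are ranked — they describe grouping structure that does
    not depend on the fixed-effect forms, and sharing them removes
    optimizer jitter from the AICc differences.  The two estimated
    variances are counted in every candidate's parameter total.
    Non-converged candidates sink to the bottom of the ranking.
    """
    covariates = list(covariates)
    std = Standardizer.fit(table, covariates)
    tt = std.transform(table)
    y = tt["y"].to_numpy(float)
    id_codes, _ = pd.factorize(tt["individual_id"])
    yr_codes, _ = pd.factorize(tt["year"])
    n = len(tt)
    terms_proto = [("individual", id_codes), ("year", yr_codes)]

    def make_terms(var_fix):
        return [RandomTerm(name=nm, groups=g, z=np.ones((n, 1)),
                           var_fixed=np.array([var_fix[nm]]),
                           col_names=["intercept"])
                for nm, g in terms_proto]

    # stage 1: estimate the grouping variances on the all-linear model
    all_linear = {c: "linear" for c in covariates}
    X0, names0, _, _ = _design_for_forms(tt, all_linear, covariates,
                                         spline_df=spline_df)
    res0 = fit_mixed_logit(
        X0, y, make_terms({"individual": np.nan, "year": np.nan}),
        beta_names=names0, maxfev=maxfev)
    var_hat = {"individual": res0.variances["individual:intercept"],
               "year": res0.variances["year:intercept"]}
    n_var = res0.n_var_estimated

    models = []
    for combo in itertools.product(("linear", "spline"),
                                   repeat=len(covariates)):
        forms = dict(zip(covariates, combo))
        X, names, slices, used_knots = _design_for_forms(
            tt, forms, covariates, spline_df=spline_df)
        res = fit_mixed_logit(X, y, make_terms(var_hat),
                              beta_names=names)
        k = X.shape[1] + n_var
        crit = aicc(res.loglik, k, n)
        models.append(DielModel(forms=forms, result=res, standardizer=std,
                                knots=used_knots, covariates=covariates,
                                aicc=crit, col_slices=slices))
    models.sort(key=lambda m: (not m.converged, m.aicc))
    for i, m in enumerate(models):
        m.rank = i + 1
    return models


def response_curve(model: DielModel, covariate: str,
                   grid: np.ndarray | None = None, n_grid: int = 100,
                   level: float = 0.95,
                   train_range: tuple[float, float] | None = None
                   ) -> pd.DataFrame:
    """Probability of daytime foraging along one covariate (Fig-4 style).

    All other covariates sit at their (standardized) mean; the confidence
    band is delta-method on the linear predictor; the x column is
    back-transformed to original units.  Grid points outside the training
    range are flagged ``extrapolated``.
    """
    if covariate not in model.covariates:
        raise KeyError(f"{covariate!r} not in model")
    sd = model.standardizer.sds[covariate]
    mu = model.standardizer.means[covariate]
    if grid is None:
        kn = model.knots.get(covariate)
        if kn is not None:
            lo, hi = kn[0], kn[-1]
        else:
            lo, hi = -2.0, 2.0
        grid_std = np.linspace(lo, hi, n_grid)
    else:
        grid_std = (np.asarray(grid, dtype=float) - mu) / sd
    eta, var = model.linear_predictor(covariate, grid_std)
    z = norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.maximum(var, 0.0))
    out = pd.DataFrame({
        covariate: grid_std * sd + mu,
        "p": expit(eta),
        "lo": expit(eta - z * se),
        "hi": expit(eta + z * se),
    })
    if train_range is not None:
        out["extrapolated"] = (out[covariate] < train_range[0]) | \
            (out[covariate] > train_range[1])
    return out
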