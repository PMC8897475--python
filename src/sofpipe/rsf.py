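"""Weighted use-availability resource selection functions (RSFs).

The RSF contrasts used locations (case = 1, weight 1) against available
locations (case = 0, weight W = 1000) in a mixed logistic regression with a
random intercept per individual whose variance is *fixed* at a large
constant, and an estimated diagonal random slope per covariate — the
infinitely-weighted-likelihood formulation that makes logistic regression
approximate the inhomogeneous-Poisson use-availability model.  The
exponential fixed-effect linear predictor, exp(beta' x), is the relative
probability of occurrence used downstream for risk maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_env import EnvStack, Raster
from .mixedlogit import MixedLogitResult, RandomTerm, fit_mixed_logit

DEFAULT_SIGMA0_SQ = 1e6
DEFAULT_WEIGHT = 1000.0


@dataclass
class Standardizer:
    """Center-and-scale transform stored with every fitted model."""

    means: dict[str, float]
    sds: dict[str, float]

    @classmethod
    def fit(cls, table: pd.DataFrame, covariates) -> "Standardizer":
        means = {c: float(table[c].mean()) for c in covariates}
        sds = {}
        for c in covariates:
            sd = float(table[c].std(ddof=0))
            if sd == 0:
                raise ValueError(f"covariate {c!r} is constant")
            sds[c] = sd
        return cls(means=means, sds=sds)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.means:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out

    def transform_array(self, name: str, values):
        return (np.asarray(values, dtype=float)
                - self.means[name]) / self.sds[name]

    def inverse(self, name: str, values):
        return np.asarray(values, dtype=float) * self.sds[name] \
            + self.means[name]


@dataclass
class CollinearityReport:
    corr: pd.DataFrame
    vif: pd.Series
    r_max: float
    vif_max: float

    @property
    def passed(self) -> bool:
        off = self.corr.to_numpy().copy()
        np.fill_diagonal(off, 0.0)
        return bool(np.nanmax(np.abs(off)) <= self.r_max
                    and self.vif.max() < self.vif_max)


def screen_collinearity(table: pd.DataFrame, covariates,
                        r_max: float, vif_max: float = 2.0
                        ) -> CollinearityReport:
    """Pairwise Pearson |r| and variance inflation factors.

    VIF_j = 1/(1 - R^2_j) from regressing covariate j on the others.
    Constant covariates are rejected (their VIF is undefined).
    """
    covariates = list(covariates)
    if len(covariates) < 2:
        raise ValueError("need at least two covariates to screen")
    X = table[covariates].to_numpy(float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate: VIF undefined")
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False),
                        index=covariates, columns=covariates)
    vifs = {}
    for j, name in enumerate(covariates):
        yj = X[:, j]
        Xo = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        vifs[name] = 1.0 / max(1.0 - r2, 1e-12)
    return CollinearityReport(corr=corr, vif=pd.Series(vifs),
                              r_max=r_max, vif_max=vif_max)


@dataclass
class RSFModel:
    """Fitted weighted RSF with its standardization transform."""

    result: MixedLogitResult
    covariates: list[str]
    standardizer: Standardizer
    sigma0_sq: float
    weight: float
    n_used: int
    n_available: int

    @property
    def coefficients(self) -> pd.DataFrame:
        lo, hi = self.result.ci()
        return pd.DataFrame({
            "coef": self.result.beta,
            "se": self.result.beta_se,
            "ci_lo": lo, "ci_hi": hi,
        }, index=self.result.beta_names)

    @property
    def beta(self) -> pd.Series:
        """Fixed-effect slopes on the standardized scale (no intercept)."""
        return pd.Series(self.result.beta[1:], index=self.covariates)

    @property
    def beta_raw_scale(self) -> pd.Series:
        """Slopes per original covariate unit (descaled)."""
        return pd.Series(
            [self.result.beta[1 + j] / self.standardizer.sds[c]
             for j, c in enumerate(self.covariates)],
            index=self.covariates)

    @property
    def converged(self) -> bool:
        return self.result.converged

    def report(self) -> dict:
        lo, hi = self.result.ci()
        return {
            "covariates": self.covariates,
            "beta": dict(zip(self.result.beta_names,
                             map(float, self.result.beta))),
            "ci_lo": dict(zip(self.result.beta_names, map(float, lo))),
            "ci_hi": dict(zip(self.result.beta_names, map(float, hi))),
            "random_slope_variances": self.result.variances,
            "sigma0_sq": self.sigma0_sq,
            "weight": self.weight,
            "loglik": self.result.loglik,
            "converged": self.result.converged,
            "n_used": self.n_used,
            "n_available": self.n_available,
        }


def build_table(used: pd.DataFrame, available: pd.DataFrame,
                covariates, weight: float = DEFAULT_WEIGHT) -> pd.DataFrame:
    """Stack used/available rows into a use-availability table.

    Both frames need the covariate columns plus ``individual_id`` (and
    optionally ``year``).  Rows with missing covariates are dropped and
    counted in ``table.attrs['n_dropped']``.
    """
    u = used.copy()
    u["case"] = 1
    u["weight"] = 1.0
    a = available.copy()
    a["case"] = 0
    a["weight"] = float(weight)
    keep = ["case", "weight", "individual_id"] + list(covariates)
    if "year" in u.columns and "year" in a.columns:
        keep.append("year")
    table = pd.concat([u[keep], a[keep]], ignore_index=True)
    n0 = len(table)
    table = table.dropna(subset=list(covariates)).reset_index(drop=True)
    table.attrs["n_dropped"] = n0 - len(table)
    return table


def fit_weighted_rsf(table: pd.DataFrame, covariates,
                     sigma0_sq: float = DEFAULT_SIGMA0_SQ,
                     random_slopes: bool = True,
                     standardize: bool = True,
                     maxfev: int = 60,
                     theta0: np.ndarray | None = None) -> RSFModel:
    """Fit the weighted mixed RSF on a use-availability table.

    ``table`` needs columns case (1 used / 0 available), weight,
    individual_id and the covariates.  Covariates are centered and scaled
    internally (the transform is stored on the model); the individual
    random intercept variance is fixed at ``sigma0_sq`` and never
    estimated.
    """
    covariates = list(covariates)
    if table["individual_id"].nunique() < 2:
        # single individual: drop the random structure entirely; the fit
        # reduces to plain weighted logistic regression
        return _fit_single_individual(table, covariates, sigma0_sq,
                                      standardize)
    std = Standardizer.fit(table, covariates) if standardize else \
        Standardizer(means={c: 0.0 for c in covariates},
                     sds={c: 1.0 for c in covariates})
    tt = std.transform(table)
    Xc = tt[covariates].to_numpy(float)
    X = np.column_stack([np.ones(len(tt)), Xc])
    y = tt["case"].to_numpy(float)
    w = tt["weight"].to_numpy(float)
    codes, _ = pd.factorize(tt["individual_id"])
    if random_slopes:
        z = np.column_stack([np.ones(len(tt)), Xc])
        var_fixed = np.concatenate([[sigma0_sq],
                                    np.full(len(covariates), np.nan)])
        col_names = ["intercept"] + covariates
    else:
        z = np.ones((len(tt), 1))
        var_fixed = np.array([sigma0_sq])
        col_names = ["intercept"]
    term = RandomTerm(name="individual", groups=codes, z=z,
                      var_fixed=var_fixed, col_names=col_names)
    res = fit_mixed_logit(X, y, [term], weights=w,
                          beta_names=["intercept"] + covariates,
                          theta0=theta0, maxfev=maxfev)
    assert res.variances["individual:intercept"] == sigma0_sq
    return RSFModel(result=res, covariates=covariates, standardizer=std,
                    sigma0_sq=sigma0_sq,
                    weight=float(table.loc[table["case"] == 0,
                                           "weight"].max()
                                 if (table["case"] == 0).any() else 1.0),
                    n_used=int((table["case"] == 1).sum()),
                    n_available=int((table["case"] == 0).sum()))


def _fit_single_individual(table, covariates, sigma0_sq, standardize):
    std = Standardizer.fit(table, covariates) if standardize else \
        Standardizer(means={c: 0.0 for c in covariates},
                     sds={c: 1.0 for c in covariates})
    tt = std.transform(table)
    X = np.column_stack([np.ones(len(tt)),
                         tt[covariates].to_numpy(float)])
    res = fit_mixed_logit(X, tt["case"].to_numpy(float), [],
                          weights=tt["weight"].to_numpy(float),
                          beta_names=["intercept"] + covariates)
    return RSFModel(result=res, covariates=list(covariates),
                    standardizer=std, sigma0_sq=sigma0_sq,
                    weight=float(table.loc[table["case"] == 0,
                                           "weight"].max()
                                 if (table["case"] == 0).any() else 1.0),
                    n_used=int((table["case"] == 1).sum()),
                    n_available=int((table["case"] == 0).sum()))


def predict_scores(model: RSFModel, env: EnvStack,
                   month: int | None = None,
                   extra_layers: dict[str, np.ndarray] | None = None
                   ) -> Raster:
    """Per-pixel RSF score exp(beta' x_std), fixed effects only, land NaN.

    Covariates are pulled from the stack's layers (``sst`` resolves via
    ``month``) or from ``extra_layers``; a covariate absent from both is an
    error naming it.
    """
    grid = env.grid
    eta = np.zeros((grid.ny, grid.nx))
    for j, name in enumerate(model.covariates):
        if extra_layers and name in extra_layers:
            vals = np.asarray(extra_layers[name], dtype=float)
        elif name == "sst":
            if month is None and 0 not in env.sst_monthly:
                raise ValueError("predict_scores: month needed for sst")
            vals = env.sst_for_month(month or 0).values
        elif name in env.layers:
            vals = env.layers[name].values
        else:
            raise KeyError(f"covariate {name!r} missing from EnvStack")
        x_std = model.standardizer.transform_array(name, vals)
        eta += model.result.beta[1 + j] * x_std
    scores = np.exp(eta)
    scores[env.land_mask] = np.nan
    return Raster(grid=grid, values=scores, name="rsf_score")
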