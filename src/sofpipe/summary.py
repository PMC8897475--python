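"""Habitat-use summaries and derived diel-shift quantities.

Group means (e.g. distance to shore of nighttime resting locations) are
estimated with an intercept-only linear mixed model with random intercepts
for individual and year, so repeated measures within a bird or a season do
not masquerade as independent observations; min/max are raw ranges.  On
top of the summaries sit the derived diel quantities: the offshore
night-rest shift (km), the day-night difference in sea-surface
temperature, the percent reduction in seal-encounter risk, and the
rest-at-colony / rest-at-sea tactic split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


def mixed_mean_ci(values, individual_id, year=None, level: float = 0.95):
    """Population mean and Wald CI from an intercept-only mixed model.

    Random intercepts for individual and (when more than one is present)
    year; a single year drops the year effect with a log note.  With all
    grouping variances forced to zero this reduces to the sample mean.
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    values = values[ok]
    ind = pd.Series(np.asarray(individual_id)[ok], name="ind")
    if len(values) == 0:
        return np.nan, np.nan, np.nan
    if np.ptp(values) == 0:
        return float(values[0]), float(values[0]), float(values[0])
    if ind.nunique() < 2:
        m = values.mean()
        se = values.std(ddof=1) / np.sqrt(len(values))
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        return float(m), float(m - z * se), float(m + z * se)
    df = pd.DataFrame({"y": values, "ind": ind.to_numpy()})
    vc = {"ind": "0 + C(ind)"}
    if year is not None:
        yr = pd.Series(np.asarray(year)[ok])
        if yr.nunique() >= 2:
            df["yr"] = yr.to_numpy()
            vc["yr"] = "0 + C(yr)"
        else:
            logger.info("mixed_mean_ci: single year, year effect dropped")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                "y ~ 1", groups=np.ones(len(df)), vc_formula=vc, data=df)
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
            mean = float(fit.fe_params.iloc[0])
            se = float(fit.bse_fe.iloc[0])
    except (np.linalg.LinAlgError, ValueError):
        # tiny/degenerate samples: mean and SE over individual means
        g = df.groupby("ind")["y"].mean()
        mean = float(g.mean())
        se = float(g.std(ddof=1) / np.sqrt(len(g))) if len(g) > 1 else 0.0
    if not np.isfinite(se):
        # boundary variance estimate: fall back to the between-individual
        # spread of per-individual means
        g = df.groupby("ind")["y"].mean()
        se = float(g.std(ddof=1) / np.sqrt(len(g))) if len(g) > 1 else 0.0
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2.0)
    return mean, mean - z * se, mean + z * se


@dataclass
class HabitatUseSummary:
    """Table of per-group, per-variable mixed means, CIs and raw ranges."""

    table: pd.DataFrame   # index (group, variable)

    def to_csv(self, path):
        self.table.to_csv(path)


def habitat_use_summary(locations: pd.DataFrame, variables,
                        group_col: str = "group") -> HabitatUseSummary:
    """Table-1-style summary over location groups.

    ``locations`` has one row per fix with columns ``individual_id``,
    ``year``, a group label (e.g. 'day_forage_rest_at_sea') and the
    habitat variables.  Means and CIs come from the mixed model,
    min/max from the raw fixes.
    """
    rows = []
    for grp, sub in locations.groupby(group_col):
        for var in variables:
            vals = sub[var].to_numpy(float)
            mean, lo, hi = mixed_mean_ci(
                vals, sub["individual_id"].to_numpy(),
                sub["year"].to_numpy() if "year" in sub else None)
            rows.append({
                "group": grp, "variable": var, "mean": mean,
                "ci_lo": lo, "ci_hi": hi,
                "min": (float(np.nanmin(vals))
                        if np.isfinite(vals).any() else np.nan),
                "max": (float(np.nanmax(vals))
                        if np.isfinite(vals).any() else np.nan),
                "n_locations": int(np.isfinite(vals).sum()),
                "n_birds": int(sub["individual_id"].nunique()),
            })
    table = pd.DataFrame(rows).set_index(["group", "variable"])
    return HabitatUseSummary(table=table)


def diel_shift(per_fix: pd.DataFrame) -> tuple[pd.Series, tuple]:
    """Per-bird and cohort offshore shift between night rest and day forage.

    ``per_fix`` needs columns individual_id, year, dist_shore, and a
    ``period`` column in {'day_forage', 'night_rest'}.  The per-bird shift
    is mean dist_shore(night rest) minus mean dist_shore(day forage);
    positive = farther offshore at night.  Birds missing one period are
    excluded and counted.  Returns (per-bird shifts, (mean, lo, hi)).
    """
    shifts, years = {}, {}
    excluded = 0
    for bird, sub in per_fix.groupby("individual_id"):
        day = sub.loc[sub["period"] == "day_forage", "dist_shore"]
        night = sub.loc[sub["period"] == "night_rest", "dist_shore"]
        if len(day) == 0 or len(night) == 0:
            excluded += 1
            continue
        shifts[bird] = float(night.mean() - day.mean())
        years[bird] = sub["year"].iloc[0] if "year" in sub else 0
    if excluded:
        logger.info("diel_shift: %d birds missing one period", excluded)
    s = pd.Series(shifts, name="shift_km")
    if len(s) == 0:
        return s, (np.nan, np.nan, np.nan)
    mean_ci = mixed_mean_ci(s.to_numpy(),
                            np.array(list(s.index)),
                            np.array([years[b] for b in s.index]))
    return s, mean_ci


def delta_sst(summary: HabitatUseSummary,
              night_group: str = "night_rest_rest_at_sea",
              day_group: str = "day_forage_rest_at_sea") -> float:
    """SST(night rest) - SST(day forage), degrees C (e.g. 16.9 - 16.6)."""
    t = summary.table
    return float(t.loc[(night_group, "sst"), "mean"]
                 - t.loc[(day_group, "sst"), "mean"])


def tactic_proportions(bird_tactics: pd.Series) -> dict:
    """Percentages of birds per nocturnal tactic.

    ``bird_tactics`` maps bird id to 'rest_at_colony' / 'rest_at_sea' /
    None (unassigned; reported separately).  A bird's tactic is expected
    to be the majority rule over its trips.
    """
    assigned = bird_tactics.dropna()
    n = len(assigned)
    out = {"n_birds": int(len(bird_tactics)), "n_assigned": int(n),
           "n_unassigned": int(len(bird_tactics) - n)}
    for tactic in ("rest_at_colony", "rest_at_sea"):
        cnt = int((assigned == tactic).sum())
        out[f"{tactic}_count"] = cnt
        out[f"{tactic}_pct"] = 100.0 * cnt / n if n else np.nan
    return out


def majority_tactic(trip_tactics: pd.DataFrame) -> pd.Series:
    """Bird-level tactic by majority over trips (ties -> rest_at_sea).

    ``trip_tactics`` has columns individual_id and tactic (None allowed).
    """
    def vote(sub):
        t = sub.dropna()
        if len(t) == 0:
            return None
        n_sea = (t == "rest_at_sea").sum()
        n_col = (t == "rest_at_colony").sum()
        return "rest_at_sea" if n_sea >= n_col else "rest_at_colony"

    return trip_tactics.groupby("individual_id")["tactic"].apply(vote)
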