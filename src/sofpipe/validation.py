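"""Boyce-style cross-validation of RSF models.

A fitted RSF is judged by how well its binned score map predicts
independent locations: held-out individuals' used points are tallied per
score bin, adjusted for the bin's areal share of the map, and the Spearman
rank correlation between bin rank (1..10) and that area-adjusted frequency
is averaged over folds.  Folds always split *individuals*, never points:
leave-one-individual-out (seals) or 80/20 k-fold by individual (gannets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .fearscape import BinnedMap, bin_scores
from .rsf import fit_weighted_rsf


@dataclass
class CVResult:
    fold_rs: list[float]
    scheme: str
    n_bins: int = 10
    skipped_folds: int = 0
    fold_details: list[dict] = field(default_factory=list)

    @property
    def mean_rs(self) -> float:
        return float(np.mean(self.fold_rs)) if self.fold_rs else np.nan


def area_adjusted_frequency(test_bins: np.ndarray, binned: BinnedMap
                            ) -> pd.Series:
    """Per-bin frequency of test points adjusted for bin area.

    f_b = (share of test points in bin b) / (share of map pixels in bin
    b).  Bins absent from the raster get NaN (dropped from correlations,
    with a flag); under uniform use every f_b is 1.
    """
    nb = binned.n_bins
    vals = binned.raster.values
    pix_counts = np.array([(vals == b).sum() for b in range(1, nb + 1)],
                          dtype=float)
    total_pix = pix_counts.sum()
    tb = np.asarray(test_bins, dtype=float)
    tb = tb[np.isfinite(tb)]
    pt_counts = np.array([(tb == b).sum() for b in range(1, nb + 1)],
                         dtype=float)
    total_pts = pt_counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (pt_counts / total_pts) / (pix_counts / total_pix)
    f[pix_counts == 0] = np.nan
    return pd.Series(f, index=pd.RangeIndex(1, nb + 1, name="bin"))


def spearman_bins(freq: pd.Series) -> float:
    """Spearman r between bin rank and area-adjusted frequency."""
    ok = freq.notna()
    if ok.sum() < 3:
        return np.nan
    r, _ = spearmanr(freq.index[ok], freq[ok])
    return float(r)


def make_folds(individuals: np.ndarray, scheme: str, seed: int = 0,
               test_fraction: float = 0.2) -> list[np.ndarray]:
    """Partition individuals into CV folds (each entry = test set ids)."""
    ids = np.unique(individuals)
    if scheme == "loo":
        return [np.array([i]) for i in ids]
    if scheme == "kfold":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(ids)
        n_folds = max(2, int(round(1.0 / test_fraction)))
        return [perm[k::n_folds] for k in range(n_folds)]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cv_rsf(table: pd.DataFrame, covariates, scheme: str = "loo",
           seed: int = 0, n_bins: int = 10, min_test_points: int = 20,
           fit_kwargs: dict | None = None) -> CVResult:
    """Cross-validate a weighted RSF on a use-availability table.

    Per fold: refit on training individuals, score *all* available rows of
    the fold (a stand-in for the mapped landscape), bin the scores into
    ``n_bins`` equal-count bins, place the test individuals' used points
    in those bins, and correlate bin rank against area-adjusted frequency.
    """
    fit_kwargs = dict(fit_kwargs or {})
    ids = table["individual_id"].to_numpy()
    if len(np.unique(ids)) < 3:
        raise ValueError("cross-validation needs at least 3 individuals")
    folds = make_folds(ids, scheme, seed=seed)
    fold_rs, details = [], []
    skipped = 0
    for test_ids in folds:
        is_test = np.isin(ids, test_ids)
        train = table.loc[~is_test]
        test_used = table.loc[is_test & (table["case"] == 1)]
        if len(test_used) < min_test_points:
            skipped += 1
            continue
        model = fit_weighted_rsf(train, covariates, **fit_kwargs)
        # score the availability sample as the landscape reference
        avail = table.loc[table["case"] == 0]
        tt_av = model.standardizer.transform(avail)
        tt_te = model.standardizer.transform(test_used)
        beta = model.result.beta[1:]
        s_av = np.exp(tt_av[list(covariates)].to_numpy(float) @ beta)
        s_te = np.exp(tt_te[list(covariates)].to_numpy(float) @ beta)
        edges = np.quantile(s_av, np.linspace(0, 1, n_bins + 1))
        inner = edges[1:-1]
        av_bins = np.searchsorted(inner, s_av, side="left") + 1
        te_bins = np.searchsorted(inner, s_te, side="left") + 1
        pix_counts = np.array([(av_bins == b).sum()
                               for b in range(1, n_bins + 1)], float)
        pt_counts = np.array([(te_bins == b).sum()
                              for b in range(1, n_bins + 1)], float)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (pt_counts / pt_counts.sum()) \
                / (pix_counts / pix_counts.sum())
        f[pix_counts == 0] = np.nan
        ok = np.isfinite(f)
        r, _ = spearmanr(np.arange(1, n_bins + 1)[ok], f[ok])
        fold_rs.append(float(r))
        details.append({"test_ids": list(map(str, test_ids)),
                        "n_test_used": int(len(test_used)),
                        "rs": float(r)})
    return CVResult(fold_rs=fold_rs, scheme=scheme, n_bins=n_bins,
                    skipped_folds=skipped, fold_details=details)
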