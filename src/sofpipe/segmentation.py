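"""Segmentation-clustering of step series into rest / forage / commute.

The model is the classic joint segmentation/clustering of a bivariate
series (smoothed speed, constant-step-length turning angle): the series is
partitioned into contiguous segments, each segment belongs to one of a
small number of behavioral classes, and within a class observations are
Gaussian with class-specific mean and (diagonal) variance.  For fixed class
parameters the optimal partition into K segments is found exactly by
dynamic programming; class parameters are refined by classification-EM
sweeps; the number of segments is chosen by a BIC-style penalized
likelihood.  States are relabeled deterministically by ascending mean
speed: rest < forage < commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .trajectory import Track

STATE_NAMES = ("rest", "forage", "commute")

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-6


@dataclass
class BehaviorSequence:
    """Per-fix behavioral states and the segment partition behind them."""

    segments: list[tuple[int, int, str]]  # (start, end exclusive, state)
    states: np.ndarray                    # per-fix state names
    n_segments: int
    model_score: float                    # penalized log-likelihood
    k_chosen: int = 0
    degenerate: bool = False
    class_means: dict = field(default_factory=dict)

    def state_mask(self, state: str) -> np.ndarray:
        return self.states == state


def _standardize(features: np.ndarray) -> np.ndarray:
    """Per-track standardization; missing values imputed at the mean."""
    out = np.array(features, dtype=float)
    for j in range(out.shape[1]):
        col = out[:, j]
        mu = np.nanmean(col)
        sd = np.nanstd(col)
        col = np.where(np.isfinite(col), col, mu)
        out[:, j] = (col - mu) / (sd if sd > 0 else 1.0)
    return out


def _pointwise_negloglik(x: np.ndarray, means: np.ndarray,
                         variances: np.ndarray) -> np.ndarray:
    """-loglik of each point under each class; shape (n, n_classes)."""
    n, d = x.shape
    C = means.shape[0]
    out = np.zeros((n, C))
    for c in range(C):
        var = np.maximum(variances[c], _VAR_FLOOR)
        z = (x - means[c]) ** 2 / var
        out[:, c] = 0.5 * (z.sum(axis=1)
                           + np.sum(_LOG2PI + np.log(var)))
    return out


def _segment_cost_matrix(x: np.ndarray, means: np.ndarray,
                         variances: np.ndarray, Lmin: int,
                         nll: np.ndarray | None = None):
    """cost[i, j] = min over classes of -loglik of points i..j (inclusive).

    Also returns the argmin class.  Entries for segments shorter than Lmin
    are +inf.  O(n^2 * n_classes) via per-class cumulative sums.
    """
    if nll is None:
        nll = _pointwise_negloglik(x, means, variances)
    n, C = nll.shape
    cum = np.vstack([np.zeros(C), np.cumsum(nll, axis=0)])   # (n+1, C)
    best = np.full((n, n), np.inf)
    which = np.zeros((n, n), dtype=np.int8)
    for c in range(C):
        cost_c = cum[1:, c][None, :] - cum[:-1, c][:, None]
        upd = cost_c < best
        best[upd] = cost_c[upd]
        which[upd] = c
    lengths = (np.arange(1, n + 1)[None, :] - np.arange(n)[:, None])
    best[lengths < Lmin] = np.inf
    return best, which


def _dp_segment(cost: np.ndarray, Kmax: int):
    """Exact DP over the segment cost matrix.

    Returns ``total[k]`` (best cost using k+1 segments of the whole series)
    and a backpointer table for reconstruction.
    """
    n = cost.shape[0]
    Kmax = min(Kmax, n)
    best = np.full((Kmax, n), np.inf)
    back = np.zeros((Kmax, n), dtype=int)
    best[0] = cost[0]
    for k in range(1, Kmax):
        # candidate start i for the last segment ending at j
        prev = best[k - 1]
        cand = prev[:-1, None] + cost[1:, :]   # i-1 -> start i = 1..n-1
        arg = np.argmin(cand, axis=0)
        best[k] = np.min(cand, axis=0)
        back[k] = arg + 1
    return best, back


def _backtrack(back: np.ndarray, k: int, n: int) -> list[tuple[int, int]]:
    bounds = []
    j = n - 1
    for kk in range(k, -1, -1):
        i = back[kk, j] if kk > 0 else 0
        bounds.append((i, j + 1))
        j = i - 1
    return bounds[::-1]


def _init_params(x: np.ndarray, n_states: int, n_init: int, seed):
    gm = GaussianMixture(n_components=n_states, covariance_type="diag",
                         n_init=n_init, random_state=seed, reg_covar=1e-4)
    gm.fit(x)
    return gm.means_.copy(), gm.covariances_.copy()


def _segment_once(x, nll, Lmin, Kmax, log_pen, coarsen):
    """One DP pass: optimal bounds, per-segment classes, chosen K.

    ``coarsen > 1`` runs the DP on blocks of that many fixes (with exact
    local refinement of every boundary afterwards) — an approximation
    used for long series; ``coarsen = 1`` is the exact program.
    """
    n, C = nll.shape
    cum = np.vstack([np.zeros(C), np.cumsum(nll, axis=0)])

    if coarsen <= 1:
        cost, which = _segment_cost_matrix(x, None, None, Lmin, nll=nll)
        best, back = _dp_segment(cost, Kmax)
        total = best[:, -1]
        ks = np.arange(1, len(total) + 1)
        crit = 2.0 * total + log_pen * (ks - 1)
        k_star = int(np.argmin(crit))
        bounds = _backtrack(back, k_star, n)
    else:
        starts = np.arange(0, n, coarsen)
        block_nll = np.add.reduceat(nll, starts, axis=0)
        nb = len(starts)
        bcum = np.vstack([np.zeros(C), np.cumsum(block_nll, axis=0)])
        bcost = np.full((nb, nb), np.inf)
        for c in range(C):
            cc = bcum[1:, c][None, :] - bcum[:-1, c][:, None]
            np.minimum(bcost, cc, out=bcost)
        lb = (np.arange(1, nb + 1)[None, :] - np.arange(nb)[:, None])
        bcost[lb < max(1, int(np.ceil(Lmin / coarsen)))] = np.inf
        kmax_b = min(Kmax, nb)
        best, back = _dp_segment(bcost, kmax_b)
        total = best[:, -1]
        ks = np.arange(1, len(total) + 1)
        crit = 2.0 * total + log_pen * (ks - 1)
        k_star = int(np.argmin(crit))
        bbounds = _backtrack(back, k_star, nb)
        cuts = [starts[i] for (i, _) in bbounds[1:]]
        # refine each cut exactly within +/- coarsen fixes
        edges = [0] + cuts + [n]
        for ci in range(1, len(edges) - 1):
            lo = max(edges[ci - 1] + Lmin, edges[ci] - coarsen)
            hi = min(edges[ci + 1] - Lmin, edges[ci] + coarsen)
            if lo >= hi:
                continue
            left_start, right_end = edges[ci - 1], edges[ci + 1]
            cand = np.arange(lo, hi + 1)
            left = cum[cand] - cum[left_start]     # (m, C)
            right = cum[right_end] - cum[cand]
            score = left.min(axis=1) + right.min(axis=1)
            edges[ci] = int(cand[np.argmin(score)])
        bounds = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    seg_classes, tot = [], 0.0
    for (i, j) in bounds:
        seg_nll = cum[j] - cum[i]
        c = int(np.argmin(seg_nll))
        seg_classes.append(c)
        tot += float(seg_nll[c])
    return bounds, seg_classes, tot, len(bounds)


def segment_cluster(series: pd.DataFrame, Kmax: int | None = None,
                    n_states: int = 3, Lmin: int = 5,
                    n_init: int = 10, seed: int = 0,
                    penalty: float = 3.0, max_iter: int = 8,
                    coarsen: int | None = None,
                    features=("smoothed_speed", "turn_angle"),
                    ) -> BehaviorSequence:
    """Segment a step series and assign rest/forage/commute states.

    ``series`` is a step-series frame with the feature columns; features
    are standardized internally per track.  ``penalty`` scales the
    BIC-style cost ``penalty * (K - 1) * log(n)`` on extra segments.
    ``coarsen=None`` picks the exact DP for series up to 600 fixes and a
    block-coarsened DP (blocks of ``Lmin`` fixes, boundaries refined
    exactly) beyond that.  Series shorter than ``3 * Lmin`` get a
    single-segment degenerate output whose state comes from a plain
    speed threshold.
    """
    feats_raw = series[list(features)].to_numpy(float)
    speed_raw = series["smoothed_speed"].to_numpy(float)
    n = len(series)
    if n < 3 * Lmin:
        mean_sp = float(np.nanmean(speed_raw))
        state = ("rest" if mean_sp < 2.0
                 else ("commute" if mean_sp > 15.0 else "forage"))
        return BehaviorSequence(
            segments=[(0, n, state)],
            states=np.full(n, state, dtype=object),
            n_segments=1, model_score=np.nan, k_chosen=1, degenerate=True)

    x = _standardize(feats_raw)
    if Kmax is None:
        Kmax = max(1, min(30, n // (2 * Lmin)))
    Kmax = max(1, min(Kmax, n // Lmin))
    if coarsen is None:
        coarsen = 1 if n <= 600 else Lmin

    means, variances = _init_params(x, n_states, n_init, seed)
    log_pen = penalty * np.log(n)

    prev_labels = None
    result = None
    for _ in range(max_iter):
        nll = _pointwise_negloglik(x, means, variances)
        bounds, seg_classes, tot, k_used = _segment_once(
            x, nll, Lmin, Kmax, log_pen, coarsen)
        labels = np.empty(n, dtype=int)
        for (i, j), c in zip(bounds, seg_classes):
            labels[i:j] = c
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        prev_labels = labels
        # classification-M step: update class params from assigned points
        for c in range(n_states):
            pts = x[labels == c]
            if len(pts) >= 2:
                means[c] = pts.mean(axis=0)
                variances[c] = np.maximum(pts.var(axis=0), _VAR_FLOOR)
        result = (bounds, seg_classes, labels,
                  -tot - 0.5 * log_pen * (k_used - 1), k_used)

    bounds, seg_classes, labels, score, k_used = result

    # deterministic relabeling by ascending mean raw speed
    order = []
    for c in range(n_states):
        pts = speed_raw[labels == c]
        order.append(np.nanmean(pts) if len(pts) else np.inf)
    rank = np.argsort(np.argsort(order))  # class -> rank
    name_of = {c: STATE_NAMES[min(int(rank[c]), len(STATE_NAMES) - 1)]
               for c in range(n_states)}
    states = np.array([name_of[c] for c in labels], dtype=object)
    segments = []
    for (i, j), c in zip(bounds, seg_classes):
        segments.append((i, j, name_of[c]))
    class_means = {name_of[c]: float(np.nanmean(speed_raw[labels == c]))
                   for c in range(n_states) if (labels == c).any()}
    return BehaviorSequence(segments=segments, states=states,
                            n_segments=len(segments), model_score=score,
                            k_chosen=k_used, class_means=class_means)


@dataclass
class TripTactic:
    """Nocturnal tactic of one central-place foraging trip."""

    trip_id: str
    tactic: str | None                   # 'rest_at_colony' | 'rest_at_sea'
    night_fraction_resting: float = np.nan
    n_night_fixes: int = 0


def classify_tactic(track: Track, behavior: BehaviorSequence,
                    is_day: np.ndarray, colony_xy=(0.0, 0.0),
                    radius_km: float = 1.0) -> TripTactic:
    """Rest-at-colony vs rest-at-sea for one trip.

    A trip rests at the colony iff *all* its night-period fixes lie within
    ``radius_km`` of the colony; any offshore night fix makes it
    rest-at-sea.  Trips without night fixes get an undefined tactic and
    are excluded from diel analyses.  Also reports the fraction of night
    fixes that the segmentation labels as resting.
    """
    night = ~np.asarray(is_day, dtype=bool)
    n_night = int(night.sum())
    trip_id = track.trip_id or track.individual_id
    if n_night == 0:
        return TripTactic(trip_id=trip_id, tactic=None, n_night_fixes=0)
    xy = track.xy[night]
    d = np.hypot(xy[:, 0] - colony_xy[0], xy[:, 1] - colony_xy[1])
    tactic = "rest_at_colony" if bool((d <= radius_km).all()) \
        else "rest_at_sea"
    frac_rest = float(np.mean(behavior.states[night] == "rest"))
    return TripTactic(trip_id=trip_id, tactic=tactic,
                      night_fraction_resting=frac_rest,
                      n_night_fixes=n_night)
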