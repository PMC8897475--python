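"""Laplace-approximated mixed logistic regression.

This is the estimation engine behind both RSF stages and the diel model:
a binomial GLMM with optional per-row weights, arbitrary grouped random
effects with *diagonal* covariance, and the option of fixing selected
variance components (the "infinitely weighted" use-availability trick of
habitat-selection practice fixes the individual intercept variance at a
large constant instead of estimating it).

Estimation: for given variance components the joint penalized likelihood
is maximized over (fixed effects, random effects) by Newton/IRLS; the
marginal likelihood of the variance components is the Laplace
approximation at that mode; free variances are optimized on the log scale
by Nelder-Mead.  Wald covariance of the fixed effects comes from the
fixed-effect block of the inverse joint precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

_MAX_NEWTON = 50


@dataclass
class RandomTerm:
    """One grouped random-effect term with diagonal covariance.

    ``z`` holds the per-row design for the term's ``q`` effects (a column
    of ones for a random intercept, covariate columns for random slopes);
    ``groups`` are integer group codes in ``0..n_groups-1``.  Entries of
    ``var_fixed`` that are finite fix that effect's variance; NaN entries
    are estimated.
    """

    name: str
    groups: np.ndarray
    z: np.ndarray
    var_fixed: np.ndarray  # (q,), NaN = estimate
    col_names: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return int(self.groups.max()) + 1

    @property
    def q(self) -> int:
        return self.z.shape[1]


@dataclass
class MixedLogitResult:
    beta: np.ndarray
    beta_se: np.ndarray
    beta_cov: np.ndarray
    beta_names: list[str]
    loglik: float                 # Laplace marginal log-likelihood
    variances: dict[str, float]   # per random-effect column
    converged: bool
    n_obs: int
    n_fixed: int
    n_var_estimated: int
    random_effects: dict[str, np.ndarray] = field(default_factory=dict)

    def ci(self, level: float = 0.95):
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        return (self.beta - z * self.beta_se, self.beta + z * self.beta_se)


def _expand_random_design(terms: list[RandomTerm], n: int):
    """Dense expanded Z (n, dim_u) plus per-column metadata."""
    cols, labels, fixed = [], [], []
    for t in terms:
        G, q = t.n_groups, t.q
        block = np.zeros((n, G * q))
        for c in range(q):
            block[np.arange(n), t.groups * q + c] = t.z[:, c]
        cols.append(block)
        for g in range(G):
            for c in range(q):
                labels.append((t.name, c))
        fixed.extend(list(t.var_fixed) * G)
    if cols:
        Z = np.hstack(cols)
    else:
        Z = np.zeros((n, 0))
    return Z, labels, np.asarray(fixed, dtype=float)


def _newton_joint(A, y, w, pen, coef0, tol=1e-9):
    """Maximize sum w*(y*eta - log(1+e^eta)) - 0.5 coef' P coef."""
    coef = coef0.copy()
    ll_prev = -np.inf
    converged = False
    for _ in range(_MAX_NEWTON):
        eta = A @ coef
        p = expit(eta)
        ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta)))
                   - 0.5 * np.sum(pen * coef ** 2))
        grad = A.T @ (w * (y - p)) - pen * coef
        Wd = w * p * (1.0 - p)
        H = (A * Wd[:, None]).T @ A
        H[np.diag_indices_from(H)] += pen + 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # halving line search on the penalized objective
        t = 1.0
        for _ls in range(30):
            cand = coef + t * step
            eta_c = A @ cand
            ll_c = float(np.sum(w * (y * eta_c - np.logaddexp(0.0, eta_c)))
                         - 0.5 * np.sum(pen * cand ** 2))
            if ll_c >= ll - 1e-12:
                break
            t *= 0.5
        coef = cand
        if abs(ll_c - ll_prev) < tol * (abs(ll_c) + 1.0):
            converged = True
            ll_prev = ll_c
            break
        ll_prev = ll_c
    # refresh the Hessian at the final coefficients
    p_fin = expit(A @ coef)
    Wd = w * p_fin * (1.0 - p_fin)
    H = (A * Wd[:, None]).T @ A
    H[np.diag_indices_from(H)] += pen + 1e-12
    return coef, ll_prev, converged, H


def fit_mixed_logit(X: np.ndarray, y: np.ndarray, terms: list[RandomTerm],
                    weights: np.ndarray | None = None,
                    beta_names: list[str] | None = None,
                    theta0: np.ndarray | None = None,
                    maxfev: int = 80, theta_tol: float = 1e-3,
                    ) -> MixedLogitResult:
    """Fit the weighted mixed logistic model.

    ``X`` must include the intercept column if one is wanted.  Returns the
    Laplace-ML fit with Wald standard errors for the fixed effects.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    Z, labels, var_fixed = _expand_random_design(terms, n)
    dim_u = Z.shape[1]
    A = np.hstack([X, Z])

    est_mask = ~np.isfinite(var_fixed)
    # map each estimated u-column to its shared variance parameter
    est_keys = []
    key_of_col = np.full(dim_u, -1, dtype=int)
    for j, lab in enumerate(labels):
        if est_mask[j]:
            if lab not in est_keys:
                est_keys.append(lab)
            key_of_col[j] = est_keys.index(lab)
    n_theta = len(est_keys)

    coef_warm = np.zeros(p + dim_u)
    state = {"coef": coef_warm}

    def lam_vector(theta):
        lam = var_fixed.copy()
        if n_theta:
            lam[est_mask] = np.exp(theta)[key_of_col[est_mask]]
        return lam

    def profile_negll(theta):
        lam = lam_vector(theta)
        pen = np.concatenate([np.zeros(p), 1.0 / np.maximum(lam, 1e-12)]) \
            if dim_u else np.zeros(p)
        coef, llp, conv, H = _newton_joint(A, y, w, pen, state["coef"])
        state["coef"] = coef
        state["H"] = H
        state["conv"] = conv
        if dim_u:
            Huu = H[p:, p:]
            sign, logdet_H = np.linalg.slogdet(Huu)
            if sign <= 0:
                return 1e10
            logdet_D = float(np.sum(np.log(np.maximum(lam, 1e-12))))
            logL = llp - 0.5 * (logdet_D + logdet_H)
        else:
            logL = llp
        state["logL"] = logL
        return -logL

    if n_theta:
        th0 = (np.full(n_theta, np.log(0.25)) if theta0 is None
               else np.asarray(theta0, dtype=float))
        res = minimize(profile_negll, th0, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": theta_tol,
                                "fatol": 1e-4})
        theta_hat = res.x
    else:
        theta_hat = np.zeros(0)
    neg = profile_negll(theta_hat)  # refresh state at the optimum
    logL = -neg

    coef = state["coef"]
    H = state["H"]
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    beta = coef[:p]
    beta_se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    # runaway coefficients indicate (quasi-)separation: the mode exists
    # only at infinity and Wald inference is meaningless
    if np.max(np.abs(beta)) > 50.0:
        state["conv"] = False

    lam = lam_vector(theta_hat)
    variances = {}
    for key in est_keys:
        tname, c = key
        term = next(t for t in terms if t.name == tname)
        cname = (term.col_names[c] if term.col_names else str(c))
        j = labels.index(key)
        variances[f"{tname}:{cname}"] = float(lam[j])
    for t in terms:
        for c in range(t.q):
            if np.isfinite(t.var_fixed[c]):
                cname = t.col_names[c] if t.col_names else str(c)
                variances[f"{t.name}:{cname}"] = float(t.var_fixed[c])

    ranef = {}
    off = p
    for t in terms:
        G, q = t.n_groups, t.q
        ranef[t.name] = coef[off:off + G * q].reshape(G, q)
        off += G * q

    return MixedLogitResult(
        beta=beta, beta_se=beta_se, beta_cov=cov[:p, :p],
        beta_names=beta_names or [f"x{j}" for j in range(p)],
        loglik=float(logL), variances=variances,
        converged=bool(state.get("conv", False)),
        n_obs=n, n_fixed=p, n_var_estimated=n_theta,
        random_effects=ranef)
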