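"""Maximum-likelihood linear mixed models with structured covariance.

Fits y = X b + sum_k u_k + e where each u_k is a vector of i.i.d. random
intercepts over the levels of a grouping factor (factors may be crossed),
and e may carry an AR-1 correlation within ordered blocks (e.g. censuses
within a tank-year).  Estimation is direct maximum likelihood over the
variance parameters with the fixed effects profiled out by GLS, which makes
full-vs-reduced likelihood-ratio tests (Type III drops) straightforward.

statsmodels' MixedLM covers crossed intercepts but not AR-1 residual
correlation, which the treatment-effect model needs; this fitter handles
both cases through one code path and is cross-checked against MixedLM on
the intercept-only case in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class LmmResult:
    beta: np.ndarray
    vcov_beta: np.ndarray
    loglik: float
    variances: dict  # variance component name -> sigma^2
    sigma2_resid: float
    rho: float | None  # AR-1 parameter, None if not modelled
    converged: bool
    n: int
    exog_names: list = field(default_factory=list)
    boundary: bool = False  # some variance pinned at (near) zero

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))


def _ar1_blocks(ar1_group: np.ndarray, time: np.ndarray) -> list[np.ndarray]:
    blocks = []
    for g in np.unique(ar1_group):
        idx = np.flatnonzero(ar1_group == g)
        blocks.append(idx[np.argsort(time[idx], kind="stable")])
    return blocks


def _build_V(
    n: int,
    Zs: list[np.ndarray],
    sig2: np.ndarray,
    sigma2_e: float,
    rho: float | None,
    blocks: list[np.ndarray] | None,
) -> np.ndarray:
    V = np.zeros((n, n))
    for Z, s2 in zip(Zs, sig2):
        V += s2 * (Z @ Z.T)
    if rho is None or blocks is None:
        V[np.diag_indices(n)] += sigma2_e
    else:
        for idx in blocks:
            m = len(idx)
            lagmat = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
            V[np.ix_(idx, idx)] += sigma2_e * rho**lagmat
    return V


def _neg_loglik(params, y, X, Zs, blocks, use_ar1):
    k = len(Zs)
    sig2 = np.exp(params[:k])
    sigma2_e = np.exp(params[k])
    rho = np.tanh(params[k + 1]) if use_ar1 else None
    n = len(y)
    V = _build_V(n, Zs, sig2, sigma2_e, rho, blocks)
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.log(np.diag(c)).sum()
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    except np.linalg.LinAlgError:
        return 1e10
    r = y - X @ beta
    quad = r @ np.linalg.solve(V, r)
    return 0.5 * (logdet + quad + n * np.log(2 * np.pi))


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    random_intercepts: dict[str, np.ndarray] | None = None,
    ar1_group: np.ndarray | None = None,
    time: np.ndarray | None = None,
    exog_names: list | None = None,
    maxiter: int = 400,
) -> LmmResult:
    """Fit by ML; random_intercepts maps factor name -> level labels per row."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)
    random_intercepts = random_intercepts or {}
    names = list(random_intercepts)
    Zs = []
    for name in names:
        labels = np.asarray(random_intercepts[name])
        levels, inv = np.unique(labels, return_inverse=True)
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), inv] = 1.0
        Zs.append(Z)
    use_ar1 = ar1_group is not None
    blocks = _ar1_blocks(np.asarray(ar1_group), np.asarray(time)) if use_ar1 else None

    var_y = max(float(np.var(y)), 1e-8)
    k = len(Zs)
    x0 = np.full(k + 1 + (1 if use_ar1 else 0), np.log(var_y / (k + 1)))
    if use_ar1:
        x0[-1] = 0.0
    bounds = [(-25.0, 25.0)] * (k + 1)
    if use_ar1:
        bounds.append((-5.0, 5.0))
    res = optimize.minimize(
        _neg_loglik, x0, args=(y, X, Zs, blocks, use_ar1),
        method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter},
    )
    # polish from a couple of alternative starts if the first fit stalls
    for start_scale in (0.1, 2.0):
        x1 = x0 + np.log(start_scale)
        r2 = optimize.minimize(
            _neg_loglik, x1, args=(y, X, Zs, blocks, use_ar1),
            method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter},
        )
        if r2.fun < res.fun - 1e-9:
            res = r2
    params = res.x
    sig2 = np.exp(params[:k])
    sigma2_e = float(np.exp(params[k]))
    rho = float(np.tanh(params[k + 1])) if use_ar1 else None
    V = _build_V(n, Zs, sig2, sigma2_e, rho, blocks)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ np.linalg.solve(V, y))
    vcov = np.linalg.inv(XtViX)
    return LmmResult(
        beta=beta,
        vcov_beta=vcov,
        loglik=-float(res.fun),
        variances=dict(zip(names, map(float, sig2))),
        sigma2_resid=sigma2_e,
        rho=rho,
        converged=bool(res.success),
        n=n,
        exog_names=exog_names or [f"x{j}" for j in range(X.shape[1])],
        boundary=bool((sig2 < 1e-8 * var_y).any()),
    )


def lr_test(full: LmmResult, reduced: LmmResult, df: int) -> tuple[float, float]:
    """Likelihood-ratio chi^2 and p for nested ML fits (clamped at 0)."""
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return chi2, float(stats.chi2.sf(chi2, df))
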