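"""Regularized multivariate S-map for time-varying per-capita interaction effects.

For each recipient with at least one accepted donor, a mixed embedding
{recipient lags, donor contemporaneous densities} predicts the recipient's
per-capita growth ln((N_{t+1}+1)/(N_t+1)).  At every target point a locally
weighted ridge regression is solved; the fitted coefficient of a donor
column is the per-capita interaction effect of that donor at that time,
an estimate of d(1/N_r * dN_r/dt)/dN_d on the standardized-density scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mesoweb.data_model import CompositeSeries, growth_by_fragment

THETA_GRID = (0, 0.1, 0.5, 1, 1.5, 2, 2.5, 3, 4, 6, 8)
LAMBDA_GRID = (0, 0.0001, 0.001, 0.01, 0.1, 0.5, 1, 2)


@dataclass
class SmapConfig:
    theta: float = 0.0
    lam: float = 0.0
    theta_grid: tuple = THETA_GRID
    lambda_grid: tuple = LAMBDA_GRID

    def __post_init__(self) -> None:
        if self.theta < 0 or self.lam < 0:
            raise ValueError("theta and lambda must be non-negative")


@dataclass
class MixedEmbedding:
    """Embedding columns = recipient lags then donor contemporaneous values."""

    recipient: str
    donors: list[str]
    n_recipient_lags: int
    X: np.ndarray  # (n, dim) standardized predictor block
    y: np.ndarray  # (n,) per-capita growth of the recipient at t -> t+1
    keys: list[tuple]  # (tank, treatment, year, census) at time t
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.columns:
            self.columns = [
                f"{self.recipient}_lag{j}" for j in range(self.n_recipient_lags)
            ] + list(self.donors)

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    @property
    def n(self) -> int:
        return len(self.y)

    def donor_column(self, donor: str) -> int:
        return self.n_recipient_lags + self.donors.index(donor)


def build_mixed_embedding(
    recipient: CompositeSeries,
    donors: dict[str, CompositeSeries],
    E: int,
) -> MixedEmbedding:
    """Substitute donor densities into the recipient's lagged embedding.

    The dimension is max(E, 1 + n_donors): donor columns replace the deepest
    recipient lags, but at least one recipient column (lag 0) is always
    kept.  Rows are valid only when every lag, every donor value and the
    t+1 growth response lie inside the same fragment.
    """
    if not donors:
        raise ValueError("no donors; link not S-mappable")
    donor_names = sorted(donors)
    dim = max(E, 1 + len(donor_names))
    n_lags = max(1, dim - len(donor_names))
    dim = n_lags + len(donor_names)

    growth = growth_by_fragment(recipient)
    donor_idx = {d: donors[d].key_index() for d in donor_names}
    rows, ys, keys = [], [], []
    for fid, f in enumerate(recipient.fragments):
        g = growth[fid]
        for j in range(n_lags - 1, len(f) - 1):  # t+1 response needs j+1 in fragment
            key_t = (f.tank_id, f.treatment, f.year, int(f.censuses[j]))
            dvals = []
            ok = True
            for d in donor_names:
                pos = donor_idx[d].get(key_t, -1)
                if pos < 0:
                    ok = False
                    break
                dvals.append(donors[d].values[pos])
            if not ok:
                continue
            lags = recipient.values[f.start + j - np.arange(n_lags)]
            rows.append(np.concatenate([lags, dvals]))
            ys.append(g[j])
            keys.append(key_t)
    if not rows:
        raise ValueError("no valid rows for mixed embedding")
    return MixedEmbedding(
        recipient=recipient.taxon,
        donors=donor_names,
        n_recipient_lags=n_lags,
        X=np.array(rows),
        y=np.array(ys),
        keys=keys,
    )


def _distance_matrix(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def _weight_matrix(D: np.ndarray, theta: float, loocv: bool) -> np.ndarray:
    """W[t, i] = exp(-theta * d_ti / mean_i'!=t d_ti'); self row excluded under LOOCV."""
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    dbar = (D * off).sum(1) / (n - 1)
    if np.any(dbar == 0):
        raise ValueError("degenerate embedding: zero mean neighbour distance")
    W = np.exp(-theta * D / dbar[:, None])
    if loocv:
        np.fill_diagonal(W, 0.0)
    return W


def regularized_smap(
    embed: MixedEmbedding,
    theta: float,
    lam: float,
    loocv: bool = True,
    D: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Locally weighted ridge regression at every embedded point.

    Returns (coefficients (n, dim), intercepts (n,), rmse).  For target row
    t the weights are w_i = exp(-theta * d_i / dbar_t) with dbar_t the mean
    distance from t to the other rows; the solve minimizes
    sum_i w_i (y_i - b0 - b.x_i)^2 + lam * ||b||^2 with an unpenalized
    intercept.  Under LOOCV (the default, used for both tuning and the
    reported coefficients) the target row is excluded from its own fit.
    """
    n, d = embed.X.shape
    if n < d + 2:
        raise ValueError("too few valid rows for the embedding dimension")
    if D is None:
        D = _distance_matrix(embed.X)
    W = _weight_matrix(D, theta, loocv)
    X1 = np.column_stack([np.ones(n), embed.X])
    # batched normal equations: A[t] = X1' diag(W[t]) X1 (+ lam on slopes)
    A = np.einsum("tn,ni,nj->tij", W, X1, X1)
    rhs = np.einsum("tn,ni,n->ti", W, X1, embed.y)
    pen = np.zeros((d + 1, d + 1))
    pen[1:, 1:] = np.eye(d)
    A = A + lam * pen
    try:
        B = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as exc:
        bad = [t for t in range(n) if np.linalg.matrix_rank(A[t]) < d + 1]
        raise ValueError(
            f"singular weighted system at lambda={lam} (rows {bad[:5]}...)"
        ) from exc
    preds = np.einsum("ti,ti->t", X1, B)
    rmse = float(np.sqrt(np.mean((preds - embed.y) ** 2)))
    return B[:, 1:], B[:, 0], rmse


def tune_smap(
    embed: MixedEmbedding,
    theta_grid: tuple = THETA_GRID,
    lambda_grid: tuple = LAMBDA_GRID,
    loocv: bool = True,
) -> tuple[SmapConfig, pd.DataFrame]:
    """Grid search over (theta, lambda) minimizing LOOCV RMSE.

    Ties break toward smaller lambda, then smaller theta.  The full RMSE
    surface is returned alongside the chosen configuration.
    """
    D = _distance_matrix(embed.X)
    rows = []
    best = None
    for theta in theta_grid:
        for lam in lambda_grid:
            try:
                _, _, rmse = regularized_smap(embed, theta, lam, loocv=loocv, D=D)
            except ValueError:
                rmse = np.inf
            rows.append((theta, lam, rmse))
            cand = (rmse, lam, theta)
            if best is None or cand < best:
                best = cand
    surface = pd.DataFrame(rows, columns=["theta", "lambda", "rmse"])
    cfg = SmapConfig(theta=best[2], lam=best[1],
                     theta_grid=tuple(theta_grid), lambda_grid=tuple(lambda_grid))
    return cfg, surface


def interaction_timeseries(
    accepted_links: list[tuple[str, str]],
    composites: dict[str, CompositeSeries],
    E_map: dict[str, int],
    theta_grid: tuple = THETA_GRID,
    lambda_grid: tuple = LAMBDA_GRID,
    loocv: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-link S-map coefficient series over (tank, treatment, year, census).

    One model is fitted per recipient (all its accepted donors enter the
    same mixed embedding); each donor's coefficient series is read off that
    single model.  Returns a tidy frame with columns donor, recipient,
    tank, treatment, year, census, coefficient, plus per-recipient chosen
    (theta, lambda, rmse) metadata.
    """
    donors_of: dict[str, list[str]] = {}
    for donor, recipient in accepted_links:
        donors_of.setdefault(recipient, []).append(donor)
    rows = []
    meta = {}
    for recipient, donor_names in sorted(donors_of.items()):
        embed = build_mixed_embedding(
            composites[recipient],
            {d: composites[d] for d in donor_names},
            E_map[recipient],
        )
        cfg, surface = tune_smap(embed, theta_grid, lambda_grid, loocv=loocv)
        coefs, _, rmse = regularized_smap(embed, cfg.theta, cfg.lam, loocv=loocv)
        meta[recipient] = {
            "theta": cfg.theta, "lambda": cfg.lam, "rmse": rmse,
            "dim": embed.dim, "n_rows": embed.n,
        }
        for d in embed.donors:
            col = embed.donor_column(d)
            for (tank, treat, year, census), c in zip(embed.keys, coefs[:, col]):
                rows.append((d, recipient, tank, treat, year, census, float(c)))
    frame = pd.DataFrame(
        rows,
        columns=["donor", "recipient", "tank", "treatment", "year", "census",
                 "coefficient"],
    )
    return frame, meta
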