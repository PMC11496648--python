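"""Convergent cross mapping with a three-criterion acceptance cascade.

A directed link donor -> recipient is accepted when (1) cross-map skill of
the recipient's manifold predicting the donor converges with library length
(delta rho > 0.1), (2) the skill at full library beats a seasonal-surrogate
null (alpha = 0.05; 0.05 < p < 0.1 kept as "marginal"), and (3) lagged cross
mapping peaks at a non-positive donor lag.  Criteria run in that order and
short-circuit: a pair failing convergence never spends surrogate effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mesoweb.data_model import CompositeSeries
from mesoweb.state_space import build_lagged_block, _pairwise_dist

DELTA_RHO_THRESHOLD = 0.1
ALPHA = 0.05
MARGINAL_P = 0.1


@dataclass
class SurrogateSet:
    """Seasonal surrogates: cyclic (census-position) mean preserved exactly,
    anomalies permuted over the whole composite."""

    taxon: str
    values: np.ndarray  # (len(composite), n_surrogates)
    seed: int
    cycle: int = 10


@dataclass
class CCMResult:
    donor: str
    recipient: str
    E: int
    L_min: int
    L_max: int
    rho_min: float = np.nan
    rho_min_sd: float = np.nan
    rho_max: float = np.nan
    delta_rho: float = np.nan
    surrogate_p: float = np.nan
    optimal_lag: int | None = None
    lag_profile: dict = field(default_factory=dict)
    decision: str = "reject"
    failed_criterion: int | None = None  # 1, 2 or 3; None if accepted

    @property
    def accepted(self) -> bool:
        return self.decision in ("accept", "marginal")


class CrossMapContext:
    """Recipient-side geometry shared by every donor, lag and surrogate.

    The neighbour search depends only on the recipient's delay embedding,
    so the pairwise distance matrix (predictee excluded from its own
    neighbours) is computed once per (recipient, E).
    """

    def __init__(self, recipient: CompositeSeries, E: int):
        self.recipient = recipient
        self.E = E
        self.block = build_lagged_block(recipient, E, tp=0)
        self.D = _pairwise_dist(self.block.vectors)
        np.fill_diagonal(self.D, np.inf)
        self.keys = self.block.keys

    @property
    def n_rows(self) -> int:
        return self.block.n

    def target_index(self, donor: CompositeSeries, lag: int = 0) -> np.ndarray:
        """Composite position of the donor value at each row's time t+lag.

        -1 marks rows whose (tank, year, census+lag) does not exist in the
        donor composite (fragment boundary or missing census).
        """
        kidx = donor.key_index()
        out = np.empty(len(self.keys), dtype=int)
        for i, (tank, treat, year, census) in enumerate(self.keys):
            out[i] = kidx.get((tank, treat, year, census + lag), -1)
        return out


def _neighbour_rhos(
    D: np.ndarray, targets: np.ndarray, k: int, libs: list[np.ndarray]
) -> np.ndarray:
    """Cross-map skill for each library subset.

    For every predictee row, its k nearest library rows (self excluded via
    the inf diagonal) forecast the target with weights exp(-d/d_min); rows
    at zero distance (exact duplicates) take over with unit weights.
    """
    n = D.shape[0]
    rhos = np.empty(len(libs))
    for li, idx in enumerate(libs):
        Dsub = D[:, idx]
        kk = min(k, idx.size)
        order = np.argsort(Dsub, axis=1, kind="stable")[:, :kk]
        dn = np.take_along_axis(Dsub, order, axis=1)
        nb = idx[order]
        d1 = dn[:, :1]
        with np.errstate(invalid="ignore", over="ignore"):
            w = np.exp(-dn / d1)
        dup = d1[:, 0] == 0.0
        if dup.any():
            w[dup] = (dn[dup] == 0.0).astype(float)
        w[~np.isfinite(dn)] = 0.0
        tv = targets[nb]
        pred = (w * tv).sum(1) / w.sum(1)
        rhos[li] = _pearson(pred, targets)
    return rhos


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cross_map(
    library: CompositeSeries | CrossMapContext,
    target: CompositeSeries,
    E: int | None = None,
    L: int | None = None,
    n_samples: int = 1,
    seed: int | None = None,
    lag: int = 0,
) -> np.ndarray:
    """rho per random library draw for recipient-manifold -> donor prediction.

    ``library`` is the affected (recipient) variable whose manifold is used;
    ``target`` is the putative cause being predicted.  Each draw samples L
    embedded rows without replacement; predictions cover all valid rows.
    """
    ctx = library if isinstance(library, CrossMapContext) else CrossMapContext(library, E)
    tgt_idx = ctx.target_index(target, lag=lag)
    valid = np.flatnonzero(tgt_idx >= 0)
    if valid.size == 0:
        raise ValueError("no rows with a valid target at this lag")
    D = ctx.D[np.ix_(valid, valid)]
    targets = target.values[tgt_idx[valid]]
    n = valid.size
    if L is None:
        L = n
    if L > n:
        raise ValueError(f"library length {L} exceeds available rows {n}")
    k = ctx.E + 1
    if L == n:
        rho = _neighbour_rhos(D, targets, k, [np.arange(n)])
        return np.repeat(rho, n_samples)
    rng = np.random.default_rng(seed)
    libs = [rng.choice(n, size=L, replace=False) for _ in range(n_samples)]
    return _neighbour_rhos(D, targets, k, libs)


def ccm_convergence(
    donor: CompositeSeries,
    recipient: CompositeSeries,
    E: int,
    n_samples: int = 1000,
    seed: int | None = None,
    context: CrossMapContext | None = None,
) -> CCMResult:
    """Criterion 1: convergence of cross-map skill with library length."""
    ctx = context or CrossMapContext(recipient, E)
    tgt_idx = ctx.target_index(donor)
    n_valid = int((tgt_idx >= 0).sum())
    L_min = E + 1
    L_max = n_valid
    rho_min_draws = cross_map(ctx, donor, L=L_min, n_samples=n_samples, seed=seed)
    rho_max_draws = cross_map(ctx, donor, L=L_max, n_samples=1)
    res = CCMResult(
        donor=donor.taxon,
        recipient=recipient.taxon,
        E=E,
        L_min=L_min,
        L_max=L_max,
        rho_min=float(rho_min_draws.mean()),
        rho_min_sd=float(rho_min_draws.std(ddof=1)) if n_samples > 1 else 0.0,
        rho_max=float(rho_max_draws.mean()),
    )
    res.delta_rho = res.rho_max - res.rho_min
    return res


def seasonal_surrogate(
    series: CompositeSeries, cycle: int = 10, n: int = 1000, seed: int | None = None
) -> SurrogateSet:
    """Null series preserving the cyclic mean, shuffling anomalies.

    The 24 fragments are treated as one consecutive series with a
    ``cycle``-point season; the mean at each census position (computed over
    available observations, so 9-point fragments are handled) is kept
    exactly, and the anomalies are permuted uniformly over the whole
    composite.
    """
    positions = np.array([census - 1 for (_, _, _, census) in series.keys()]) % cycle
    profile = np.array(
        [series.values[positions == p].mean() if (positions == p).any() else 0.0
         for p in range(cycle)]
    )
    anomalies = series.values - profile[positions]
    rng = np.random.default_rng(seed)
    m = len(series.values)
    surr = np.empty((m, n))
    base = profile[positions]
    pos_idx = [np.flatnonzero(positions == p) for p in range(cycle)]
    for j in range(n):
        a = np.empty(m)
        # anomalies permute within each census position, so every surrogate
        # keeps the empirical cyclic mean profile exactly while losing the
        # cross-fragment alignment that carries any causal signal
        for idx in pos_idx:
            a[idx] = anomalies[rng.permutation(idx)]
        surr[:, j] = base + a
    return SurrogateSet(taxon=series.taxon, values=surr, seed=seed, cycle=cycle)


def surrogate_test(
    observed_rho: float,
    surrogates: SurrogateSet,
    recipient: CompositeSeries | CrossMapContext,
    donor: CompositeSeries,
    E: int | None = None,
) -> tuple[float, np.ndarray]:
    """Criterion 2: one-sided p against the seasonal-surrogate null.

    The recipient manifold is kept intact; the putative-cause series is
    replaced by each surrogate, cross-mapped at the full library, and
    p = (1 + #{null >= observed}) / (1 + n).
    """
    ctx = recipient if isinstance(recipient, CrossMapContext) else CrossMapContext(recipient, E)
    tgt_idx = ctx.target_index(donor)
    valid = np.flatnonzero(tgt_idx >= 0)
    D = ctx.D[np.ix_(valid, valid)]
    k = ctx.E + 1
    n = valid.size
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    dn = np.take_along_axis(D, order, axis=1)
    d1 = dn[:, :1]
    with np.errstate(invalid="ignore", over="ignore"):
        w = np.exp(-dn / d1)
    dup = d1[:, 0] == 0.0
    if dup.any():
        w[dup] = (dn[dup] == 0.0).astype(float)
    w[~np.isfinite(dn)] = 0.0
    w = w / w.sum(1, keepdims=True)
    pos = tgt_idx[valid]
    S = surrogates.values[pos, :]  # (n, m) null target values
    S_nb = surrogates.values[pos[order], :]  # (n, k, m)
    preds = np.einsum("nk,nkm->nm", w, S_nb)
    pc = preds - preds.mean(0)
    sc = S - S.mean(0)
    denom = np.sqrt((pc**2).sum(0) * (sc**2).sum(0))
    with np.errstate(invalid="ignore", divide="ignore"):
        null = np.where(denom > 0, (pc * sc).sum(0) / denom, 0.0)
    m = null.size
    p = (1.0 + np.sum(null >= observed_rho)) / (1.0 + m)
    return float(p), null


def lagged_ccm(
    donor: CompositeSeries,
    recipient: CompositeSeries,
    E: int | None = None,
    lags: tuple = (-2, -1, 0, 1, 2),
    n_samples: int = 100,
    seed: int | None = None,
    context: CrossMapContext | None = None,
) -> tuple[int, dict]:
    """Criterion 3: mean cross-map skill per donor lag; argmax must be <= 0.

    The donor is predicted at time t+lag from the recipient manifold at t;
    rows whose lagged target leaves the fragment are masked.  Ties are
    broken toward smaller |lag|, then the more negative lag.
    """
    ctx = context or CrossMapContext(recipient, E)
    profile: dict[int, float] = {}
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(lags))
    for lag, cs in zip(lags, child):
        tgt_idx = ctx.target_index(donor, lag=lag)
        n_valid = int((tgt_idx >= 0).sum())
        if n_valid < ctx.E + 2:
            profile[lag] = np.nan
            continue
        rhos = cross_map(
            ctx, donor, L=n_valid, n_samples=n_samples,
            seed=int(cs.generate_state(1)[0] % 2**31), lag=lag,
        )
        profile[lag] = float(rhos.mean())
    return best_lag(profile), profile


def best_lag(profile: dict[int, float]) -> int:
    """Argmax of the lag profile; ties prefer smaller |lag|, then the more
    negative lag.  NaN entries (fully masked lags) are excluded."""
    finite = {l: r for l, r in profile.items() if np.isfinite(r)}
    if not finite:
        raise ValueError("all lags masked")
    return max(finite, key=lambda l: (finite[l], -abs(l), -l))


def detect_links(
    composites: dict[str, CompositeSeries],
    E_map: dict[str, int],
    n_samples: int = 1000,
    n_surrogates: int = 1000,
    lag_samples: int = 100,
    alpha: float = ALPHA,
    marginal_p: float = MARGINAL_P,
    delta_rho_threshold: float = DELTA_RHO_THRESHOLD,
    cycle: int = 10,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame, list[CCMResult]]:
    """Evaluate all ordered taxon pairs through the three-criterion cascade.

    Returns accepted (incl. marginal) directed links, a tidy results table
    and the full per-pair results.  Surrogate sets are built lazily per
    donor, only when some pair involving that donor survives criterion 1.
    """
    taxa = sorted(composites)
    ss = np.random.SeedSequence(seed)
    surrogate_cache: dict[str, SurrogateSet] = {}
    contexts = {t: CrossMapContext(composites[t], E_map[t]) for t in taxa}
    results: list[CCMResult] = []
    pair_seeds = ss.spawn(len(taxa) * (len(taxa) - 1) + len(taxa))
    surr_seeds = {t: int(s.generate_state(1)[0] % 2**31)
                  for t, s in zip(taxa, pair_seeds[-len(taxa):])}
    i = 0
    for donor in taxa:
        for recipient in taxa:
            if donor == recipient:
                continue
            cs = pair_seeds[i]
            i += 1
            s1, s3 = (int(x.generate_state(1)[0] % 2**31) for x in cs.spawn(2))
            ctx = contexts[recipient]
            res = ccm_convergence(
                composites[donor], composites[recipient], E_map[recipient],
                n_samples=n_samples, seed=s1, context=ctx,
            )
            if not (res.delta_rho > delta_rho_threshold):
                res.decision, res.failed_criterion = "reject", 1
                results.append(res)
                continue
            if donor not in surrogate_cache:
                surrogate_cache[donor] = seasonal_surrogate(
                    composites[donor], cycle=cycle, n=n_surrogates,
                    seed=surr_seeds[donor],
                )
            p, _ = surrogate_test(
                res.rho_max, surrogate_cache[donor], ctx, composites[donor]
            )
            res.surrogate_p = p
            if p >= marginal_p:
                res.decision, res.failed_criterion = "reject", 2
                results.append(res)
                continue
            best, profile = lagged_ccm(
                composites[donor], composites[recipient],
                n_samples=lag_samples, seed=s3, context=ctx,
            )
            res.optimal_lag, res.lag_profile = best, profile
            if best > 0:
                res.decision, res.failed_criterion = "reject", 3
            else:
                res.decision = "accept" if p < alpha else "marginal"
            results.append(res)
    accepted = [(r.donor, r.recipient) for r in results if r.accepted]
    table = pd.DataFrame(
        [
            {
                "donor": r.donor, "recipient": r.recipient, "E": r.E,
                "Lmin": r.L_min, "Lmax": r.L_max, "rho_min": r.rho_min,
                "rho_max": r.rho_max, "delta_rho": r.delta_rho,
                "p_surrogate": r.surrogate_p, "opt_lag": r.optimal_lag,
                "decision": r.decision, "failed_criterion": r.failed_criterion,
            }
            for r in results
        ]
    )
    return accepted, table, results
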