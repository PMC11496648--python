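"""Time-delay embedding over fragmented composites and simplex projection.

A composite series is a concatenation of short fragments; an embedded point
is valid only when every lag (and the prediction target) falls inside the
same fragment.  Simplex projection forecasts each point from its E+1 nearest
neighbours in lag space with exponentially decaying weights, and the
embedding dimension is chosen by leave-one-out cross-validated skill over a
scan of E.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mesoweb.data_model import CompositeSeries


@dataclass
class EmbeddingConfig:
    E: int
    tau: int = 1
    exclusion: str = "self"  # LOOCV neighbour exclusion rule; no Theiler window

    def __post_init__(self) -> None:
        if self.E < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.tau != 1:
            raise ValueError("only tau = 1 is supported")


@dataclass
class LaggedBlock:
    """Delay-embedded rows with within-fragment validity.

    vectors[i] = (x_t, x_{t-1}, ..., x_{t-E+1}) for the i-th valid point;
    targets[i] is the value to predict (x_{t+tp} by default).  point_ids
    give (fragment_id, position-within-fragment) of time t; keys give the
    (tank, treatment, year, census) of time t.
    """

    E: int
    vectors: np.ndarray  # (n, E)
    targets: np.ndarray  # (n,)
    point_ids: list[tuple[int, int]]
    keys: list[tuple]
    tp: int = 1

    @property
    def n(self) -> int:
        return len(self.targets)


@dataclass
class ForecastSkill:
    rho: float
    mae: float
    rmse: float
    n_predictions: int


def _skill(pred: np.ndarray, obs: np.ndarray) -> ForecastSkill:
    err = pred - obs
    if np.std(pred) == 0 or np.std(obs) == 0:
        rho = 0.0
    else:
        rho = float(np.corrcoef(pred, obs)[0, 1])
    return ForecastSkill(
        rho=rho,
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        n_predictions=len(obs),
    )


def build_lagged_block(
    series: CompositeSeries,
    E: int,
    tp: int = 1,
    target_series: CompositeSeries | None = None,
    target_by_fragment: list[np.ndarray] | None = None,
) -> LaggedBlock:
    """Embed a composite, keeping only rows fully inside one fragment.

    By default the target is the series' own value tp steps ahead.  With
    ``target_series`` the target is another composite's value at t+tp,
    matched by (tank, year, census) key; rows whose target key does not
    exist are dropped.  With ``target_by_fragment`` the target is an
    arbitrary per-fragment vector indexed at the position of time t (used
    for per-capita growth responses).
    """
    shortest = min(len(f) for f in series.fragments)
    if E >= shortest:
        raise ValueError(
            f"fragment too short to embed: E={E} exceeds shortest fragment "
            f"length {shortest}"
        )
    tkidx = target_series.key_index() if target_series is not None else None
    tkeys = target_series.keys() if target_series is not None else None

    vecs, targs, pids, keys = [], [], [], []
    for fid, f in enumerate(series.fragments):
        L = len(f)
        for j in range(E - 1, L):
            # lags x_t .. x_{t-E+1} all inside this fragment by construction
            if target_by_fragment is not None:
                tvec = target_by_fragment[fid]
                if j >= len(tvec):
                    continue
                y = tvec[j]
            elif target_series is not None:
                key = (f.tank_id, f.treatment, f.year, int(f.censuses[j]) + tp)
                if key not in tkidx:
                    continue
                y = target_series.values[tkidx[key]]
            else:
                if j + tp >= L or j + tp < 0:
                    continue
                y = series.values[f.start + j + tp]
            vecs.append(series.values[f.start + j - np.arange(E)])
            targs.append(y)
            pids.append((fid, j))
            keys.append((f.tank_id, f.treatment, f.year, int(f.censuses[j])))
    if not vecs:
        raise ValueError("no valid embedded rows")
    return LaggedBlock(
        E=E,
        vectors=np.array(vecs),
        targets=np.array(targs, dtype=float),
        point_ids=pids,
        keys=keys,
        tp=tp,
    )


def simplex_weights(
    dist: np.ndarray, lib_idx: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour indices and simplex weights for one predictee.

    ``dist`` holds distances from the predictee to every candidate row
    (with np.inf at excluded rows); ``lib_idx`` are the candidate row
    indices.  Zero-distance (exact duplicate) neighbours, when present,
    take over with unit weights; otherwise weights are exp(-d/d_min) over
    the k nearest.  Ties are broken by candidate order, which callers keep
    stable by (fragment_id, position).
    """
    d = dist[lib_idx]
    finite = np.isfinite(d)
    if finite.sum() < 1:
        raise ValueError("no neighbours available")
    order = np.argsort(d, kind="stable")[:k]
    dn = d[order]
    if dn[0] == 0.0:
        zero = order[dn == 0.0]
        return lib_idx[zero], np.ones(len(zero))
    w = np.exp(-dn / dn[0])
    return lib_idx[order], w


def _pairwise_dist(vectors: np.ndarray) -> np.ndarray:
    diff = vectors[:, None, :] - vectors[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def simplex_forecast(
    block: LaggedBlock, loocv: bool = True
) -> tuple[np.ndarray, ForecastSkill]:
    """Forecast every valid row from its E+1 nearest neighbours.

    Under LOOCV the predictee row itself is excluded from its neighbour
    set (exact duplicates of it remain and are handled by the
    zero-distance rule).  Without LOOCV the row may select itself, which
    makes the in-sample forecast trivially exact at duplicated states;
    that mode exists for diagnostics only.
    """
    n = block.n
    k = block.E + 1
    if n < k + 1:
        raise ValueError(f"need at least E+2={k + 1} valid rows, have {n}")
    D = _pairwise_dist(block.vectors)
    if loocv:
        np.fill_diagonal(D, np.inf)
    all_idx = np.arange(n)
    preds = np.empty(n)
    for i in range(n):
        nb, w = simplex_weights(D[i], all_idx, k)
        preds[i] = np.dot(w, block.targets[nb]) / w.sum()
    return preds, _skill(preds, block.targets)


def select_embedding_dimension(
    series: CompositeSeries,
    Emin: int = 2,
    Emax: int = 6,
    criterion: str = "rmse",
    tp: int = 1,
) -> tuple[int, pd.DataFrame]:
    """Scan E in [Emin, Emax] with LOOCV simplex skill; pick the best E.

    Returns the chosen E and the full skill table (one row per E with rho,
    mae, rmse and a ``consistent`` flag marking whether the three criteria
    agree on the winner).  The default criterion is minimum RMSE.
    """
    rows = []
    for E in range(Emin, Emax + 1):
        block = build_lagged_block(series, E, tp=tp)
        _, sk = simplex_forecast(block, loocv=True)
        rows.append((E, sk.rho, sk.mae, sk.rmse, sk.n_predictions))
    table = pd.DataFrame(rows, columns=["E", "rho", "mae", "rmse", "n"])
    winners = {
        "rho": int(table.loc[table["rho"].idxmax(), "E"]),
        "mae": int(table.loc[table["mae"].idxmin(), "E"]),
        "rmse": int(table.loc[table["rmse"].idxmin(), "E"]),
    }
    table.attrs["winners"] = winners
    table.attrs["consistent"] = len(set(winners.values())) == 1
    if criterion not in winners:
        raise ValueError(f"unknown criterion {criterion!r}")
    return winners[criterion], table
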