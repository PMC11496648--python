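import numpy as np
import pytest

from mesoweb.data_model import preprocess
from mesoweb.smap import (
    MixedEmbedding,
    build_mixed_embedding,
    interaction_timeseries,
    regularized_smap,
    tune_smap,
)
from tests.conftest import panel_from_series


def make_embedding(rng, n=120, dim=3, beta=None, noise=0.01):
    X = rng.standard_normal((n, dim))
    beta = np.asarray(beta) if beta is not None else rng.standard_normal(dim)
    y = X @ beta + noise * rng.standard_normal(n)
    return MixedEmbedding(
        recipient="r", donors=[f"d{j}" for j in range(dim - 1)],
        n_recipient_lags=1, X=X, y=y,
        keys=[("C1", "C", 1, j) for j in range(n)],
    )


def smap_oracle(X, y, theta, lam, loocv=True):
    """Brute-force locally weighted ridge: explicit loops and normal equations."""
    n, d = X.shape
    coefs = np.empty((n, d))
    icept = np.empty(n)
    for t in range(n):
        dist = np.sqrt(((X - X[t]) ** 2).sum(1))
        dbar = dist[np.arange(n) != t].mean()
        w = np.exp(-theta * dist / dbar)
        if loocv:
            w[t] = 0.0
        X1 = np.column_stack([np.ones(n), X])
        A = X1.T @ np.diag(w) @ X1
        A[1:, 1:] += lam * np.eye(d)
        b = np.linalg.solve(A, X1.T @ (w * y))
        icept[t], coefs[t] = b[0], b[1:]
    return coefs, icept


class TestMixedEmbedding:
    def _composites(self):
        rng = np.random.default_rng(5)
        series = {t: rng.uniform(1, 9, 240) for t in
                  ["rec", "d1", "d2", "d3", "d4"]}
        return preprocess(panel_from_series(series), ln_exempt=())

    def test_three_donors_at_E5_keeps_two_lags(self):
        comps = self._composites()
        emb = build_mixed_embedding(
            comps["rec"], {d: comps[d] for d in ["d1", "d2", "d3"]}, E=5)
        assert emb.columns == ["rec_lag0", "rec_lag1", "d1", "d2", "d3"]
        assert emb.dim == 5

    def test_four_donors_at_E2_expands_to_dim5(self):
        comps = self._composites()
        emb = build_mixed_embedding(
            comps["rec"], {d: comps[d] for d in ["d1", "d2", "d3", "d4"]}, E=2)
        assert emb.columns == ["rec_lag0", "d1", "d2", "d3", "d4"]

    def test_single_donor_at_E3(self):
        comps = self._composites()
        emb = build_mixed_embedding(comps["rec"], {"d1": comps["d1"]}, E=3)
        assert emb.columns == ["rec_lag0", "rec_lag1", "d1"]

    def test_no_donor_rejected(self):
        comps = self._composites()
        with pytest.raises(ValueError, match="no donors"):
            build_mixed_embedding(comps["rec"], {}, E=3)

    def test_rows_respect_fragments(self):
        comps = self._composites()
        emb = build_mixed_embedding(comps["rec"], {"d1": comps["d1"]}, E=3)
        # 2 recipient lags + t+1 response: 10 - 2 rows per 10-point fragment
        assert emb.n == 24 * 8


class TestRegularizedSmap:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(40, 200))
            dim = int(rng.integers(2, 6))
            emb = make_embedding(rng, n=n, dim=dim, noise=0.3)
            theta = float(rng.uniform(0, 6))
            lam = float(rng.choice([0.0, 0.01, 0.5]))
            coefs, icept, _ = regularized_smap(emb, theta, lam)
            oc, oi = smap_oracle(emb.X, emb.y, theta, lam)
            assert np.allclose(coefs, oc, atol=1e-8)
            assert np.allclose(icept, oi, atol=1e-8)

    def test_theta_zero_lambda_zero_is_global_ols(self, rng):
        emb = make_embedding(rng, n=80, dim=3, noise=0.5)
        coefs, icept, _ = regularized_smap(emb, 0.0, 0.0, loocv=False)
        X1 = np.column_stack([np.ones(emb.n), emb.X])
        beta, *_ = np.linalg.lstsq(X1, emb.y, rcond=None)
        assert np.allclose(coefs, beta[1:], atol=1e-9)
        assert np.allclose(icept, beta[0], atol=1e-9)

    def test_huge_lambda_shrinks_slopes_to_zero(self, rng):
        emb = make_embedding(rng, n=80, dim=3)
        coefs, icept, _ = regularized_smap(emb, 0.0, 1e9, loocv=False)
        assert np.max(np.abs(coefs)) < 1e-5
        assert np.allclose(icept, emb.y.mean(), atol=1e-4)

    def test_linear_system_recovery(self, rng):
        emb = make_embedding(rng, n=150, dim=2, beta=[2.0, -1.0], noise=0.01)
        coefs, _, _ = regularized_smap(emb, 1.0, 0.001)
        assert np.max(np.abs(coefs - np.array([2.0, -1.0]))) < 0.05

    def test_coefficients_invariant_to_row_permutation(self, rng):
        emb = make_embedding(rng, n=60, dim=3, noise=0.2)
        coefs, _, _ = regularized_smap(emb, 2.0, 0.01)
        perm = rng.permutation(emb.n)
        emb2 = MixedEmbedding(
            recipient="r", donors=emb.donors, n_recipient_lags=1,
            X=emb.X[perm], y=emb.y[perm], keys=[emb.keys[i] for i in perm],
        )
        coefs2, _, _ = regularized_smap(emb2, 2.0, 0.01)
        assert np.allclose(coefs2, coefs[perm], atol=1e-10)

    def test_constant_donor_column_shrinks_under_ridge(self, rng):
        emb = make_embedding(rng, n=100, dim=3, noise=0.1)
        emb.X[:, 2] = 0.0
        coefs, _, _ = regularized_smap(emb, 0.5, 0.1)
        assert np.max(np.abs(coefs[:, 2])) < 1e-8


class TestTuneSmap:
    def test_full_surface_returned_with_tie_break(self, rng):
        emb = make_embedding(rng, n=60, dim=2, noise=0.2)
        emb.y = np.zeros(emb.n)  # degenerate: every config fits perfectly
        cfg, surface = tune_smap(emb)
        assert len(surface) == 11 * 8
        assert (cfg.theta, cfg.lam) == (0, 0)

    def test_linear_dynamics_prefer_small_theta(self, rng):
        emb = make_embedding(rng, n=200, dim=3, noise=0.3)
        cfg, _ = tune_smap(emb)
        assert cfg.theta <= 1.0

    def test_state_dependent_dynamics_prefer_positive_theta(self, rng):
        n = 240
        X = rng.standard_normal((n, 2))
        # strongly state-dependent slope on x2
        y = (1.5 * np.tanh(2 * X[:, 0])) * X[:, 1] + 0.05 * rng.standard_normal(n)
        emb = MixedEmbedding("r", ["d"], 1, X, y,
                             [("C1", "C", 1, j) for j in range(n)])
        cfg, _ = tune_smap(emb)
        assert cfg.theta > 0


class TestInteractionSeries:
    def test_only_accepted_links_get_series(self, synthetic_run):
        comps = synthetic_run["composites"]
        E = synthetic_run["E_map"]
        links = [("phytoplankton", "rotifers"), ("phyt_pred", "rotifers")]
        series, meta = interaction_timeseries(links, comps, E)
        assert set(zip(series.donor, series.recipient)) == set(links)
        assert set(meta) == {"rotifers"}
        # one recipient model: both donors share (theta, lambda)
        assert {"theta", "lambda", "rmse"} <= set(meta["rotifers"])

    def test_series_keys_cover_all_tanks_years(self, synthetic_run):
        comps = synthetic_run["composites"]
        series, _ = interaction_timeseries(
            [("macrophytes", "herbivores")], comps, synthetic_run["E_map"])
        assert set(series.treatment) == {"C", "I", "H", "IH"}
        assert set(series.year) == {1, 2, 3}
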