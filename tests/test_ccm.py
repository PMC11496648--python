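import numpy as np
import pytest

import mesoweb.ccm as ccm_mod
from mesoweb.ccm import (
    CrossMapContext,
    best_lag,
    ccm_convergence,
    cross_map,
    detect_links,
    lagged_ccm,
    seasonal_surrogate,
    surrogate_test,
)
from mesoweb.data_model import preprocess
from tests.conftest import panel_from_series


def fold(values):
    panel = panel_from_series({"t": np.asarray(values)})
    return preprocess(panel, ln_exempt=("t",))["t"]


class TestSeasonalSurrogates:
    def test_cyclic_mean_preserved_and_anomalies_permuted(self, synthetic_run):
        comp = synthetic_run["composites"]["rotifers"]
        surr = seasonal_surrogate(comp, n=200, seed=9)
        positions = np.array([c - 1 for (_, _, _, c) in comp.keys()]) % 10
        orig_anom = np.sort(
            comp.values
            - np.array([comp.values[positions == p].mean() for p in range(10)])[positions]
        )
        for j in range(surr.values.shape[1]):
            s = surr.values[:, j]
            for p in range(10):
                assert abs(s[positions == p].mean()
                           - comp.values[positions == p].mean()) < 1e-10
            s_anom = s - np.array(
                [s[positions == p].mean() for p in range(10)]
            )[positions]
            assert np.allclose(np.sort(s_anom), orig_anom, atol=1e-10)

    def test_zero_anomaly_series_is_fixed_point(self):
        base = np.tile(np.arange(10, dtype=float) + 1, 24)
        comp = fold(base)
        surr = seasonal_surrogate(comp, n=20, seed=1)
        assert np.allclose(surr.values, comp.values[:, None], atol=1e-12)

    def test_nine_point_fragments_supported(self):
        comp = fold(np.random.default_rng(0).uniform(1, 9, 240))
        # drop one census from one fragment to force uneven cyclic coverage
        f = comp.fragments[3]
        f.censuses = f.censuses[1:]
        f.raw = f.raw[1:]
        keep = np.ones(240, bool)
        keep[f.start] = False
        comp.values = comp.values[keep]
        comp.raw = comp.raw[keep]
        start = 0
        for fr in comp.fragments:
            fr.start = start
            start += len(fr)
        surr = seasonal_surrogate(comp, n=5, seed=2)
        assert surr.values.shape == (239, 5)


class TestCrossMap:
    def test_full_library_deterministic(self, logistic_pair):
        comps = logistic_pair["composites"]
        E = logistic_pair["E_map"]["y_response"]
        r1 = cross_map(comps["y_response"], comps["x_driver"], E=E, n_samples=3)
        r2 = cross_map(comps["y_response"], comps["x_driver"], E=E, n_samples=3)
        assert np.array_equal(r1, r2)
        assert np.ptp(r1) == 0  # full library: every draw identical

    def test_seeded_subsample_reproducible(self, logistic_pair):
        comps = logistic_pair["composites"]
        E = logistic_pair["E_map"]["y_response"]
        r1 = cross_map(comps["y_response"], comps["x_driver"], E=E, L=30,
                       n_samples=50, seed=7)
        r2 = cross_map(comps["y_response"], comps["x_driver"], E=E, L=30,
                       n_samples=50, seed=7)
        assert np.array_equal(r1, r2)

    def test_library_longer_than_rows_rejected(self, logistic_pair):
        comps = logistic_pair["composites"]
        with pytest.raises(ValueError, match="exceeds available rows"):
            cross_map(comps["y_response"], comps["x_driver"], E=2, L=10_000)

    def test_independent_noise_has_no_skill(self, rng):
        a = fold(rng.standard_normal(240) ** 2)
        b_panel = panel_from_series({"u": rng.standard_normal(240) ** 2})
        b = preprocess(b_panel, ln_exempt=("u",))["u"]
        rho = cross_map(a, b, E=2, n_samples=1)
        assert abs(rho[0]) < 0.25

    def test_convergence_detects_true_direction(self, logistic_pair):
        comps = logistic_pair["composites"]
        E = logistic_pair["E_map"]
        res_true = ccm_convergence(comps["x_driver"], comps["y_response"],
                                   E["y_response"], n_samples=200, seed=5)
        res_false = ccm_convergence(comps["y_response"], comps["x_driver"],
                                    E["x_driver"], n_samples=200, seed=5)
        assert res_true.delta_rho > 0.1
        assert res_true.delta_rho > res_false.delta_rho
        assert res_true.L_min == E["y_response"] + 1

    def test_summary_stable_under_doubled_sampling(self, logistic_pair):
        comps = logistic_pair["composites"]
        E = logistic_pair["E_map"]["y_response"]
        r1 = cross_map(comps["y_response"], comps["x_driver"], E=E, L=20,
                       n_samples=400, seed=1)
        r2 = cross_map(comps["y_response"], comps["x_driver"], E=E, L=20,
                       n_samples=800, seed=2)
        tol = 3 * r1.std(ddof=1) / np.sqrt(400)
        assert abs(r1.mean() - r2.mean()) < 3 * tol


class TestSurrogateTest:
    def test_rank_formula_extremes(self, logistic_pair):
        comps = logistic_pair["composites"]
        ctx = CrossMapContext(comps["y_response"],
                              logistic_pair["E_map"]["y_response"])
        surr = seasonal_surrogate(comps["x_driver"], n=50, seed=3)
        p_hi, null = surrogate_test(1.1, surr, ctx, comps["x_driver"])
        assert p_hi == pytest.approx(1 / 51)
        p_lo, _ = surrogate_test(-1.1, surr, ctx, comps["x_driver"])
        assert p_lo == 1.0
        med = float(np.median(null))
        p_med, _ = surrogate_test(med, surr, ctx, comps["x_driver"])
        assert 0.3 < p_med < 0.7

    def test_true_link_beats_null(self, logistic_pair):
        comps = logistic_pair["composites"]
        E = logistic_pair["E_map"]["y_response"]
        ctx = CrossMapContext(comps["y_response"], E)
        obs = cross_map(ctx, comps["x_driver"])[0]
        surr = seasonal_surrogate(comps["x_driver"], n=1000, seed=11)
        p, _ = surrogate_test(obs, surr, ctx, comps["x_driver"])
        assert p < 0.05


class TestLaggedCCM:
    def test_optimal_lag_nonpositive_for_true_link(self, logistic_pair):
        comps = logistic_pair["composites"]
        best, profile = lagged_ccm(comps["x_driver"], comps["y_response"],
                                   E=logistic_pair["E_map"]["y_response"],
                                   seed=2)
        assert best <= 0
        assert set(profile) == {-2, -1, 0, 1, 2}

    def test_tie_breaks_prefer_small_then_negative_lags(self):
        assert best_lag({-2: 0.5, -1: 0.5, 0: 0.5, 1: 0.5, 2: 0.5}) == 0
        assert best_lag({-1: 0.5, 1: 0.5, 0: 0.2}) == -1
        assert best_lag({-2: 0.9, 2: np.nan}) == -2
        with pytest.raises(ValueError):
            best_lag({0: np.nan})


class TestDetectLinks:
    def test_logistic_pair_cascade(self, logistic_pair):
        accepted, table, results = detect_links(
            logistic_pair["composites"], logistic_pair["E_map"],
            n_samples=300, n_surrogates=300, seed=8,
        )
        assert ("x_driver", "y_response") in accepted
        assert ("y_response", "x_driver") not in accepted
        rej = table[(table.donor == "y_response")].iloc[0]
        assert rej.failed_criterion in (1, 2, 3)

    def test_cascade_short_circuits_surrogates(self, rng, monkeypatch):
        a = rng.standard_normal(240) ** 2
        b = rng.standard_normal(240) ** 2
        panel = panel_from_series({"a": a, "b": b})
        comps = preprocess(panel, ln_exempt=("a", "b"))
        calls = {"n": 0}
        real = ccm_mod.seasonal_surrogate

        def counting(*args, **kwargs):
            calls["n"] += 1
            return real(*args, **kwargs)

        monkeypatch.setattr(ccm_mod, "seasonal_surrogate", counting)
        _, table, _ = detect_links(comps, {"a": 2, "b": 2},
                                   n_samples=100, n_surrogates=50, seed=4)
        failed_c1 = (table.failed_criterion == 1).sum()
        assert calls["n"] <= max(0, 2 - failed_c1)

    def test_rerun_bit_identical(self, logistic_pair):
        kw = dict(n_samples=100, n_surrogates=100, seed=21)
        _, t1, _ = detect_links(logistic_pair["composites"],
                                logistic_pair["E_map"], **kw)
        _, t2, _ = detect_links(logistic_pair["composites"],
                                logistic_pair["E_map"], **kw)
        assert t1.equals(t2)
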