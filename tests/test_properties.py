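import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesoweb.properties import (
    anova_consistency,
    classify_idd,
    idd_regression,
    summarize_link,
)


def coef_frame(values, treatments=("C",), years=(1,), tanks=("C1",)):
    rows = []
    i = 0
    for tr in treatments:
        for y in years:
            for tk in tanks:
                for c, v in enumerate(values, start=1):
                    rows.append({"treatment": tr, "year": y, "tank": tk,
                                 "census": c, "coefficient": v})
                    i += 1
    return pd.DataFrame(rows)


class TestIddRegression:
    def test_exact_linear_input(self):
        x = np.linspace(-2, 2, 30)
        c = -0.5 * x + 0.3
        slope, icept, r2, direction, degenerate = idd_regression(c, x)
        assert slope == pytest.approx(-0.5, abs=1e-12)
        assert direction == "negative" and not degenerate
        assert r2 == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_slope_matches_covariance_ratio(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(40)
        c = rng.standard_normal(40)
        slope, *_ = idd_regression(c, x)
        assert slope == pytest.approx(
            np.cov(x, c, ddof=1)[0, 1] / np.var(x, ddof=1), abs=1e-12
        )

    def test_zero_slope_flagged_negative_by_convention(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        c = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        slope, _, _, direction, degenerate = idd_regression(c, x)
        assert slope == 0.0 and direction == "negative" and degenerate

    def test_zero_density_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            idd_regression(np.arange(5.0), np.ones(5))

    def test_independent_coefficients_fall_in_null_band(self, rng):
        x = rng.standard_normal(200)
        c = rng.standard_normal(200)
        slope, *_ = idd_regression(c, x)
        null = []
        for _ in range(500):
            perm = rng.permutation(x)
            null.append(abs(np.cov(perm, c, ddof=0)[0, 1] / np.var(perm)))
        assert abs(slope) < np.quantile(null, 0.95)
        assert classify_idd(c, x, seed=0) == "independent"


class TestClassifyIdd:
    def test_three_way_taxonomy_on_true_jacobians(self, rng):
        """Generator-style J series with b<0, b>0, b=0 land in the right class."""
        hits = 0
        cases = []
        for b in (-0.3, 0.3, 0.0):
            for _ in range(10):
                x = rng.standard_normal(216)
                J = 0.4 + b * x + 0.05 * rng.standard_normal(216)
                want = ("negative" if b < 0 else
                        "positive" if b > 0 else "independent")
                got = classify_idd(J, x, seed=1)
                cases.append((want, got))
                hits += want == got
        assert hits / len(cases) >= 0.9


class TestSummarizeLink:
    def test_constant_coefficient(self):
        frame = coef_frame([0.7] * 10, years=(1, 2), tanks=("C1", "C2"))
        strength, variability = summarize_link(frame)
        assert strength == pytest.approx(0.7)
        assert variability == pytest.approx(0.0)

    def test_alternating_signs_decouple_mean_and_sd(self):
        a = 0.4
        frame = coef_frame([a, -a] * 5)
        strength, variability = summarize_link(frame)
        assert strength == pytest.approx(0.0, abs=1e-12)
        assert variability == pytest.approx(a * np.sqrt(10 / 9), rel=1e-12)

    def test_missing_cell_uses_remaining_cells(self):
        f1 = coef_frame([0.2] * 10, years=(1,), tanks=("C1",))
        f2 = coef_frame([0.6] * 10, years=(2,), tanks=("C1",))
        strength, _ = summarize_link(pd.concat([f1, f2]))
        assert strength == pytest.approx(0.4)

    def test_single_point_cell_warns_and_drops_sd(self):
        f1 = coef_frame([0.2] * 10, years=(1,), tanks=("C1",))
        f2 = coef_frame([0.6], years=(2,), tanks=("C1",))
        with pytest.warns(UserWarning, match="<2 points"):
            strength, variability = summarize_link(pd.concat([f1, f2]))
        assert variability == pytest.approx(0.0)

    def test_no_controls_rejected(self):
        frame = coef_frame([0.1] * 10, treatments=("I",))
        with pytest.raises(ValueError, match="no control"):
            summarize_link(frame)

    def test_mean_strength_invariant_to_census_order(self, rng):
        vals = rng.standard_normal(10)
        f1 = coef_frame(vals)
        f2 = coef_frame(vals[::-1])
        assert summarize_link(f1)[0] == pytest.approx(summarize_link(f2)[0])


class TestAnovaConsistency:
    def _frame(self, fn, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for tr in ("C", "I", "H", "IH"):
            for tank in (f"{tr}1", f"{tr}2"):
                for year in (1, 2, 3):
                    for census in range(1, 11):
                        rows.append({
                            "treatment": tr, "tank": tank, "year": year,
                            "census": census,
                            "coefficient": fn(tr, year, census, rng),
                        })
        return pd.DataFrame(rows)

    def test_treatment_only_signal(self):
        shift = {"C": 0.0, "I": 1.0, "H": 2.0, "IH": 3.0}
        frame = self._frame(lambda tr, y, c, rng: shift[tr])
        table = anova_consistency(frame)
        assert table.loc["treatment", "sum_sq"] > 0
        assert table.loc["census_date", "sum_sq"] == pytest.approx(0, abs=1e-18)

    def test_date_driven_signal_dominates_residual(self):
        frame = self._frame(
            lambda tr, y, c, rng: np.sin(c) + 0.05 * rng.standard_normal())
        table = anova_consistency(frame)
        assert table.loc["census_date", "sum_sq"] > 10 * table.loc[
            "residual", "sum_sq"]

    def test_pure_noise_F_near_one(self):
        fs = []
        for seed in range(15):
            frame = self._frame(lambda tr, y, c, rng: rng.standard_normal(),
                                seed=seed)
            table = anova_consistency(frame)
            fs.append(table.loc["treatment", "F"])
        assert 0.5 < np.mean(fs) < 2.0
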