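"""Reduce per-link coefficient series to the three interaction properties.

Each accepted link gets: the recipient-density-dependence of its effect
(IDD; the OLS slope of S-map coefficients on the recipient's standardized
density, all treatments and years pooled), its temporal variability (mean
over control year x replicate cells of the within-cell SD), and its mean
strength (mean over those cells of |within-cell mean|).  A fixed-effects
two-way ANOVA (treatment x census date) checks that coefficient fluctuations
are consistent across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from mesoweb.data_model import CompositeSeries


@dataclass
class LinkProperties:
    donor: str
    recipient: str
    idd_slope: float
    idd_direction: str  # "negative" or "positive"
    idd_magnitude: float
    mean_strength: float
    temporal_variability: float
    degenerate_slope: bool = False


def idd_regression(
    coefficients: np.ndarray, recipient_density: np.ndarray
) -> tuple[float, float, float, str, bool]:
    """OLS of interaction effect on recipient standardized density.

    Returns (slope, intercept, r2, direction, degenerate).  Direction is the
    sign of the slope; an exactly zero slope is labelled "negative" by
    convention and flagged degenerate.  Statistical significance is
    deliberately not consulted for the direction call.
    """
    c = np.asarray(coefficients, float)
    x = np.asarray(recipient_density, float)
    if len(c) < 3:
        raise ValueError("need at least 3 paired points")
    vx = np.var(x)
    if vx == 0:
        raise ValueError("zero variance in recipient density")
    slope = float(np.cov(x, c, ddof=0)[0, 1] / vx)
    intercept = float(c.mean() - slope * x.mean())
    resid = c - (intercept + slope * x)
    vc = np.var(c)
    r2 = float(1.0 - np.var(resid) / vc) if vc > 0 else 0.0
    degenerate = slope == 0.0
    direction = "positive" if slope > 0 else "negative"
    return slope, intercept, r2, direction, degenerate


def classify_idd(
    coefficients: np.ndarray,
    recipient_density: np.ndarray,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
) -> str:
    """Three-way density-dependence call: negative / positive / independent.

    The binary direction (sign of the slope) is what downstream models use;
    this classifier additionally separates density-independent variability
    by comparing |slope| with its permutation null (density labels shuffled).
    """
    slope, _, _, direction, _ = idd_regression(coefficients, recipient_density)
    rng = np.random.default_rng(seed)
    x = np.asarray(recipient_density, float)
    c = np.asarray(coefficients, float)
    vx = np.var(x)
    null = np.array([
        abs(np.cov(rng.permutation(x), c, ddof=0)[0, 1] / vx)
        for _ in range(n_perm)
    ])
    if abs(slope) <= np.quantile(null, 1 - alpha):
        return "independent"
    return direction


def summarize_link(
    series: pd.DataFrame, control_treatment: str = "C"
) -> tuple[float, float]:
    """Mean strength and temporal variability from control coefficients.

    Per (year, tank) cell: mean and SD of the coefficients over censuses;
    then the absolute values are averaged across cells.  Cells with fewer
    than 2 points have no SD and are dropped with a warning.
    """
    ctl = series[series["treatment"] == control_treatment]
    if ctl.empty:
        raise ValueError("no control coefficients for this link")
    means, sds = [], []
    for (_, _), cell in ctl.groupby(["year", "tank"]):
        v = cell["coefficient"].to_numpy()
        means.append(np.mean(v))
        if len(v) >= 2:
            sds.append(np.std(v, ddof=1))
        else:
            warnings.warn("cell with <2 points dropped from SD summary")
    mean_strength = float(np.mean(np.abs(means)))
    temporal_variability = float(np.mean(np.abs(sds))) if sds else np.nan
    return mean_strength, temporal_variability


def link_properties(
    interaction_series: pd.DataFrame,
    composites: dict[str, CompositeSeries],
) -> pd.DataFrame:
    """LinkProperties table for every link in an interaction-series frame."""
    rows = []
    key_cache: dict[str, dict] = {}
    for (donor, recipient), g in interaction_series.groupby(["donor", "recipient"]):
        comp = composites[recipient]
        if recipient not in key_cache:
            key_cache[recipient] = comp.key_index()
        kidx = key_cache[recipient]
        dens = np.array(
            [
                comp.values[kidx[(t, tr, y, c)]]
                for t, tr, y, c in zip(g["tank"], g["treatment"], g["year"], g["census"])
            ]
        )
        slope, _, r2, direction, degenerate = idd_regression(
            g["coefficient"].to_numpy(), dens
        )
        strength, variability = summarize_link(g)
        rows.append(
            {
                "donor": donor, "recipient": recipient,
                "idd_slope": slope, "idd_direction": direction,
                "idd_magnitude": abs(slope), "mean_strength": strength,
                "temporal_variability": variability, "r2": r2,
                "degenerate_slope": degenerate,
            }
        )
    return pd.DataFrame(rows)


def anova_consistency(series: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of coefficients on treatment x census date.

    Census date is the (year, census) combination; replication comes from
    the tanks.  No random effects and no autocorrelation are modelled.  An
    unreplicated interaction (one observation per cell) leaves no residual
    and is flagged.
    """
    df = series.copy()
    df["date"] = df["year"].astype(str) + "_" + df["census"].astype(str)
    model = smf.ols("coefficient ~ C(treatment) * C(date)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(treatment)": "treatment",
            "C(date)": "census_date",
            "C(treatment):C(date)": "treatment:census_date",
            "Residual": "residual",
        }
    )
    table.attrs["interaction_confounded"] = bool(
        table.loc["residual", "df"] <= 0 or not np.isfinite(model.mse_resid)
    )
    return table
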