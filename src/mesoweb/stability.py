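"""Population sensitivity to press disturbance and its interaction-property drivers.

Sensitivity of taxon i in year j to a treatment is |LRR| with
LRR = ln((T_ij + 0.1)/(C_ij + 0.1)), T and C being mean raw densities in the
treatment and control tanks.  The headline model regresses ln(1+|LRR|) of
each link's recipient on the link's mean strength, temporal variability,
ln(IDD magnitude), IDD direction, their interaction, and the recipient's
functional role, with random intercepts for link identity and year; terms
are judged by Type III likelihood-ratio chi^2 from full-vs-reduced ML fits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from patsy import dmatrix

from mesoweb.data_model import CommunityPanel, preprocess
from mesoweb.lmm import LmmResult, fit_lmm, lr_test

CONTRASTS = ("I", "H", "IH")

#: default functional-role map; user-overridable (the producer/predator/prey
#: assignment of some groups, e.g. molluscs, is a modelling choice)
DEFAULT_FUNCTIONS = {
    "phytoplankton": "producer",
    "macrophytes": "producer",
    "phyt_pred": "predator",
    "benth_pred": "predator",
    "neust_pred": "predator",
    "rotifers": "prey",
    "crust_zoop": "prey",
    "detritivores": "prey",
    "herbivores": "prey",
    "molluscs": "prey",
}


def log_response_ratio(T: float, C: float) -> float:
    """ln((T + 0.1)/(C + 0.1)) on raw (unstandardized) mean densities."""
    if T < 0 or C < 0:
        raise ValueError("densities must be non-negative")
    return float(np.log((T + 0.1) / (C + 0.1)))


def sensitivity_table(panel: CommunityPanel) -> pd.DataFrame:
    """|LRR| per taxon x year x treatment contrast (treatment vs control).

    T and C are means over the replicate tanks and all censuses of the
    year.  A missing treatment arm drops that contrast with a warning.
    """
    df = panel.data
    means = (
        df.groupby(["taxon", "year", "treatment"])["raw_density"].mean().unstack()
    )
    rows = []
    for (taxon, year), m in means.iterrows():
        if "C" not in m or pd.isna(m["C"]):
            warnings.warn(f"no control densities for {taxon} year {year}")
            continue
        for tr in CONTRASTS:
            if tr not in m or pd.isna(m[tr]):
                warnings.warn(f"missing arm {tr} for {taxon} year {year}")
                continue
            lrr = log_response_ratio(m[tr], m["C"])
            rows.append(
                {
                    "taxon": taxon, "year": int(year), "contrast": tr,
                    "T_mean": float(m[tr]), "C_mean": float(m["C"]),
                    "lrr": lrr, "sensitivity": abs(lrr),
                }
            )
    return pd.DataFrame(rows)


REGRESSION_TERMS = [
    ("mean_strength", "mean_strength"),
    ("temporal_variability", "temporal_variability"),
    ("idd", "ln_idd"),
    ("idd_direction", "C(idd_direction, Sum)"),
    ("idd_x_direction", "ln_idd:C(idd_direction, Sum)"),
    ("recipient_function", "C(recipient_function, Sum)"),
]


def _regression_frame(
    properties: pd.DataFrame,
    sensitivities: pd.DataFrame,
    contrast: str,
    functions: dict[str, str],
) -> pd.DataFrame:
    props = properties.copy()
    if (props["idd_magnitude"] <= 0).any():
        warnings.warn("links with zero IDD magnitude excluded (ln undefined)")
        props = props[props["idd_magnitude"] > 0]
    props["ln_idd"] = np.log(props["idd_magnitude"])
    props["link"] = props["donor"] + "->" + props["recipient"]
    props["recipient_function"] = props["recipient"].map(functions)
    sens = sensitivities[sensitivities["contrast"] == contrast]
    merged = props.merge(
        sens[["taxon", "year", "sensitivity"]],
        left_on="recipient", right_on="taxon", how="inner",
    )
    merged["response"] = np.log1p(merged["sensitivity"])
    return merged


def sensitivity_regression(
    properties: pd.DataFrame,
    sensitivities: pd.DataFrame,
    contrast: str,
    functions: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, LmmResult, pd.DataFrame]:
    """Mixed-model regression of recipient sensitivity on link properties.

    Returns (Type III LR table with one row per term, full-model fit, the
    analysis frame).  Fixed effects use sum-to-zero coding for the
    categorical terms so that marginal (Type III) drops are meaningful with
    the interaction present; random intercepts are link identity and year.
    """
    functions = functions or DEFAULT_FUNCTIONS
    data = _regression_frame(properties, sensitivities, contrast, functions)
    if data.empty:
        raise ValueError(f"no rows for contrast {contrast!r}")
    formula = (
        "mean_strength + temporal_variability + ln_idd"
        " + C(idd_direction, Sum) + ln_idd:C(idd_direction, Sum)"
        " + C(recipient_function, Sum)"
    )
    X = dmatrix(formula, data, return_type="dataframe")
    y = data["response"].to_numpy()
    rand = {"link": data["link"].to_numpy(), "year": data["year"].to_numpy()}
    full = fit_lmm(y, X.to_numpy(), random_intercepts=rand,
                   exog_names=list(X.columns))
    di = X.design_info
    rows = []
    for name, term_code in REGRESSION_TERMS:
        cols = []
        for term, sl in di.term_name_slices.items():
            if term == term_code:
                cols = list(range(sl.start, sl.stop))
        if not cols:
            raise RuntimeError(f"term {term_code} not found in design")
        keep = [j for j in range(X.shape[1]) if j not in cols]
        reduced = fit_lmm(y, X.to_numpy()[:, keep], random_intercepts=rand)
        chi2, p = lr_test(full, reduced, df=len(cols))
        coef = full.beta[cols[0]] if len(cols) == 1 else np.nan
        rows.append({"term": name, "chi2": chi2, "df": len(cols), "p": p,
                     "coef": coef})
    table = pd.DataFrame(rows)
    return table, full, data


def partial_effect(
    fit: LmmResult, data: pd.DataFrame, variable: str, n_grid: int = 25
) -> pd.DataFrame:
    """Fitted response over a grid of one continuous covariate, all other
    covariates held at their medians (categoricals at sum-to-zero means)."""
    med = data.median(numeric_only=True)
    grid = np.linspace(data[variable].min(), data[variable].max(), n_grid)
    frame = pd.DataFrame({c: med.get(c, 0.0) for c in
                          ["mean_strength", "temporal_variability", "ln_idd"]},
                         index=range(n_grid))
    frame[variable] = grid
    frame["idd_direction"] = data["idd_direction"].mode()[0]
    frame["recipient_function"] = data["recipient_function"].mode()[0]
    formula = (
        "mean_strength + temporal_variability + ln_idd"
        " + C(idd_direction, Sum) + ln_idd:C(idd_direction, Sum)"
        " + C(recipient_function, Sum)"
    )
    Xg = dmatrix(formula, pd.concat([data, frame]).tail(n_grid),
                 return_type="dataframe")
    pred = Xg.to_numpy() @ fit.beta
    return pd.DataFrame({variable: grid, "fitted": pred})


def dunnett_pvalues(
    estimates: np.ndarray,
    vcov: np.ndarray,
    n_mc: int = 200_000,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided Dunnett-type adjusted p-values by Monte-Carlo on the joint
    normal of the treatment-vs-control contrasts (method: mvn-monte-carlo)."""
    se = np.sqrt(np.diag(vcov))
    z = estimates / se
    R = vcov / np.outer(se, se)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(np.zeros(len(z)), R, size=n_mc)
    maxabs = np.abs(draws).max(axis=1)
    return np.array([(1 + np.sum(maxabs >= abs(zk))) / (1 + n_mc) for zk in z])


def treatment_effect_model(
    panel: CommunityPanel,
    taxon: str,
    ln_exempt=("macrophytes",),
    mc_seed: int = 0,
) -> dict:
    """Per-taxon LMM of standardized density on treatment and census week.

    Random intercepts: tank and year; residuals follow an AR-1 process
    within each tank-year.  Fixed terms are tested by Type III likelihood
    ratios; treatment contrasts vs control get Dunnett-type adjusted
    two-sided p-values.  If the AR-1 fit fails, the model falls back to
    independent residuals and records the downgrade.
    """
    comp = preprocess(panel, ln_exempt=ln_exempt)[taxon]
    rows = []
    for f in comp.fragments:
        for j, c in enumerate(f.censuses):
            rows.append({
                "value": comp.values[f.start + j], "treatment": f.treatment,
                "census": int(c), "tank": f.tank_id, "year": f.year,
                "tank_year": f"{f.tank_id}_{f.year}",
            })
    df = pd.DataFrame(rows)
    X = dmatrix("C(treatment, Treatment('C')) + C(census)", df,
                return_type="dataframe")
    y = df["value"].to_numpy()
    rand = {"tank": df["tank"].to_numpy(), "year": df["year"].to_numpy()}
    kwargs = dict(random_intercepts=rand, exog_names=list(X.columns))
    ar1_downgraded = False
    full = fit_lmm(y, X.to_numpy(), ar1_group=df["tank_year"].to_numpy(),
                   time=df["census"].to_numpy(), **kwargs)
    if not full.converged:
        ar1_downgraded = True
        full = fit_lmm(y, X.to_numpy(), **kwargs)

    def refit(keep_cols):
        if ar1_downgraded:
            return fit_lmm(y, X.to_numpy()[:, keep_cols], random_intercepts=rand)
        return fit_lmm(y, X.to_numpy()[:, keep_cols], random_intercepts=rand,
                       ar1_group=df["tank_year"].to_numpy(),
                       time=df["census"].to_numpy())

    di = X.design_info
    lr_rows = []
    for term, sl in di.term_name_slices.items():
        if term == "Intercept":
            continue
        cols = list(range(sl.start, sl.stop))
        keep = [j for j in range(X.shape[1]) if j not in cols]
        reduced = refit(keep)
        chi2, p = lr_test(full, reduced, df=len(cols))
        label = "treatment" if term.startswith("C(treatment") else "census"
        lr_rows.append({"term": label, "chi2": chi2, "df": len(cols), "p": p})

    tr_cols = [j for j, c in enumerate(X.columns) if c.startswith("C(treatment")]
    levels = [c.split("T.")[1].rstrip("]") for c in X.columns[tr_cols]]
    est = full.beta[tr_cols]
    vc = full.vcov_beta[np.ix_(tr_cols, tr_cols)]
    padj = dunnett_pvalues(est, vc, seed=mc_seed)
    contrasts = pd.DataFrame({
        "contrast": [f"{lv} - C" for lv in levels],
        "estimate": est, "se": np.sqrt(np.diag(vc)), "p_adj": padj,
    })
    n_tanks = df.groupby("treatment")["tank"].nunique()
    return {
        "taxon": taxon,
        "fit": full,
        "lr_table": pd.DataFrame(lr_rows),
        "contrasts": contrasts,
        "ar1_downgraded": ar1_downgraded,
        "dunnett_method": "mvn-monte-carlo",
        "single_tank_flag": bool((n_tanks < 2).any()),
    }
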