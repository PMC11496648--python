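"""Synthetic mesocosm communities with a known, density-dependent interaction web.

The generator mirrors the experimental design (2 tanks x 4 treatments x
3 years x 10 fortnightly censuses x 10 functional groups) with a discrete
Ricker-type update on the log scale.  Each directed link carries a
per-capita effect J_dr(t) = a_dr + b_dr * Nr~(t) + eps_int(t) acting on the
*standardized* donor density, so generator effects live on the same scale
as the S-map coefficients the pipeline estimates; b_dr is the ground-truth
interaction density-dependence (negative = stabilizing, positive =
destabilizing, zero = density-independent variability via eps_int).
Treatments apply selective multiplicative presses (an "insecticide" hitting
predators, an "herbicide" hitting producers) at every census.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mesoweb.data_model import TAXA, CommunityPanel


@dataclass(frozen=True)
class SyntheticLink:
    donor: str
    recipient: str
    a: float  # baseline per-capita effect (standardized-density scale)
    b: float  # recipient-density-dependence slope; sign = IDD direction


#: default interaction web: a small plankton-macrophyte-invertebrate food web
#: covering all three density-dependence classes
DEFAULT_LINKS = (
    SyntheticLink("phytoplankton", "rotifers", a=0.45, b=-0.30),
    SyntheticLink("rotifers", "phytoplankton", a=-0.45, b=-0.25),
    SyntheticLink("rotifers", "crust_zoop", a=0.40, b=0.25),
    SyntheticLink("phyt_pred", "rotifers", a=-0.40, b=0.30),
    SyntheticLink("benth_pred", "molluscs", a=-0.45, b=-0.30),
    SyntheticLink("neust_pred", "molluscs", a=-0.40, b=0.0),
    SyntheticLink("macrophytes", "herbivores", a=0.45, b=0.0),
    SyntheticLink("phytoplankton", "detritivores", a=-0.35, b=-0.25),
)

DEFAULT_PRESSES = {
    "I": {"phyt_pred": 0.45, "benth_pred": 0.45, "detritivores": 0.80},
    "H": {"macrophytes": 0.50, "phytoplankton": 0.85},
}


@dataclass
class SyntheticConfig:
    taxa: tuple = TAXA
    links: tuple = DEFAULT_LINKS
    self_reg: float = -0.4  # pull of own standardized density on growth
    sigma_int: float = 0.05  # density-independent interaction noise SD
    sigma_proc: float = 0.05  # process noise SD on log growth
    season_amp: float = 0.30  # sinusoidal forcing amplitude (log-growth units)
    season_period: int = 10  # censuses per seasonal cycle
    presses: dict = field(default_factory=lambda: dict(DEFAULT_PRESSES))
    tanks_per_treatment: int = 2
    n_years: int = 3
    n_censuses: int = 10
    ref_log_mean: float = 3.0  # reference ln(N+1) around which taxa fluctuate
    ref_log_sd: float = 0.5  # reference scale for standardized density
    init_sd: float = 0.4  # initial-condition spread on the log scale
    state_clip: float = 2.5  # saturation range of standardized densities in
    # the growth terms; beyond it responses level off (bounds the feedbacks)
    density_cap: float = 1e6

    def __post_init__(self) -> None:
        if self.n_censuses % self.season_period and \
                self.season_period % self.n_censuses:
            raise ValueError("seasonal period must divide the fragment length")
        for s in (self.sigma_int, self.sigma_proc):
            if s < 0:
                raise ValueError("noise SDs must be non-negative")

    def press_log_effects(self) -> dict[str, dict[str, float]]:
        """Per-treatment, per-taxon ln(survival) applied at every census."""
        out = {"C": {}}
        out["I"] = {t: float(np.log(s)) for t, s in self.presses.get("I", {}).items()}
        out["H"] = {t: float(np.log(s)) for t, s in self.presses.get("H", {}).items()}
        ih = dict(out["I"])
        for t, v in out["H"].items():
            ih[t] = ih.get(t, 0.0) + v
        out["IH"] = ih
        return out


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated panel.

    jacobians: frame (tank, treatment, year, census, donor, recipient,
    jacobian) with J_dr(t) exactly as used in the census -> census+1 update.
    states: standardized densities at every key.
    """

    config: SyntheticConfig
    jacobians: pd.DataFrame
    states: pd.DataFrame

    @property
    def links(self) -> tuple:
        return self.config.links

    def idd_directions(self) -> dict[tuple[str, str], str]:
        return {
            (l.donor, l.recipient):
                ("positive" if l.b > 0 else "negative" if l.b < 0 else "independent")
            for l in self.config.links
        }

    def jacobian_lookup(self) -> dict:
        return {
            (r.tank, r.year, r.census, r.donor, r.recipient): r.jacobian
            for r in self.jacobians.itertuples()
        }


def analytic_jacobian(
    truth: SyntheticTruth, link: tuple[str, str], key: tuple
) -> float:
    """True per-capita effect of ``link`` at key (tank, year, census)."""
    tank, year, census = key
    lk = (tank, year, census, link[0], link[1])
    table = truth.jacobian_lookup()
    if lk not in table:
        raise KeyError(f"no simulated state for {lk}")
    return table[lk]


def simulate_community(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[CommunityPanel, SyntheticTruth]:
    """Simulate the full design; returns a validated panel plus ground truth."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    taxa = list(cfg.taxa)
    ti = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    phases = 2 * np.pi * np.arange(n) / n
    press = cfg.press_log_effects()
    link_idx = [(ti[l.donor], ti[l.recipient], l.a, l.b) for l in cfg.links]

    panel_rows, jac_rows, state_rows = [], [], []
    treatments = ("C", "I", "H", "IH")
    for treat in treatments:
        mort = np.zeros(n)
        for t, v in press[treat].items():
            mort[ti[t]] = v
        for rep in range(cfg.tanks_per_treatment):
            tank = f"{treat}{rep + 1}"
            for year in range(1, cfg.n_years + 1):
                L = np.maximum(
                    cfg.ref_log_mean + cfg.init_sd * rng.standard_normal(n), 0.0
                )
                for census in range(1, cfg.n_censuses + 1):
                    N = np.expm1(L)
                    Nt_raw = (L - cfg.ref_log_mean) / cfg.ref_log_sd
                    # interaction responses saturate outside +-state_clip;
                    # self-limitation keeps acting on the unclipped state
                    Nt = np.clip(Nt_raw, -cfg.state_clip, cfg.state_clip)
                    for i, t in enumerate(taxa):
                        panel_rows.append((tank, treat, year, census, t, N[i]))
                        state_rows.append((tank, treat, year, census, t, Nt[i]))
                    if census == cfg.n_censuses:
                        break
                    season = cfg.season_amp * np.sin(
                        2 * np.pi * census / cfg.season_period + phases
                    )
                    growth = season + cfg.self_reg * Nt_raw + mort
                    growth += cfg.sigma_proc * rng.standard_normal(n)
                    for d, r, a, b in link_idx:
                        J = a + b * Nt[r]
                        if cfg.sigma_int > 0:
                            J += cfg.sigma_int * rng.standard_normal()
                        growth[r] += J * Nt[d]
                        jac_rows.append(
                            (tank, treat, year, census, taxa[d], taxa[r], J)
                        )
                    L = np.maximum(L + growth, 0.0)
                    if np.any(np.expm1(L) > cfg.density_cap):
                        raise RuntimeError(
                            "explosive divergence: reduce interaction or "
                            "forcing strengths"
                        )
    panel = CommunityPanel(
        pd.DataFrame(
            panel_rows,
            columns=["tank_id", "treatment", "year", "census", "taxon",
                     "raw_density"],
        )
    )
    truth = SyntheticTruth(
        config=cfg,
        jacobians=pd.DataFrame(
            jac_rows,
            columns=["tank", "treatment", "year", "census", "donor",
                     "recipient", "jacobian"],
        ),
        states=pd.DataFrame(
            state_rows,
            columns=["tank", "treatment", "year", "census", "taxon", "state"],
        ),
    )
    return panel, truth


def coupled_logistic_panel(
    seed: int | None = None,
    n_fragments: int = 24,
    fragment_length: int = 10,
    coupling: float = 0.32,
    rx: float = 3.8,
    ry: float = 3.5,
    burn_in: int = 200,
) -> CommunityPanel:
    """Unidirectionally coupled logistic maps (x drives y) folded into the
    study's fragment layout; the classic cross-mapping test system.

    One long orbit is chopped into consecutive fragments, so each fragment
    genuinely continues the same dynamics (mirroring tanks that share
    dynamics but are embedded separately).
    """
    rng = np.random.default_rng(seed)
    total = n_fragments * fragment_length
    x = rng.uniform(0.2, 0.8)
    y = rng.uniform(0.2, 0.8)
    xs, ys = np.empty(burn_in + total), np.empty(burn_in + total)
    for t in range(burn_in + total):
        x, y = x * (rx - rx * x), y * (ry - ry * y - coupling * x)
        xs[t], ys[t] = x, y
    xs, ys = xs[burn_in:], ys[burn_in:]
    rows = []
    treatments = ("C", "I", "H", "IH")
    f = 0
    for year in range(1, 4):
        for treat in treatments:
            for rep in range(1, 3):
                tank = f"{treat}{rep}"
                seg = slice(f * fragment_length, (f + 1) * fragment_length)
                for j, (xv, yv) in enumerate(zip(xs[seg], ys[seg])):
                    rows.append((tank, treat, year, j + 1, "x_driver", xv))
                    rows.append((tank, treat, year, j + 1, "y_response", yv))
                f += 1
    return CommunityPanel(
        pd.DataFrame(rows, columns=["tank_id", "treatment", "year", "census",
                                    "taxon", "raw_density"])
    )


DEFAULT_SENSITIVITY_BETAS = {
    "intercept": 0.6,
    "temporal_variability": 1.2,
    "mean_strength": 0.2,
    "ln_idd": 0.06,
    "direction": 0.05,  # coefficient of the sum-coded direction contrast
    "idd_x_direction": 0.08,
    "sd_link": 0.10,
    "sd_year": 0.05,
    "sd_resid": 0.12,
}


def simulate_sensitivity_experiment(
    n_links: int = 23,
    n_years: int = 3,
    betas: dict | None = None,
    seed: int | None = None,
    contrast: str = "IH",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parametric ground-truth experiment for the sensitivity regression.

    Link properties are drawn at realistic scales and recipient sensitivity
    is generated from the mixed model itself, with density-independent
    temporal variability constructed as the dominant destabilizing driver
    (largest positive coefficient).  Returns (properties, sensitivities)
    frames shaped exactly like the pipeline outputs so the regression can
    be run unchanged and its term ranking compared with the truth.
    """
    b = dict(DEFAULT_SENSITIVITY_BETAS)
    if betas:
        b.update(betas)
    rng = np.random.default_rng(seed)
    # one recipient per link so each link-year row carries its own response
    recipients = [f"taxon{i}" for i in range(n_links)]
    functions = {f"taxon{i}": ("producer", "prey", "predator")[i % 3]
                 for i in range(n_links)}
    props = pd.DataFrame({
        "donor": [f"donor{i}" for i in range(n_links)],
        "recipient": recipients,
        "mean_strength": np.abs(rng.normal(0.2, 0.1, n_links)) + 0.01,
        "temporal_variability": np.abs(rng.normal(0.3, 0.12, n_links)) + 0.02,
        "idd_magnitude": np.exp(rng.normal(-1.5, 0.6, n_links)),
        "idd_direction": rng.choice(["negative", "positive"], n_links),
    })
    props["idd_slope"] = np.where(
        props["idd_direction"] == "positive", 1.0, -1.0
    ) * props["idd_magnitude"]
    u_link = rng.normal(0, b["sd_link"], n_links)
    u_year = rng.normal(0, b["sd_year"], n_years)
    dir_code = np.where(props["idd_direction"] == "negative", 1.0, -1.0)
    ln_idd = np.log(props["idd_magnitude"].to_numpy())
    lin = (
        b["intercept"]
        + b["temporal_variability"] * props["temporal_variability"].to_numpy()
        + b["mean_strength"] * props["mean_strength"].to_numpy()
        + b["ln_idd"] * ln_idd
        + b["direction"] * dir_code
        + b["idd_x_direction"] * ln_idd * dir_code
        + u_link
    )
    sens_rows = []
    for year in range(1, n_years + 1):
        resp = lin + u_year[year - 1] + rng.normal(0, b["sd_resid"], n_links)
        sens = np.expm1(np.maximum(resp, 1e-6))
        for i, r in enumerate(recipients):
            sens_rows.append({"taxon": r, "year": year, "contrast": contrast,
                              "lrr": sens[i], "sensitivity": sens[i]})
    sensitivities = pd.DataFrame(sens_rows)
    props.attrs["functions"] = functions
    props.attrs["true_betas"] = b
    return props, sensitivities
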