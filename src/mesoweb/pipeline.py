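"""End-to-end orchestration: panel -> embeddings -> network -> coefficients
-> link properties -> sensitivity models, with seeded stages and a JSON
artifact manifest.

The defaults reproduce the reference analysis settings (E scanned over 2-6,
1000 cross-map samples, 1000 seasonal surrogates, lags -2..+2 with 100
samples, the exact theta/lambda grids); every knob is a config field so a
scaled-down run is one dataclass away.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mesoweb import ccm, data_model, properties, smap, stability, state_space
from mesoweb.data_model import CommunityPanel

log = logging.getLogger("mesoweb")


@dataclass
class PipelineConfig:
    input_csv: str | None = None  # None -> caller supplies a panel
    ln_exempt: tuple = ("macrophytes",)
    E_min: int = 2
    E_max: int = 6
    E_criterion: str = "rmse"
    ccm_samples: int = 1000
    n_surrogates: int = 1000
    lag_samples: int = 100
    alpha: float = 0.05
    marginal_p: float = 0.1
    delta_rho_threshold: float = 0.1
    cycle: int = 10
    theta_grid: tuple = smap.THETA_GRID
    lambda_grid: tuple = smap.LAMBDA_GRID
    contrasts: tuple = stability.CONTRASTS
    functions: dict = field(default_factory=lambda: dict(stability.DEFAULT_FUNCTIONS))
    seed: int = 0
    run_ccm: bool = True
    run_smap: bool = True
    run_stability: bool = True
    edge_list: tuple | None = None  # user-supplied links when run_ccm=False
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("ln_exempt", "theta_grid", "lambda_grid", "contrasts"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("edge_list"):
            raw["edge_list"] = tuple(tuple(e) for e in raw["edge_list"])
        return cls(**raw)


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    return {n: int(c.generate_state(1)[0] % 2**31)
            for n, c in zip(names, ss.spawn(len(names)))}


def run_pipeline(
    config: PipelineConfig,
    panel: CommunityPanel | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute every enabled stage; write tables + a manifest under outdir.

    Returns the manifest (also written as manifest.json).  A stage failure
    raises after persisting the artifacts of completed stages.
    """
    t0 = time.time()
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["ccm"])
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seeds": seeds,
        "stages": {},
        "artifacts": {},
    }

    def _finish(stage, t_start, **extra):
        manifest["stages"][stage] = {"seconds": round(time.time() - t_start, 2),
                                     **extra}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    # --- data -------------------------------------------------------------
    t = time.time()
    if panel is None:
        if config.input_csv is None:
            raise ValueError("config.input_csv or an in-memory panel required")
        panel = data_model.load_panel(config.input_csv)
    composites = data_model.preprocess(panel, ln_exempt=config.ln_exempt)
    data_model.composite_to_csv(composites, out / "composites.csv")
    with open(out / "transform_meta.json", "w") as fh:
        json.dump(data_model.transform_meta(composites), fh, indent=2)
    manifest["artifacts"]["composites"] = "composites.csv"
    _finish("data_model", t, n_records=panel.n_records,
            n_taxa=len(composites))

    # --- embedding dimensions ---------------------------------------------
    t = time.time()
    E_map: dict[str, int] = {}
    skill_tables = []
    for taxon, comp in sorted(composites.items()):
        E, table = state_space.select_embedding_dimension(
            comp, config.E_min, config.E_max, criterion=config.E_criterion
        )
        E_map[taxon] = E
        table.insert(0, "taxon", taxon)
        skill_tables.append(table)
    pd.concat(skill_tables).to_csv(out / "embedding_skill.csv", index=False)
    with open(out / "chosen_E.json", "w") as fh:
        json.dump(E_map, fh, indent=2)
    manifest["artifacts"]["embedding_skill"] = "embedding_skill.csv"
    _finish("state_space", t, chosen_E=E_map)

    # --- CCM network --------------------------------------------------------
    t = time.time()
    if config.run_ccm:
        accepted, ccm_table, _ = ccm.detect_links(
            composites, E_map,
            n_samples=config.ccm_samples, n_surrogates=config.n_surrogates,
            lag_samples=config.lag_samples, alpha=config.alpha,
            marginal_p=config.marginal_p,
            delta_rho_threshold=config.delta_rho_threshold,
            cycle=config.cycle, seed=seeds["ccm"],
        )
        ccm_table.to_csv(out / "ccm_results.csv", index=False)
        manifest["artifacts"]["ccm_results"] = "ccm_results.csv"
    else:
        if not config.edge_list:
            raise ValueError("run_ccm=False requires an edge_list")
        accepted = [tuple(e) for e in config.edge_list]
        ccm_table = pd.DataFrame()
    with open(out / "network_edges.json", "w") as fh:
        json.dump([list(e) for e in accepted], fh, indent=2)
    manifest["artifacts"]["network_edges"] = "network_edges.json"
    _finish("ccm_inference", t, n_accepted=len(accepted))

    # --- S-map interaction series ------------------------------------------
    if config.run_smap and accepted:
        t = time.time()
        series, smap_meta = smap.interaction_timeseries(
            accepted, composites, E_map,
            theta_grid=config.theta_grid, lambda_grid=config.lambda_grid,
        )
        series.to_csv(out / "interaction_series.csv", index=False)
        with open(out / "smap_params.json", "w") as fh:
            json.dump(smap_meta, fh, indent=2)
        manifest["artifacts"]["interaction_series"] = "interaction_series.csv"
        _finish("smap_interactions", t, n_links=len(accepted))

        t = time.time()
        props = properties.link_properties(series, composites)
        props.to_csv(out / "link_properties.csv", index=False)
        manifest["artifacts"]["link_properties"] = "link_properties.csv"
        _finish("interaction_properties", t, n_links=len(props))
    else:
        series, props = pd.DataFrame(), pd.DataFrame()

    # --- stability ----------------------------------------------------------
    if config.run_stability:
        t = time.time()
        sens = stability.sensitivity_table(panel)
        sens.to_csv(out / "sensitivity.csv", index=False)
        manifest["artifacts"]["sensitivity"] = "sensitivity.csv"
        reg_tables = {}
        if len(props):
            for contrast in config.contrasts:
                try:
                    table, _, _ = stability.sensitivity_regression(
                        props, sens, contrast, functions=config.functions
                    )
                except ValueError as exc:
                    log.warning("contrast %s skipped: %s", contrast, exc)
                    continue
                table.to_csv(out / f"regression_{contrast}.csv", index=False)
                reg_tables[contrast] = table
                manifest["artifacts"][f"regression_{contrast}"] = (
                    f"regression_{contrast}.csv"
                )
        _finish("stability_analysis", t, contrasts=list(reg_tables))
    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def make_report(manifest: dict, outdir: str | Path) -> dict:
    """Summarize a finished run: link tallies by sign and density-dependence,
    top-variability links, and per-contrast term tables."""
    out = Path(outdir)
    report: dict = {}
    edges_path = out / "network_edges.json"
    if edges_path.exists():
        with open(edges_path) as fh:
            edges = json.load(fh)
        report["n_links"] = len(edges)
        if not edges:
            report["note"] = "no links"
    props_path = out / "link_properties.csv"
    if props_path.exists():
        props = pd.read_csv(props_path)
        report["idd_direction_counts"] = (
            props["idd_direction"].value_counts().to_dict()
        )
        report["mean_strength_median"] = float(props["mean_strength"].median())
        report["top_variability_links"] = (
            props.nlargest(3, "temporal_variability")
            [["donor", "recipient", "temporal_variability"]]
            .to_dict("records")
        )
    for contrast in ("I", "H", "IH"):
        p = out / f"regression_{contrast}.csv"
        if p.exists():
            report[f"regression_{contrast}"] = pd.read_csv(p).to_dict("records")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
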