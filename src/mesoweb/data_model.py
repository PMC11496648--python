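"""Panel ingestion, validation and the composite-series representation.

The experimental design yields, per taxon, many short fragments of time
series (one per tank x year).  All fragments are standardized *jointly* as a
single composite (zero mean, unit variance over the concatenation) so that
state-space coordinates are comparable across tanks, treatments and years,
while dynamics (lags, growth rates) are never computed across a fragment
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("C", "I", "H", "IH")

#: canonical functional-group labels used by the default design
TAXA = (
    "phytoplankton",
    "rotifers",
    "crust_zoop",
    "macrophytes",
    "detritivores",
    "herbivores",
    "phyt_pred",
    "benth_pred",
    "neust_pred",
    "molluscs",
)

PANEL_COLUMNS = ["tank_id", "treatment", "year", "census", "taxon", "raw_density"]


class PanelValidationError(ValueError):
    """Raised when a community panel violates a design invariant."""


@dataclass
class CommunityPanel:
    """Long-format raw densities keyed by (tank, treatment, year, census, taxon)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError(f"panel missing columns: {missing}")
        df = df[PANEL_COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["census"] = df["census"].astype(int)
        df["raw_density"] = df["raw_density"].astype(float)

        bad = df[df["raw_density"] < 0]
        if len(bad):
            r = bad.iloc[0]
            raise PanelValidationError(
                f"negative density at (tank={r.tank_id}, year={r.year}, "
                f"census={r.census}, taxon={r.taxon}): {r.raw_density}"
            )
        dup = df.duplicated(subset=["tank_id", "year", "census", "taxon"])
        if dup.any():
            r = df[dup].iloc[0]
            raise PanelValidationError(
                f"duplicate key (tank={r.tank_id}, year={r.year}, "
                f"census={r.census}, taxon={r.taxon})"
            )
        unknown = set(df["treatment"]) - set(TREATMENTS)
        if unknown:
            raise PanelValidationError(f"unknown treatments: {sorted(unknown)}")
        # each fragment must be a gap-free run of censuses (constant interval)
        for (tank, year, taxon), g in df.groupby(["tank_id", "year", "taxon"]):
            cs = np.sort(g["census"].to_numpy())
            if len(cs) > 10:
                raise PanelValidationError(
                    f"fragment (tank={tank}, year={year}, taxon={taxon}) has "
                    f"{len(cs)} censuses (max 10)"
                )
            if len(cs) and not np.array_equal(cs, np.arange(cs[0], cs[0] + len(cs))):
                raise PanelValidationError(
                    f"missing census inside fragment (tank={tank}, year={year}, "
                    f"taxon={taxon}): censuses {cs.tolist()}"
                )
        self.data = df.sort_values(
            ["treatment", "tank_id", "year", "census", "taxon"]
        ).reset_index(drop=True)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.data["taxon"].unique())

    @property
    def n_records(self) -> int:
        return len(self.data)

    def tank_treatments(self) -> dict[str, str]:
        return dict(
            self.data[["tank_id", "treatment"]].drop_duplicates().to_numpy()
        )


@dataclass
class Fragment:
    """One tank-year run of consecutive censuses for one taxon.

    Carries both raw densities (for per-capita growth) and the standardized
    composite values (for embedding), so neither has to be re-derived.
    """

    tank_id: str
    treatment: str
    year: int
    censuses: np.ndarray  # 1-based census indices, strictly consecutive
    raw: np.ndarray
    start: int = 0  # offset of this fragment in the composite

    def __len__(self) -> int:
        return len(self.censuses)


@dataclass
class CompositeSeries:
    """A taxon's standardized values over the concatenated fragments."""

    taxon: str
    values: np.ndarray
    fragments: list[Fragment]
    ln_transformed: bool
    mean: float
    sd: float
    raw: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        total = sum(len(f) for f in self.fragments)
        if total != len(self.values):
            raise ValueError("fragment offsets do not tile the composite")
        pos = 0
        for f in self.fragments:
            if f.start != pos:
                raise ValueError("fragment offsets overlap or leave gaps")
            pos += len(f)

    def __len__(self) -> int:
        return len(self.values)

    def keys(self) -> list[tuple]:
        """(tank, treatment, year, census) for every composite position."""
        out = []
        for f in self.fragments:
            for c in f.censuses:
                out.append((f.tank_id, f.treatment, f.year, int(c)))
        return out

    def key_index(self) -> dict[tuple, int]:
        return {k: i for i, k in enumerate(self.keys())}

    def inverse_transform(self, values: np.ndarray | None = None) -> np.ndarray:
        """Map standardized values back to raw densities."""
        v = self.values if values is None else np.asarray(values)
        f = v * self.sd + self.mean
        if self.ln_transformed:
            return np.expm1(f)
        return f

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fid, f in enumerate(self.fragments):
            for j in range(len(f)):
                rows.append(
                    (self.taxon, fid, f.start + j, self.values[f.start + j])
                )
        return pd.DataFrame(rows, columns=["taxon", "fragment_id", "position", "value"])


def load_panel(path) -> CommunityPanel:
    """Read and validate a long-format density CSV.

    Expected columns: tank_id, treatment, year, census, taxon, raw_density.
    """
    df = pd.read_csv(path)
    return CommunityPanel(df)


def preprocess(
    panel: CommunityPanel, ln_exempt: frozenset | set | tuple = ("macrophytes",)
) -> dict[str, CompositeSeries]:
    """ln(x+1)-transform (except exempt taxa) and z-score each taxon's composite.

    Standardization is global over all fragments of a taxon, never
    per-fragment, so that a point's coordinate encodes where the community
    state sits relative to the whole experiment.
    """
    ln_exempt = set(ln_exempt)
    out: dict[str, CompositeSeries] = {}
    for taxon, g in panel.data.groupby("taxon"):
        fragments: list[Fragment] = []
        raw_parts = []
        pos = 0
        for (treat, tank, year), gf in g.groupby(
            ["treatment", "tank_id", "year"], sort=True
        ):
            gf = gf.sort_values("census")
            frag = Fragment(
                tank_id=tank,
                treatment=treat,
                year=int(year),
                censuses=gf["census"].to_numpy(),
                raw=gf["raw_density"].to_numpy(float),
                start=pos,
            )
            fragments.append(frag)
            raw_parts.append(frag.raw)
            pos += len(frag)
        raw = np.concatenate(raw_parts)
        use_ln = taxon not in ln_exempt
        f = np.log1p(raw) if use_ln else raw.copy()
        mu = float(f.mean())
        sd = float(f.std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"constant series for taxon {taxon!r}, not embeddable")
        out[taxon] = CompositeSeries(
            taxon=taxon,
            values=(f - mu) / sd,
            fragments=fragments,
            ln_transformed=use_ln,
            mean=mu,
            sd=sd,
            raw=raw,
        )
    return out


def per_capita_growth(fragment: Fragment) -> np.ndarray:
    """Per-capita growth ln((N_{t+1}+1)/(N_t+1)) within one fragment.

    The +1 offset keeps zero densities finite.  Growth is never computed
    across a fragment boundary: the caller supplies one fragment, and the
    result has length len(fragment) - 1.
    """
    if len(fragment) < 2:
        raise ValueError("fragment of length < 2 has no growth increments")
    n1 = fragment.raw + 1.0
    return np.log(n1[1:] / n1[:-1])


def growth_by_fragment(series: CompositeSeries) -> list[np.ndarray]:
    """Per-capita growth vectors for every fragment of a composite."""
    return [per_capita_growth(f) for f in series.fragments]


def composite_to_csv(composites: dict[str, CompositeSeries], path) -> None:
    pd.concat([c.to_frame() for c in composites.values()]).to_csv(path, index=False)


def transform_meta(composites: dict[str, CompositeSeries]) -> dict:
    """JSON-serializable record of transforms and fragment offsets."""
    meta = {}
    for taxon, c in composites.items():
        meta[taxon] = {
            "ln_transformed": c.ln_transformed,
            "mean": c.mean,
            "sd": c.sd,
            "fragments": [
                {
                    "tank_id": f.tank_id,
                    "treatment": f.treatment,
                    "year": f.year,
                    "start": int(f.start),
                    "length": len(f),
                    "first_census": int(f.censuses[0]),
                }
                for f in c.fragments
            ],
        }
    return meta
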