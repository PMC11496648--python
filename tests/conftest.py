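import numpy as np
import pandas as pd
import pytest

from mesoweb.data_model import CommunityPanel, preprocess
from mesoweb.state_space import select_embedding_dimension
from mesoweb.synthetic import coupled_logistic_panel, simulate_community


@pytest.fixture(scope="session")
def synthetic_run():
    """Default 10-taxon community, seed 1: panel, truth, composites, E."""
    panel, truth = simulate_community(seed=1)
    composites = preprocess(panel, ln_exempt=())
    E_map = {t: select_embedding_dimension(c)[0] for t, c in composites.items()}
    return {"panel": panel, "truth": truth, "composites": composites,
            "E_map": E_map}


@pytest.fixture(scope="session")
def logistic_pair():
    """Unidirectionally coupled logistic maps (x drives y), fragmented."""
    panel = coupled_logistic_panel(seed=3)
    composites = preprocess(panel, ln_exempt=())
    E_map = {t: select_embedding_dimension(c)[0] for t, c in composites.items()}
    return {"composites": composites, "E_map": E_map}


def panel_from_series(series_by_taxon: dict, n_fragments: int = 24,
                      fragment_length: int = 10) -> CommunityPanel:
    """Fold flat per-taxon value arrays into the study's fragment layout."""
    rows = []
    treatments = ("C", "I", "H", "IH")
    f = 0
    for year in range(1, 1 + n_fragments // 8):
        for treat in treatments:
            for rep in range(1, 3):
                tank = f"{treat}{rep}"
                for j in range(fragment_length):
                    for taxon, vals in series_by_taxon.items():
                        rows.append((tank, treat, year, j + 1, taxon,
                                     vals[f * fragment_length + j]))
                f += 1
    return CommunityPanel(pd.DataFrame(
        rows, columns=["tank_id", "treatment", "year", "census", "taxon",
                       "raw_density"]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
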