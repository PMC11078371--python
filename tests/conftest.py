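import numpy as np
import pandas as pd
import pytest

from taxodist import (
    default_scenario,
    gen_communities,
    gen_stations_env,
    gen_taxonomy,
    path_lengths,
)


@pytest.fixture
def toy_taxonomy() -> pd.DataFrame:
    """2 congeners + 1 confamilial + 1 other family, one class."""
    return pd.DataFrame(
        {
            "species": ["Alpha una", "Alpha dua", "Beta tri", "Gamma quat"],
            "genus": ["Alpha", "Alpha", "Beta", "Gamma"],
            "family": ["Famone", "Famone", "Famone", "Famtwo"],
            "class": ["Classa"] * 4,
        }
    )


@pytest.fixture
def toy_omega(toy_taxonomy):
    return path_lengths(toy_taxonomy)


@pytest.fixture
def toy_lineages() -> dict:
    return {
        "Alpha una": ("Alpha", "Famone"),
        "Alpha dua": ("Alpha", "Famone"),
        "Beta tri": ("Beta", "Famone"),
        "Gamma quat": ("Gamma", "Famtwo"),
    }


@pytest.fixture(scope="session")
def small_dataset():
    """25 stations x 50 species synthetic set shared across tests."""
    sc = default_scenario(
        seed=42, n_stations=25, n_species=50, n_genera=30, n_families=12
    )
    taxonomy = gen_taxonomy(sc)
    stations = gen_stations_env(sc)
    community, truth = gen_communities(taxonomy, stations, sc)
    return {
        "scenario": sc,
        "taxonomy": taxonomy,
        "stations": stations,
        "community": community,
        "truth": truth,
        "omega": path_lengths(taxonomy),
    }


def random_taxonomy(rng: np.random.Generator, n_species: int) -> pd.DataFrame:
    """Random strict-tree taxonomy helper (independent of synthetic_data)."""
    n_fam = max(2, n_species // 4)
    n_gen = max(n_fam, n_species // 2)
    genus_family = rng.integers(0, n_fam, size=n_gen)
    rows = []
    for s in range(n_species):
        g = int(rng.integers(0, n_gen))
        rows.append(
            {
                "species": f"Sp{s:03d} x",
                "genus": f"Gen{g:03d}",
                "family": f"Fam{genus_family[g]:03d}",
                "class": "Classa",
            }
        )
    return pd.DataFrame(rows)
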