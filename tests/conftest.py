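import numpy as np
import pandas as pd
import pytest

from mycospat.synthetic_forest import (
    PlantCensus,
    SimulationConfig,
    simulate_otu_tables,
    simulate_plant_map,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Six-species forest with one planted aggregated and one segregated pair."""
    return SimulationConfig(
        n_species=6,
        individuals_per_species=60,
        n_otus=120,
        root_depth=300,
        soil_depth=410,
        n_soil_samples=20,
        samples_per_species=8,
        pair_relationships={(0, 1): "aggregated", (2, 3): "segregated"},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_census(small_config) -> PlantCensus:
    return simulate_plant_map(small_config)


@pytest.fixture(scope="session")
def small_tables(small_config, small_census):
    return simulate_otu_tables(small_census, None, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def toy_census(points_by_species: dict[str, np.ndarray], window=(100.0, 100.0)) -> PlantCensus:
    rows = []
    k = 0
    for sp, pts in points_by_species.items():
        for x, y in pts:
            rows.append((f"i{k:03d}", sp, 5.0, float(x), float(y)))
            k += 1
    return PlantCensus(
        pd.DataFrame(rows, columns=["individual_id", "species", "dbh", "x", "y"]),
        window,
    )
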