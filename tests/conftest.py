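import numpy as np
import pandas as pd
import pytest

from enmflow import synth
from enmflow.grid import GridTransform, OccurrenceSet, RasterGrid
from enmflow.maxent import MaxentConfig


@pytest.fixture(scope="session")
def landscape():
    """60x60 landscape with three independent predictors (climate x2, topo)."""
    return synth.generate_env_stack(
        (60, 60), 3, np.eye(3), autocorr_range=3.0, seed=11,
        descriptor_map={"v1": "climate", "v2": "climate", "v3": "topography"},
    )


@pytest.fixture(scope="session")
def informative_template():
    return synth.SpeciesTemplate("informative", {"v1": (2.0, 0.0)}, prevalence=100)


@pytest.fixture(scope="session")
def occurrences(landscape, informative_template):
    return synth.generate_species_occurrences(landscape, informative_template, seed=21)


@pytest.fixture(scope="session")
def fast_config():
    return MaxentConfig(feature_class="LQ", n_background=2000, n_replicates=3)


@pytest.fixture()
def toy_grid():
    """4x4 grid with one nodata cell, unit degree cells."""
    vals = np.arange(16, dtype=float).reshape(4, 4)
    vals[3, 3] = -9999.0
    return RasterGrid(vals, GridTransform(0.0, 4.0, 1.0, 1.0))


def make_occ(grid, lons, lats, years=None, regions=None, species="sp"):
    n = len(lons)
    df = pd.DataFrame(
        {
            "lon": lons,
            "lat": lats,
            "year": years if years is not None else [2000] * n,
            "region": regions if regions is not None else [0] * n,
            "source_id": np.arange(n),
        }
    )
    return OccurrenceSet(species, df, grid)


@pytest.fixture()
def make_occurrence_set():
    return make_occ
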