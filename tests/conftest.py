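import numpy as np
import pandas as pd
import pytest

from floravision import (
    FlowerArchetype,
    SpectralDataset,
    Spectrum,
    build_viewer,
    d65,
    standard_grid,
)


@pytest.fixture(scope="session")
def grid():
    return standard_grid()


@pytest.fixture(scope="session")
def bee():
    return build_viewer("bee")


@pytest.fixture(scope="session")
def bird_vs():
    return build_viewer("bird_VS")


@pytest.fixture(scope="session")
def illuminant(grid):
    return d65(grid)


@pytest.fixture()
def gaussian_archetype():
    return FlowerArchetype(kind="gaussian_peak", center=450.0, width=40.0, amplitude=0.6, baseline=0.03)


@pytest.fixture()
def red_archetype():
    return FlowerArchetype(kind="longpass_sigmoid", center=620.0, width=15.0, amplitude=0.6, baseline=0.02)


def make_dataset(spectra_values: dict[str, np.ndarray], grid: np.ndarray, population: str = "p1",
                 species: str = "sp1", system: str = "Bee") -> SpectralDataset:
    """Small helper: dataset with every flower in one population."""
    spectra = {fid: Spectrum(fid, grid, v) for fid, v in spectra_values.items()}
    meta = pd.DataFrame(
        {
            "flower_id": list(spectra_values),
            "population_id": population,
            "species_code": species,
            "pollination_system": system,
        }
    )
    return SpectralDataset(spectra, meta)
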