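"""Pairwise color distances and the fraction-discriminable statistic.

For each population and viewer, every within-population flower pair is
compared in the viewer's color space; with n flowers there are
n(n-1)/2 unique pairs (105 for the standard sample of 15).  A pair is
*discriminable* when its color distance strictly exceeds the viewer's
behavioral threshold (ties at the threshold count as indiscriminable).
The proportion of discriminable pairs is the population's fraction
discriminable for that viewer — the unit of analysis for all downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colorspaces import color_point, hexagon_distance, rnl_distance
from .spectra_io import SpectralDataset
from .visual_systems import Illuminant, ViewerPhenotype, quantum_catches

__all__ = [
    "DistanceMatrix",
    "PopulationVariation",
    "pairwise_distances",
    "fraction_discriminable",
    "summarize_study",
    "study_means",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise color distances within one population."""

    population_id: str
    viewer_label: str
    flower_ids: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        n = len(self.flower_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match flower count")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0) or np.any(d < 0):
            raise ValueError("distances must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "distances", d)

    @property
    def n_flowers(self) -> int:
        return len(self.flower_ids)

    def pair_values(self) -> np.ndarray:
        """Unique off-diagonal distances (upper triangle, row-major)."""
        iu = np.triu_indices(self.n_flowers, k=1)
        return self.distances[iu]


@dataclass(frozen=True)
class PopulationVariation:
    """Fraction-discriminable summary of one population under one viewer."""

    population_id: str
    species_code: str
    pollination_system: str
    viewer_label: str
    n_flowers: int
    n_pairs: int
    n_discriminable: int
    fraction_discriminable: float

    def __post_init__(self) -> None:
        if self.n_pairs != self.n_flowers * (self.n_flowers - 1) // 2:
            raise ValueError("n_pairs must equal n_flowers choose 2")
        if not 0 <= self.n_discriminable <= self.n_pairs:
            raise ValueError("n_discriminable out of range")


def pairwise_distances(
    ds: SpectralDataset,
    population_id: str,
    v: ViewerPhenotype,
    ill: Illuminant,
) -> DistanceMatrix:
    """All pairwise color distances among one population's flowers.

    Distances are hexagon or RNL distances according to the viewer's
    model; reordering the flowers permutes rows/columns but leaves the
    multiset of pair distances unchanged.
    """
    flowers = ds.populations().get(population_id)
    if not flowers or len(flowers) < 2:
        raise ValueError(f"population {population_id!r} needs >= 2 flowers with spectra")
    catches = [quantum_catches(ds.spectra[f], v, ill) for f in flowers]
    n = len(flowers)
    d = np.zeros((n, n))
    if v.model == "hexagon":
        pts = [color_point(q, v) for q in catches]
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = hexagon_distance(pts[i], pts[j])
    else:
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = rnl_distance(catches[i], catches[j], v)
    return DistanceMatrix(population_id, v.label, tuple(flowers), d)


def fraction_discriminable(
    d: DistanceMatrix,
    threshold: float,
    species_code: str = "",
    pollination_system: str = "",
) -> PopulationVariation:
    """Count pairs whose distance strictly exceeds ``threshold``.

    The threshold itself is indiscriminable: a pair at exactly the
    threshold does not count.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if d.n_flowers < 2:
        raise ValueError("empty distance matrix")
    pairs = d.pair_values()
    n_disc = int(np.sum(pairs > threshold))
    return PopulationVariation(
        population_id=d.population_id,
        species_code=species_code,
        pollination_system=pollination_system,
        viewer_label=d.viewer_label,
        n_flowers=d.n_flowers,
        n_pairs=pairs.size,
        n_discriminable=n_disc,
        fraction_discriminable=n_disc / pairs.size,
    )


def summarize_study(
    ds: SpectralDataset,
    viewers: list[ViewerPhenotype],
    ill: Illuminant,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction discriminable for every population x viewer combination.

    Returns
    -------
    population_table : DataFrame
        One row per population x viewer with counts and the fraction.
    species_table : DataFrame
        Species-level mean and standard error of the fraction across that
        species' populations, per viewer.  The SE is NaN for species
        represented by a single population (undefined, no error bar).
    """
    rows = []
    for pop_id in ds.populations():
        species, system = ds.population_info(pop_id)
        for v in viewers:
            dm = pairwise_distances(ds, pop_id, v, ill)
            pv = fraction_discriminable(dm, v.threshold, species, system)
            rows.append(
                {
                    "population_id": pv.population_id,
                    "species_code": pv.species_code,
                    "pollination_system": pv.pollination_system,
                    "viewer": pv.viewer_label,
                    "n_flowers": pv.n_flowers,
                    "n_pairs": pv.n_pairs,
                    "n_discriminable": pv.n_discriminable,
                    "fraction_discriminable": pv.fraction_discriminable,
                }
            )
    pop_table = pd.DataFrame(rows)

    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    species_table = (
        pop_table.groupby(["species_code", "pollination_system", "viewer"], as_index=False)
        .agg(
            n_populations=("population_id", "nunique"),
            mean_fraction=("fraction_discriminable", "mean"),
            se_fraction=("fraction_discriminable", _se),
        )
    )
    return pop_table, species_table


def study_means(pop_table: pd.DataFrame, species_table: pd.DataFrame) -> pd.DataFrame:
    """Study-wide mean fraction per viewer, computed two ways.

    ``across_populations`` averages every population equally;
    ``across_species`` averages the species means (each species equally).
    Both are reported because they differ whenever species contribute
    unequal numbers of populations.
    """
    by_pop = pop_table.groupby("viewer")["fraction_discriminable"].mean()
    by_species = species_table.groupby("viewer")["mean_fraction"].mean()
    return pd.DataFrame(
        {"across_populations": by_pop, "across_species": by_species}
    ).reset_index()
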