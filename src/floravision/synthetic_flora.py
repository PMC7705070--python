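"""Synthetic floral reflectance datasets with field-study structure.

The generator emulates the sampling design of a mountain-meadow
pollination survey: many plant species, each classified by pollination
system, with 1-3 spatially separated populations per species and 15
flowers measured per population.  Two reflectance archetypes capture the
dominant floral signal classes:

``gaussian_peak``
    A single Gaussian reflectance band on a low baseline — the typical
    bee-pollinated flower signal (short/mid-wavelength peak, optionally
    with a UV reflectance bump).

``longpass_sigmoid``
    A sigmoidal long-pass edge — the "red" bird-pollinated flower
    signal, reflecting strongly at long wavelengths and, without a UV
    bump, essentially nothing below 400 nm (such flowers sit near the
    achromatic centre of bee color space).

Intrapopulation variation is produced by perturbing archetype
parameters with independent normal jitter (truncated to keep the
reflectance physically valid); between-population drift within a
species uses the same mechanism at a configurable scale, which is what
gives the study its nested species/population variance structure.
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .spectra_io import SpectralDataset, Spectrum
from .visual_systems import standard_grid

__all__ = [
    "UVBump",
    "FlowerArchetype",
    "ParameterJitter",
    "StudyConfig",
    "render_archetype",
    "simulate_population",
    "simulate_study",
    "default_study_config",
    "full_study_config",
]

#: Reflectance is clipped to this range after rendering (white-standard
#: overshoot slightly above 1 is physically plausible and kept).
REFLECTANCE_CAP = 1.2


@dataclass(frozen=True)
class UVBump:
    """Optional secondary UV reflectance peak of an archetype."""

    center: float = 350.0
    amplitude: float = 0.2
    width: float = 25.0


@dataclass(frozen=True)
class FlowerArchetype:
    """Parametric reflectance shape of one species' floral signal.

    ``center`` is the Gaussian peak centre or the sigmoid inflection
    point (nm); ``width`` is the Gaussian standard deviation or the
    sigmoid steepness scale (nm).
    """

    kind: str  # "gaussian_peak" | "longpass_sigmoid"
    center: float
    width: float
    amplitude: float
    baseline: float = 0.02
    uv_bump: UVBump | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_peak", "longpass_sigmoid"):
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude and baseline must be non-negative")
        if self.width <= 0:
            raise ValueError("width/steepness must be positive")


@dataclass(frozen=True)
class ParameterJitter:
    """Per-parameter normal jitter SDs for intrapopulation variation."""

    center_sd: float = 0.0
    width_sd: float = 0.0
    amplitude_sd: float = 0.0
    baseline_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.center_sd, self.width_sd, self.amplitude_sd, self.baseline_sd) < 0:
            raise ValueError("jitter SDs must be >= 0")

    def scaled(self, factor: float) -> "ParameterJitter":
        return ParameterJitter(
            self.center_sd * factor,
            self.width_sd * factor,
            self.amplitude_sd * factor,
            self.baseline_sd * factor,
        )


def render_archetype(a: FlowerArchetype, grid: np.ndarray | None = None, flower_id: str = "archetype") -> Spectrum:
    """Evaluate an archetype's reflectance on the working grid.

    gaussian_peak:     baseline + amplitude * exp(-(wl - center)^2 / (2 width^2))
    longpass_sigmoid:  baseline + amplitude / (1 + exp(-(wl - center) / width))

    plus the optional UV bump; the result is clipped to [0, 1.2].
    """
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)
    if not (grid[0] <= a.center <= grid[-1]):
        raise ValueError(f"archetype centre {a.center:g} nm outside the grid")
    if a.kind == "gaussian_peak":
        refl = a.baseline + a.amplitude * np.exp(-((grid - a.center) ** 2) / (2 * a.width**2))
    else:
        refl = a.baseline + a.amplitude / (1.0 + np.exp(-(grid - a.center) / a.width))
    if a.uv_bump is not None:
        b = a.uv_bump
        refl = refl + b.amplitude * np.exp(-((grid - b.center) ** 2) / (2 * b.width**2))
    return Spectrum(flower_id, grid, np.clip(refl, 0.0, REFLECTANCE_CAP))


def _perturb(a: FlowerArchetype, jitter: ParameterJitter, rng: np.random.Generator) -> FlowerArchetype:
    # truncate to keep parameters physically valid
    center = float(np.clip(a.center + rng.normal(0, jitter.center_sd) if jitter.center_sd else a.center, 305.0, 695.0))
    width = float(max(a.width + (rng.normal(0, jitter.width_sd) if jitter.width_sd else 0.0), 3.0))
    amplitude = float(np.clip(a.amplitude + (rng.normal(0, jitter.amplitude_sd) if jitter.amplitude_sd else 0.0), 0.0, REFLECTANCE_CAP))
    baseline = float(np.clip(a.baseline + (rng.normal(0, jitter.baseline_sd) if jitter.baseline_sd else 0.0), 0.0, 0.2))
    return replace(a, center=center, width=width, amplitude=amplitude, baseline=baseline)


def simulate_population(
    a: FlowerArchetype,
    jitter: ParameterJitter,
    n: int,
    seed: int,
    population_id: str = "pop1",
    species_code: str = "sp1",
    pollination_system: str = "Bee",
    grid: np.ndarray | None = None,
) -> SpectralDataset:
    """Draw ``n`` flowers from a population around one archetype.

    Each flower perturbs the archetype parameters with independent
    normal jitter and renders the result.  Reproducible: the same seed
    yields a bit-identical dataset.
    """
    if n < 2:
        raise ValueError("a population needs n >= 2 flowers")
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    spectra = {}
    rows = []
    for k in range(n):
        fid = f"{population_id}_f{k + 1:02d}"
        spectra[fid] = render_archetype(_perturb(a, jitter, rng), grid, fid)
        rows.append(
            {
                "flower_id": fid,
                "population_id": population_id,
                "species_code": species_code,
                "pollination_system": pollination_system,
            }
        )
    return SpectralDataset(spectra, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Whole-study simulation

#: Uniform ranges the species-level base parameters are drawn from.
SPECIES_PARAMETER_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "gaussian_peak": {
        "center": (380.0, 560.0),
        "width": (35.0, 60.0),
        "amplitude": (0.4, 0.8),
        "baseline": (0.02, 0.06),
    },
    "longpass_sigmoid": {
        "center": (600.0, 640.0),  # inflection
        "width": (10.0, 20.0),  # steepness
        "amplitude": (0.5, 0.8),
        "baseline": (0.01, 0.04),
    },
}

#: Probability that a bee-flower species carries a UV reflectance bump.
UV_BUMP_PROBABILITY = 0.3

#: Intrapopulation jitter SDs per archetype; the named default calibration.
DEFAULT_JITTER: dict[str, ParameterJitter] = {
    "gaussian_peak": ParameterJitter(center_sd=6.0, width_sd=3.0, amplitude_sd=0.06, baseline_sd=0.010),
    "longpass_sigmoid": ParameterJitter(center_sd=5.0, width_sd=4.0, amplitude_sd=0.10, baseline_sd=0.040),
}

#: Archetype used for each pollination system.
ARCHETYPE_BY_SYSTEM = {
    "Bee": "gaussian_peak",
    "Bee/Fly": "gaussian_peak",
    "Bee/Hawkmoth": "gaussian_peak",
    "Bee/Bird": "gaussian_peak",
    "Bird": "longpass_sigmoid",
}


@dataclass(frozen=True)
class StudyConfig:
    """Design of a synthetic study.

    ``n_species`` maps pollination-system label to species count;
    ``population_drift`` scales the intrapopulation jitter SDs to set
    how far population archetypes drift from their species archetype.
    ``population_variability`` is the log-normal sigma of a
    per-population multiplier on the jitter SDs: populations genuinely
    differ in how variable their flowers are, and because the same
    multiplier acts on every parameter it makes variation perceived by
    different viewers positively correlated across populations, as seen
    in field data.  Zero gives every population identical jitter.
    """

    n_species: Mapping[str, int] = field(default_factory=lambda: {"Bee": 24, "Bird": 7})
    populations_per_species: int = 2
    flowers_per_population: int = 15
    jitter: Mapping[str, ParameterJitter] = field(default_factory=lambda: dict(DEFAULT_JITTER))
    population_drift: float = 0.5
    population_variability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_species.values()):
            raise ValueError("species counts must be positive")
        if not 1 <= self.populations_per_species <= 3:
            raise ValueError("populations_per_species must be in 1..3")
        if self.flowers_per_population < 2:
            raise ValueError("flowers_per_population must be >= 2")
        if self.population_variability < 0:
            raise ValueError("population_variability must be >= 0")
        unknown = set(self.n_species) - set(ARCHETYPE_BY_SYSTEM)
        if unknown:
            raise ValueError(f"unknown pollination systems: {sorted(unknown)}")


def default_study_config(seed: int = 0, **overrides) -> StudyConfig:
    """The main-analysis design: 24 Bee + 7 Bird species, 2 populations each."""
    return StudyConfig(seed=seed, **overrides)


def full_study_config(seed: int = 0, **overrides) -> StudyConfig:
    """The full design including the mixed pollination systems (38 species)."""
    n_species = {"Bee": 24, "Bird": 7, "Bee/Fly": 4, "Bee/Hawkmoth": 1, "Bee/Bird": 2}
    return StudyConfig(n_species=n_species, seed=seed, **overrides)


def _draw_species_archetype(kind: str, rng: np.random.Generator) -> FlowerArchetype:
    r = SPECIES_PARAMETER_RANGES[kind]
    params = {name: float(rng.uniform(*bounds)) for name, bounds in r.items()}
    uv = None
    if kind == "gaussian_peak" and rng.random() < UV_BUMP_PROBABILITY:
        uv = UVBump(
            center=float(rng.uniform(330.0, 360.0)),
            amplitude=float(rng.uniform(0.1, 0.3)),
            width=float(rng.uniform(20.0, 35.0)),
        )
    return FlowerArchetype(kind=kind, uv_bump=uv, **params)


def simulate_study(c: StudyConfig, grid: np.ndarray | None = None) -> SpectralDataset:
    """Simulate a complete study dataset from a :class:`StudyConfig`.

    Species base parameters are drawn from documented uniform ranges per
    archetype; each population drifts from its species archetype by
    ``population_drift`` times the intrapopulation jitter, then flowers
    jitter independently around the population archetype.
    """
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(c.seed)
    spectra: dict[str, Spectrum] = {}
    meta = []
    sp_idx = 0
    for system in sorted(c.n_species):
        kind = ARCHETYPE_BY_SYSTEM[system]
        jitter = c.jitter.get(kind, ParameterJitter())
        drift = jitter.scaled(c.population_drift)
        for _ in range(c.n_species[system]):
            sp_idx += 1
            species = f"sp{sp_idx:02d}"
            base = _draw_species_archetype(kind, rng)
            for p in range(1, c.populations_per_species + 1):
                pop_id = f"{species}_p{p}"
                pop_archetype = _perturb(base, drift, rng)
                # mean-1 log-normal multiplier: some populations are
                # genuinely more variable than others, for every viewer
                sig = c.population_variability
                scale = float(rng.lognormal(-0.5 * sig**2, sig)) if sig > 0 else 1.0
                pop_seed = int(rng.integers(2**31))
                frag = simulate_population(
                    pop_archetype,
                    jitter.scaled(scale),
                    c.flowers_per_population,
                    pop_seed,
                    population_id=pop_id,
                    species_code=species,
                    pollination_system=system,
                    grid=grid,
                )
                spectra.update(frag.spectra)
                meta.append(frag.metadata)
    ds = SpectralDataset(spectra, pd.concat(meta, ignore_index=True))
    ds.validate()
    return ds
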