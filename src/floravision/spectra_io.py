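"""Reading, validation, cleaning and writing of floral reflectance spectra.

Spectra live on a wavelength grid in nm with reflectance expressed as a
proportion (0--1, with occasional white-standard overshoot above 1 kept
as-is).  The working range for all visual modeling is 300--700 nm; raw
field spectra are trimmed to that window, spurious negative readings are
clamped to zero, and everything is interpolated onto a common uniform
grid (1 nm by default) before any quantum-catch computation.

File formats
------------
Spectra travel as wide CSV: first column ``wl`` (wavelength, nm), one
column per flower.  Metadata is a long CSV with columns ``flower_id``,
``population_id``, ``species_code``, ``pollination_system``.  This
mirrors the de-facto layout of field-spectrometry exports, so deposited
datasets can be ingested unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "read_spectra",
    "write_spectra",
    "clean_spectrum",
    "clean_dataset",
    "POLLINATION_SYSTEMS",
    "WAVELENGTH_MIN",
    "WAVELENGTH_MAX",
]

WAVELENGTH_MIN = 300.0
WAVELENGTH_MAX = 700.0

#: Recognized pollination-system labels (single dominant group or mixed).
POLLINATION_SYSTEMS = ("Bee", "Bird", "Bee/Fly", "Bee/Bird", "Bee/Hawkmoth")

#: Column required in wide spectra CSVs for the wavelength axis.
WAVELENGTH_COLUMN = "wl"

METADATA_COLUMNS = ("flower_id", "population_id", "species_code", "pollination_system")

#: Auto-detection threshold: any reflectance above this is taken to mean
#: the file is in percent rather than proportion.
PERCENT_DETECTION_THRESHOLD = 1.5


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum.

    Parameters
    ----------
    flower_id : str
        Unique identifier of the measured flower.
    wavelengths : ndarray
        Strictly increasing wavelengths in nm.
    reflectance : ndarray
        Reflectance as a proportion, one value per wavelength.
    """

    flower_id: str
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or refl.ndim != 1 or wl.size != refl.size:
            raise ValueError(
                f"spectrum {self.flower_id!r}: wavelengths and reflectance "
                f"must be 1-D arrays of equal length"
            )
        if wl.size < 2:
            raise ValueError(f"spectrum {self.flower_id!r}: needs >= 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError(
                f"spectrum {self.flower_id!r}: wavelengths must be strictly increasing"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)

    @property
    def grid_step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def interpolate(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of reflectance onto ``grid`` (must be inside range)."""
        return np.interp(np.asarray(grid, dtype=float), self.wavelengths, self.reflectance)


@dataclass
class SpectralDataset:
    """A collection of spectra plus per-flower sample metadata.

    ``metadata`` has one row per flower with columns
    ``flower_id, population_id, species_code, pollination_system``.
    """

    spectra: dict[str, Spectrum] = field(default_factory=dict)
    metadata: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(METADATA_COLUMNS)))

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def flower_ids(self) -> list[str]:
        return list(self.spectra)

    @property
    def n_flowers(self) -> int:
        return len(self.spectra)

    def common_grid(self) -> np.ndarray:
        """The shared wavelength grid; raises if spectra disagree."""
        grids = {tuple(s.wavelengths) for s in self.spectra.values()}
        if len(grids) != 1:
            raise ValueError("spectra do not share a common wavelength grid")
        return np.asarray(next(iter(grids)), dtype=float)

    def validate(self, min_flowers_per_population: int = 2) -> None:
        """Check dataset invariants: metadata coverage, shared grid, population sizes."""
        meta_ids = set(self.metadata["flower_id"])
        orphans = sorted(set(self.spectra) - meta_ids)
        if orphans:
            raise ValueError(f"spectra lack metadata rows: {orphans}")
        unknown = sorted(set(self.metadata["pollination_system"]) - set(POLLINATION_SYSTEMS))
        if unknown:
            raise ValueError(f"unknown pollination systems: {unknown}")
        self.common_grid()
        counts = self.metadata[self.metadata["flower_id"].isin(self.spectra)]
        sizes = counts.groupby("population_id")["flower_id"].nunique()
        small = sizes[sizes < min_flowers_per_population]
        if len(small):
            raise ValueError(
                f"populations with fewer than {min_flowers_per_population} flowers: "
                f"{sorted(small.index)}"
            )

    def subset(self, flower_ids: Iterable[str]) -> "SpectralDataset":
        ids = list(flower_ids)
        missing = [f for f in ids if f not in self.spectra]
        if missing:
            raise KeyError(f"flowers not in dataset: {missing}")
        meta = self.metadata[self.metadata["flower_id"].isin(ids)].copy()
        return SpectralDataset({f: self.spectra[f] for f in ids}, meta)

    def populations(self) -> dict[str, list[str]]:
        """Mapping population_id -> ordered flower ids present in the spectra."""
        out: dict[str, list[str]] = {}
        for row in self.metadata.itertuples():
            if row.flower_id in self.spectra:
                out.setdefault(row.population_id, []).append(row.flower_id)
        return out

    def population_info(self, population_id: str) -> tuple[str, str]:
        """(species_code, pollination_system) of a population."""
        rows = self.metadata[self.metadata["population_id"] == population_id]
        if rows.empty:
            raise KeyError(f"unknown population: {population_id!r}")
        return str(rows.iloc[0]["species_code"]), str(rows.iloc[0]["pollination_system"])

    def to_wide_frame(self) -> pd.DataFrame:
        grid = self.common_grid()
        data = {WAVELENGTH_COLUMN: grid}
        for fid, s in self.spectra.items():
            data[fid] = s.reflectance
        return pd.DataFrame(data)


def read_spectra(
    path: str | Path,
    metadata_path: str | Path,
    units: str = "auto",
) -> SpectralDataset:
    """Read a wide spectra CSV and its metadata CSV into a raw dataset.

    Reflectance columns are auto-rescaled from percent to proportion when
    any value exceeds 1.5 (``units='auto'``); pass ``units='percent'`` or
    ``units='proportion'`` to override the heuristic.

    Raises
    ------
    ValueError
        On duplicate flower ids, flowers missing from the metadata, or a
        non-monotone wavelength column.
    """
    if units not in ("auto", "percent", "proportion"):
        raise ValueError(f"units must be auto|percent|proportion, got {units!r}")
    wide = pd.read_csv(path)
    if wide.columns[0] != WAVELENGTH_COLUMN:
        raise ValueError(
            f"first column of spectra CSV must be {WAVELENGTH_COLUMN!r}, "
            f"got {wide.columns[0]!r}"
        )
    flower_cols = list(wide.columns[1:])
    dupes = sorted({c for c in flower_cols if flower_cols.count(c) > 1})
    if dupes:
        raise ValueError(f"duplicate flower ids in spectra CSV: {dupes}")
    wl = wide[WAVELENGTH_COLUMN].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength column is not strictly increasing")

    meta = pd.read_csv(metadata_path, dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata CSV missing columns: {missing_cols}")
    meta_ids = set(meta["flower_id"])
    orphans = sorted(set(flower_cols) - meta_ids)
    if orphans:
        raise ValueError(f"flowers present in spectra but absent from metadata: {orphans}")

    values = wide[flower_cols].to_numpy(dtype=float)
    if units == "percent" or (units == "auto" and np.nanmax(values) > PERCENT_DETECTION_THRESHOLD):
        values = values / 100.0

    spectra = {
        fid: Spectrum(fid, wl, values[:, j]) for j, fid in enumerate(flower_cols)
    }
    meta = meta[meta["flower_id"].isin(flower_cols)].reset_index(drop=True)
    return SpectralDataset(spectra, meta)


def write_spectra(
    ds: SpectralDataset,
    path: str | Path,
    metadata_path: str | Path | None = None,
    decimals: int = 6,
) -> None:
    """Write a dataset back to wide-CSV (+ metadata CSV); round-trips with read_spectra."""
    wide = ds.to_wide_frame()
    wide.to_csv(path, index=False, float_format=f"%.{decimals}f")
    if metadata_path is not None:
        ds.metadata.loc[:, list(METADATA_COLUMNS)].to_csv(metadata_path, index=False)


def clean_spectrum(s: Spectrum, grid_step: float = 1.0) -> Spectrum:
    """Trim to 300--700 nm, clamp negative readings to zero, regrid.

    The output lies on the uniform grid ``300:700:grid_step`` obtained by
    linear interpolation.  Values above 1 (white-standard overshoot) are
    kept; only negatives are replaced by zero.  Idempotent on already
    clean spectra.

    Raises
    ------
    ValueError
        If the raw spectrum does not cover the full 300--700 nm window.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    lo, hi = float(s.wavelengths[0]), float(s.wavelengths[-1])
    gaps = []
    if lo > WAVELENGTH_MIN:
        gaps.append(f"[{WAVELENGTH_MIN:g}, {lo:g}) nm")
    if hi < WAVELENGTH_MAX:
        gaps.append(f"({hi:g}, {WAVELENGTH_MAX:g}] nm")
    if gaps:
        raise ValueError(
            f"spectrum {s.flower_id!r} does not cover 300-700 nm; missing {', '.join(gaps)}"
        )
    n = int(round((WAVELENGTH_MAX - WAVELENGTH_MIN) / grid_step))
    grid = WAVELENGTH_MIN + grid_step * np.arange(n + 1)
    refl = np.interp(grid, s.wavelengths, s.reflectance)
    refl = np.maximum(refl, 0.0)
    return Spectrum(s.flower_id, grid, refl)


def clean_dataset(ds: SpectralDataset, grid_step: float = 1.0) -> SpectralDataset:
    """Apply :func:`clean_spectrum` to every spectrum of a dataset."""
    cleaned = {fid: clean_spectrum(s, grid_step) for fid, s in ds.spectra.items()}
    return SpectralDataset(cleaned, ds.metadata.copy())
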