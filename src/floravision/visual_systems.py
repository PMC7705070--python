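"""Viewer phenotypes, receptor sensitivities, illuminants and quantum catches.

A viewer phenotype bundles everything needed to map a reflectance
spectrum into a perceptual color space: an ordered set of receptor
sensitivity curves, their relative densities, a noise level (Weber
fraction), the color-space model (bee hexagon or avian
receptor-noise-limited space) with its discrimination threshold, and the
adaptation background.

Receptor quantum catches are computed as

    Q_i = integral over 300-700 nm of R(lambda) I(lambda) S_i(lambda)

(trapezoid rule on the working grid) and adapted by von Kries
normalization to the background, q_i = Q_i / Q_i^background, so a
stimulus identical to the background has q = 1 in every receptor.

Sensitivities default to the Govardovskii A1 visual-pigment nomogram
(alpha plus beta band) evaluated at the phenotype's lambda_max values;
the default phenotypes live in ``data/viewers.yaml`` and every field can
be overridden at construction time or replaced by curves loaded from
file.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .spectra_io import Spectrum, WAVELENGTH_MAX, WAVELENGTH_MIN

__all__ = [
    "ReceptorSensitivity",
    "Illuminant",
    "ViewerPhenotype",
    "QuantumCatchVector",
    "standard_grid",
    "pigment_template",
    "d65",
    "flat_illuminant",
    "flat_background",
    "load_viewer_defaults",
    "build_viewer",
    "quantum_catches",
]

#: Default constant reflectance of the achromatic adaptation background.
#: A neutral grey of foliage-like albedo; the von Kries step makes the
#: background the achromatic reference point regardless of this level.
DEFAULT_BACKGROUND_REFLECTANCE = 0.3


def standard_grid(step: float = 1.0) -> np.ndarray:
    """The working wavelength grid, 300..700 nm inclusive."""
    n = int(round((WAVELENGTH_MAX - WAVELENGTH_MIN) / step))
    return WAVELENGTH_MIN + step * np.arange(n + 1)


@dataclass(frozen=True)
class ReceptorSensitivity:
    """A photoreceptor spectral sensitivity curve, unit peak, on a grid."""

    name: str
    wavelengths: np.ndarray
    curve: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        cv = np.asarray(self.curve, dtype=float)
        if wl.shape != cv.shape:
            raise ValueError("wavelengths and curve must have the same shape")
        if np.any(cv < 0):
            raise ValueError(f"receptor {self.name!r}: negative sensitivity values")
        peak = cv.max()
        if peak <= 0:
            raise ValueError(f"receptor {self.name!r}: identically zero curve")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "curve", cv / peak)

    @property
    def lambda_peak(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.curve))])


@dataclass(frozen=True)
class Illuminant:
    """Relative quantum irradiance per nm on the working grid."""

    name: str
    wavelengths: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ir = np.asarray(self.irradiance, dtype=float)
        if wl.shape != ir.shape:
            raise ValueError("wavelengths and irradiance must have the same shape")
        if np.any(ir < 0) or not np.any(ir > 0):
            raise ValueError(f"illuminant {self.name!r}: irradiance must be non-negative and not all zero")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "irradiance", ir)


@dataclass(frozen=True)
class ViewerPhenotype:
    """A complete visual phenotype for color-space modeling."""

    label: str
    receptors: tuple[ReceptorSensitivity, ...]
    relative_densities: tuple[float, ...]
    weber_fraction: float
    model: str  # "hexagon" | "rnl"
    threshold: float
    background: Spectrum

    def __post_init__(self) -> None:
        if self.model not in ("hexagon", "rnl"):
            raise ValueError(f"unknown model {self.model!r}")
        if len(self.relative_densities) != len(self.receptors):
            raise ValueError("one relative density per receptor required")
        if any(d <= 0 for d in self.relative_densities):
            raise ValueError("receptor densities must be positive")
        if self.weber_fraction <= 0:
            raise ValueError("Weber fraction must be positive")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def n_receptors(self) -> int:
        return len(self.receptors)

    @property
    def receptor_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.receptors)


@dataclass(frozen=True)
class QuantumCatchVector:
    """Von-Kries-adapted receptor quantum catches of one flower."""

    flower_id: str
    viewer_label: str
    q: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))


# ---------------------------------------------------------------------------
# Pigment nomogram

def _govardovskii_a1(lambda_max: float, wl: np.ndarray) -> np.ndarray:
    # alpha band
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    # beta band
    b_max = 189.0 + 0.315 * lambda_max
    d = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - b_max) / d) ** 2))
    return alpha + beta


def pigment_template(
    lambda_max: float, grid: np.ndarray | None = None, name: str | None = None
) -> ReceptorSensitivity:
    """A1 visual-pigment nomogram sensitivity, normalized to unit peak.

    Produces a smooth unimodal curve (alpha band plus the short-wavelength
    beta band) whose maximum falls within one grid step of ``lambda_max``.
    Deterministic: the same inputs always give bit-identical curves.
    """
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)
    if not (grid[0] <= lambda_max <= grid[-1]):
        raise ValueError(
            f"lambda_max={lambda_max:g} nm outside the grid "
            f"[{grid[0]:g}, {grid[-1]:g}] nm"
        )
    # The beta band skews the summed template slightly short of the nominal
    # peak (up to ~2 nm for UV pigments); recentre by fixed-point correction
    # on a fine grid so the realized peak is at lambda_max.
    fine = np.arange(max(grid[0], lambda_max - 60.0), min(grid[-1], lambda_max + 60.0), 0.05)
    lm_eff = float(lambda_max)
    for _ in range(3):
        peak = fine[int(np.argmax(_govardovskii_a1(lm_eff, fine)))]
        lm_eff += lambda_max - peak
    curve = _govardovskii_a1(lm_eff, grid)
    return ReceptorSensitivity(name or f"pigment{lambda_max:g}", grid, curve)


def sensitivities_from_file(path: str | Path, grid: np.ndarray | None = None) -> tuple[ReceptorSensitivity, ...]:
    """Load receptor curves from a CSV (first column wl, one column per receptor)."""
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)
    df = pd.read_csv(path)
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        curve = np.interp(grid, wl, df[col].to_numpy(dtype=float))
        out.append(ReceptorSensitivity(str(col), grid, curve))
    return tuple(out)


# ---------------------------------------------------------------------------
# Illuminants and backgrounds

def _data_path(name: str):
    return resources.files("floravision").joinpath("data", name)


def d65(grid: np.ndarray | None = None) -> Illuminant:
    """CIE D65 standard daylight, in relative quanta on the working grid.

    The bundled table is spectral power (energy); it is converted to
    relative photon counts (multiplied by wavelength) and peak-normalized,
    since photoreceptors count photons.
    """
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)
    with resources.as_file(_data_path("d65.csv")) as p:
        table = pd.read_csv(p)
    energy = np.interp(grid, table["wl"].to_numpy(float), table["irradiance"].to_numpy(float))
    quanta = energy * grid
    return Illuminant("D65", grid, quanta / quanta.max())


def flat_illuminant(grid: np.ndarray | None = None) -> Illuminant:
    """Equal-quanta (flat) illuminant; mainly for tests and diagnostics."""
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)
    return Illuminant("flat", grid, np.ones_like(grid))


def flat_background(
    reflectance: float = DEFAULT_BACKGROUND_REFLECTANCE, grid: np.ndarray | None = None
) -> Spectrum:
    """Flat achromatic adaptation background of constant reflectance."""
    if reflectance <= 0:
        raise ValueError("background reflectance must be positive")
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)
    return Spectrum("background", grid, np.full_like(grid, float(reflectance)))


# ---------------------------------------------------------------------------
# Viewer construction

def load_viewer_defaults() -> dict:
    """The packaged default phenotype parameters (see ``data/viewers.yaml``)."""
    with resources.as_file(_data_path("viewers.yaml")) as p:
        return yaml.safe_load(p.read_text())


def build_viewer(
    label: str,
    *,
    lambda_max: Sequence[float] | None = None,
    relative_densities: Sequence[float] | None = None,
    weber_fraction: float | None = None,
    threshold: float | None = None,
    background: Spectrum | None = None,
    sensitivity_file: str | Path | None = None,
    grid: np.ndarray | None = None,
) -> ViewerPhenotype:
    """Construct a viewer phenotype from the packaged defaults plus overrides.

    ``label`` is one of ``bee``, ``bird_VS``, ``bird_UVS`` (or any key added
    to the viewer config file).  The bee is a trichromat evaluated in the
    color hexagon with threshold 0.11 hexagon units; the birds are
    tetrachromats evaluated in the receptor-noise-limited space with
    threshold 1 JND, Weber fraction 0.1 and relative densities 1:2:2:4.
    """
    defaults = load_viewer_defaults()
    if label not in defaults:
        raise ValueError(f"unknown viewer label {label!r}; known: {sorted(defaults)}")
    cfg = defaults[label]
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)

    if sensitivity_file is not None:
        receptors = sensitivities_from_file(sensitivity_file, grid)
    else:
        peaks = list(cfg["lambda_max"] if lambda_max is None else lambda_max)
        names = cfg.get("receptor_names") or [f"r{i}" for i in range(len(peaks))]
        if len(names) != len(peaks):
            names = [f"r{i}" for i in range(len(peaks))]
        receptors = tuple(
            pigment_template(lm, grid, name=nm) for nm, lm in zip(names, peaks)
        )

    densities = relative_densities if relative_densities is not None else cfg.get(
        "relative_densities", [1.0] * len(receptors)
    )
    weber = weber_fraction if weber_fraction is not None else cfg.get("weber_fraction", 0.1)
    thr = threshold if threshold is not None else cfg["threshold"]
    bg = background if background is not None else flat_background(grid=grid)
    return ViewerPhenotype(
        label=label,
        receptors=receptors,
        relative_densities=tuple(float(d) for d in densities),
        weber_fraction=float(weber),
        model=cfg["model"],
        threshold=float(thr),
        background=bg,
    )


# ---------------------------------------------------------------------------
# Quantum catches

def _raw_catches(refl: np.ndarray, v: ViewerPhenotype, ill: Illuminant, grid: np.ndarray) -> np.ndarray:
    out = np.empty(v.n_receptors)
    for i, rec in enumerate(v.receptors):
        out[i] = np.trapezoid(refl * ill.irradiance * rec.curve, grid)
    return out


def quantum_catches(s: Spectrum, v: ViewerPhenotype, ill: Illuminant) -> QuantumCatchVector:
    """Von-Kries-adapted quantum catches of a cleaned spectrum.

    Raises if the wavelength grids of spectrum, viewer and illuminant
    disagree, or if the adaptation background yields a zero catch in any
    receptor (the normalization would be undefined).
    """
    grid = s.wavelengths
    for rec in v.receptors:
        if rec.wavelengths.shape != grid.shape or not np.allclose(rec.wavelengths, grid):
            raise ValueError("receptor sensitivities are not on the spectrum grid")
    if ill.wavelengths.shape != grid.shape or not np.allclose(ill.wavelengths, grid):
        raise ValueError("illuminant is not on the spectrum grid")
    if v.background.wavelengths.shape != grid.shape or not np.allclose(v.background.wavelengths, grid):
        raise ValueError("adaptation background is not on the spectrum grid")

    q_raw = _raw_catches(s.reflectance, v, ill, grid)
    q_bg = _raw_catches(v.background.reflectance, v, ill, grid)
    if np.any(q_bg <= 0):
        bad = [v.receptors[i].name for i in np.flatnonzero(q_bg <= 0)]
        raise ValueError(f"background gives zero quantum catch in receptors {bad}")
    return QuantumCatchVector(s.flower_id, v.label, q_raw / q_bg)
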