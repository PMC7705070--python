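"""Color spaces: the bee color hexagon and the receptor-noise-limited space.

Bee hexagon
-----------
Adapted catches q are transformed to receptor excitations by the
half-maximal hyperbolic response E = q / (q + 1), so the adaptation
background (q = 1) maps to E = 0.5 and the hexagon centre.  For the
receptor order (uv, blue, green) the chromaticity coordinates are

    x = (sqrt(3)/2) (E_green - E_uv)
    y = E_blue - (E_uv + E_green) / 2

Hue is the radial angle atan2(y, x); saturation (spectral purity) is the
Euclidean distance from the (0, 0) origin.  All achievable points lie in
the closed hexagon of circumradius 1, so saturation is in [0, 1].
Distances are plain Euclidean distances in (x, y); bees discriminate a
pair only beyond a behavioral threshold, conventionally 0.11 hexagon
units.

Receptor-noise-limited (RNL) space
----------------------------------
Receptor contrasts between stimuli a and b are log ratios of adapted
catches, df_i = ln(q_i^a / q_i^b).  Channel noise is set by the Weber
fraction of the most abundant receptor class and scales with the inverse
square root of relative density:

    e_i = w * sqrt(eta_max / eta_i)

The chromatic distance dS (in just-noticeable-difference units) is the
standard noise-weighted Euclidean distance; for a tetrachromat

    dS^2 = sum over pairs i<j of (prod of e_k for k not in {i,j})^2 (df_j - df_i)^2
           -------------------------------------------------------------------
           sum over triples {i,j,k} of (e_i e_j e_k)^2

implemented here for any receptor count n >= 2 (the dichromat special
case reduces to |df_1 - df_2| / sqrt(e_1^2 + e_2^2)).  One JND is the
conventional discrimination threshold for diurnal birds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import prod

import numpy as np

from .visual_systems import QuantumCatchVector, ViewerPhenotype

__all__ = [
    "ColorPoint",
    "NoiseVector",
    "hexagon_point",
    "hexagon_distance",
    "rnl_noise",
    "rnl_distance",
    "rnl_saturation",
    "color_point",
]

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class ColorPoint:
    """A stimulus located in a viewer's color space."""

    flower_id: str
    space: str  # "hexagon" | "rnl"
    coords: np.ndarray
    hue: float | None = None
    saturation: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))


@dataclass(frozen=True)
class NoiseVector:
    """Per-receptor noise standard deviations e_i of an RNL viewer."""

    e: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=float)
        if np.any(e <= 0):
            raise ValueError("noise values must be positive")
        object.__setattr__(self, "e", e)


def hexagon_point(q: QuantumCatchVector) -> ColorPoint:
    """Map adapted catches of a trichromat (uv, blue, green) into the hexagon."""
    qv = q.q
    if qv.shape != (3,):
        raise ValueError(f"hexagon model needs 3 receptors, got {qv.shape[0]}")
    if np.any(qv < 0):
        raise ValueError("quantum catches must be non-negative")
    e = qv / (qv + 1.0)
    e_uv, e_b, e_g = e
    x = _SQRT3_2 * (e_g - e_uv)
    y = e_b - (e_uv + e_g) / 2.0
    return ColorPoint(
        flower_id=q.flower_id,
        space="hexagon",
        coords=np.array([x, y]),
        hue=float(np.arctan2(y, x)),
        saturation=float(np.hypot(x, y)),
    )


def hexagon_distance(a: ColorPoint, b: ColorPoint) -> float:
    """Euclidean distance between two hexagon points, in hexagon units."""
    if a.space != "hexagon" or b.space != "hexagon":
        raise ValueError(f"expected two hexagon points, got {a.space!r} and {b.space!r}")
    return float(np.hypot(*(a.coords - b.coords)))


def rnl_noise(v: ViewerPhenotype) -> NoiseVector:
    """Receptor noise e_i = w * sqrt(eta_max / eta_i).

    Noise is proportional to the Weber fraction and independent of the
    magnitude of receptor stimulation; the densest receptor class attains
    e = w exactly.
    """
    if v.model != "rnl":
        raise ValueError(f"viewer {v.label!r} is not a receptor-noise-limited viewer")
    eta = np.asarray(v.relative_densities, dtype=float)
    if np.any(eta <= 0):
        raise ValueError("receptor densities must be positive")
    return NoiseVector(v.weber_fraction * np.sqrt(eta.max() / eta))


def _rnl_delta_s(df: np.ndarray, e: np.ndarray) -> float:
    n = df.size
    if n < 2:
        raise ValueError("RNL distance needs at least 2 receptors")
    idx = range(n)
    num = 0.0
    for i, j in combinations(idx, 2):
        others = prod(e[k] for k in idx if k not in (i, j))
        num += (others ** 2) * (df[j] - df[i]) ** 2
    den = sum(
        prod(e[k] for k in subset) ** 2 for subset in combinations(idx, n - 1)
    )
    return float(np.sqrt(num / den))


def rnl_distance(
    qa: QuantumCatchVector, qb: QuantumCatchVector, v: ViewerPhenotype
) -> float:
    """Chromatic distance dS between two stimuli, in JND units.

    Uses log receptor contrasts, so the distance is invariant to scaling
    both stimuli's catches by a common factor and depends only on
    differences between receptor contrasts.
    """
    if qa.q.shape != qb.q.shape or qa.q.shape[0] != v.n_receptors:
        raise ValueError("catch vectors do not match the viewer's receptor count")
    if np.any(qa.q <= 0) or np.any(qb.q <= 0):
        raise ValueError("RNL contrasts need strictly positive quantum catches")
    df = np.log(qa.q / qb.q)
    return _rnl_delta_s(df, rnl_noise(v).e)


def rnl_saturation(q: QuantumCatchVector, v: ViewerPhenotype) -> float:
    """RNL distance of a stimulus from the adaptation background (JND units).

    The background is the achromatic point of the adapted space (q = 1 in
    every receptor), so its distance is the natural saturation analogue
    for an RNL viewer.
    """
    if np.any(q.q <= 0):
        raise ValueError("RNL saturation needs strictly positive quantum catches")
    df = np.log(q.q)
    return _rnl_delta_s(df, rnl_noise(v).e)


def color_point(q: QuantumCatchVector, v: ViewerPhenotype) -> ColorPoint:
    """Locate a stimulus in the viewer's own space (hexagon or RNL).

    For an RNL viewer the coordinates are the log contrasts to the
    background and saturation is :func:`rnl_saturation`; hue is defined
    only in the hexagon.
    """
    if v.model == "hexagon":
        return hexagon_point(q)
    if np.any(q.q <= 0):
        raise ValueError("RNL coordinates need strictly positive quantum catches")
    df = np.log(q.q)
    return ColorPoint(
        flower_id=q.flower_id,
        space="rnl",
        coords=df,
        hue=None,
        saturation=rnl_saturation(q, v),
    )
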