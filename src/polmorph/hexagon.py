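"""Hexagon colour space for hymenopteran trichromats.

Photoreceptor quantum catches are computed as illuminant x sensitivity x
reflectance integrals, normalized von Kries-style by the catch from the
adaptation background, so the background itself always maps to unit catch.
Excitations E = P/(P+1) then place a stimulus in the colour hexagon:

    x = (sqrt(3)/2) (E_G - E_UV)
    y = E_B - (E_UV + E_G)/2

with UV at lower-left, green at lower-right and blue at top. The adapted
background sits at the origin; colour contrast is the Euclidean distance of
a locus from the origin and green contrast is |E_G - 0.5|, the achromatic
long-wavelength signal bees use to detect small targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import (
    STANDARD_GRID,
    ReceptorSet,
    Spectrum,
    flat_background,
    illuminant_d65,
    receptor_set,
    resample,
)

__all__ = [
    "QuantumCatch",
    "HexLocus",
    "quantum_catch",
    "excitation",
    "hexagon_locus",
    "locus_from_reflectance",
    "color_contrast",
    "green_contrast",
    "pairwise_distances",
]

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class QuantumCatch:
    """Receptor catches relative to the adaptation background (unitless)."""

    p_uv: float
    p_b: float
    p_g: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_uv, self.p_b, self.p_g)


@dataclass
class HexLocus:
    """A stimulus locus in the colour hexagon."""

    e_uv: float
    e_b: float
    e_g: float
    label: str = ""
    part: str = "other"  # sepal | labellum | other
    category: int | None = None
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        for e in (self.e_uv, self.e_b, self.e_g):
            if not 0.0 <= e < 1.0:
                raise ValueError("excitations must lie in [0, 1)")
        if self.part not in ("sepal", "labellum", "other"):
            raise ValueError(f"unknown part {self.part!r}")
        self.x = _SQRT3_2 * (self.e_g - self.e_uv)
        self.y = self.e_b - (self.e_uv + self.e_g) / 2.0


def quantum_catch(
    reflectance: Spectrum,
    receptors: ReceptorSet | None = None,
    illuminant: Spectrum | None = None,
    background: Spectrum | None = None,
) -> QuantumCatch:
    """Von Kries-adapted quantum catches P_i for the three receptor classes.

    P_i = integral(I S_i R) / integral(I S_i R_b), trapezoidal rule on the
    10 nm standard grid. All four spectra must cover 300-650 nm.
    """
    receptors = receptors if receptors is not None else receptor_set()
    illuminant = illuminant if illuminant is not None else illuminant_d65()
    background = background if background is not None else flat_background()
    for s, what in ((reflectance, "reflectance"), (illuminant, "illuminant"), (background, "background")):
        if not s.covers():
            raise ValueError(f"{what} spectrum does not cover 300-650 nm")
    grid = STANDARD_GRID
    refl = resample(reflectance, grid).values
    illum = resample(illuminant, grid).values
    bg = resample(background, grid).values
    catches = []
    for cls in ("UV", "B", "G"):
        sens = resample(receptors[cls], grid).values
        denom = np.trapezoid(illum * sens * bg, grid)
        if denom <= 0.0:
            raise ValueError("degenerate adaptation: zero background catch")
        catches.append(float(np.trapezoid(illum * sens * refl, grid) / denom))
    return QuantumCatch(*catches)


def excitation(p: QuantumCatch) -> tuple[float, float, float]:
    """Receptor excitations E_i = P_i / (P_i + 1), each in [0, 1)."""
    vals = p.as_tuple()
    if any(v < 0 for v in vals):
        raise ValueError("quantum catches must be non-negative")
    return tuple(v / (v + 1.0) for v in vals)


def hexagon_locus(
    e,
    label: str = "",
    part: str = "other",
    category: int | None = None,
) -> HexLocus:
    """Build a hexagon locus from an (E_UV, E_B, E_G) triple."""
    e_uv, e_b, e_g = (float(v) for v in e)
    return HexLocus(e_uv, e_b, e_g, label=label, part=part, category=category)


def locus_from_reflectance(
    reflectance: Spectrum,
    receptors: ReceptorSet | None = None,
    illuminant: Spectrum | None = None,
    background: Spectrum | None = None,
    part: str = "other",
    category: int | None = None,
) -> HexLocus:
    """Full pipeline: reflectance -> catches -> excitations -> locus."""
    e = excitation(quantum_catch(reflectance, receptors, illuminant, background))
    return hexagon_locus(e, label=reflectance.name, part=part, category=category)


def color_contrast(locus: HexLocus) -> float:
    """Hexagon distance of a locus from the adapted background (origin)."""
    return float(np.hypot(locus.x, locus.y))


def green_contrast(e) -> float:
    """Achromatic green-receptor contrast |E_G - 0.5|."""
    e_g = e.e_g if isinstance(e, HexLocus) else float(e)
    return abs(e_g - 0.5)


def pairwise_distances(loci: list[HexLocus]) -> pd.DataFrame:
    """Labelled symmetric matrix of Euclidean hexagon distances between loci."""
    if len(loci) < 2:
        raise ValueError("need at least two loci")
    labels = [lc.label for lc in loci]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate locus labels")
    xy = np.array([[lc.x, lc.y] for lc in loci])
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    return pd.DataFrame(d, index=labels, columns=labels)
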