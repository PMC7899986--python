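"""Synthetic inputs with the statistical structure the analyses assume.

Each generator is bit-reproducible under a fixed seed and targets the study
conditions observed in the Deep Lead *Caladenia* population: flower-like
reflectance spectra (UV-absorbing long-pass tepals, long-wavelength crimson
labella), multi-year category x patch fruiting records with the observed
category proportions and per-patch fruiting rates, binary marker matrices
with a controlled expected phi_PT, and Jukes-Cantor-evolved alignments on a
star topology with chosen within/between-group divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markers import Alignment, MarkerMatrix
from .repro import PlantRecord
from .spectra import STANDARD_GRID, Spectrum

__all__ = [
    "SpectrumParams",
    "PopulationParams",
    "tepal_params",
    "labellum_params",
    "gen_spectrum",
    "gen_plant_records",
    "gen_marker_matrix",
    "gen_alignment",
]

#: Observed flower-colour category proportions in the unbiased census years.
CATEGORY_PROBS = (0.21, 0.26, 0.30, 0.15, 0.08)
#: Flower distribution over patches in the natural-pollination years.
PATCH_PROBS = tuple(np.array([35, 24, 10, 16, 49]) / 134.0)
#: Per-patch fruiting probabilities (fruits/flowers in the monitored years);
#: pooled over PATCH_PROBS these give the observed 15.7% overall fruit set.
PATCH_FRUIT_PROBS = (11 / 35, 6 / 24, 1 / 10, 1 / 16, 2 / 49)


@dataclass
class SpectrumParams:
    """Shape parameters of a synthetic flower reflectance curve.

    The curve is baseline + a sigmoidal long-pass edge (the step-up around
    400 nm typical of UV-absorbing yellow-green tepals) + Gaussian bumps for
    crimson (long-wavelength) and UV reflectance, plus Gaussian noise,
    clipped to [0, 1.2].
    """

    baseline: float = 0.05
    edge_nm: float = 400.0
    edge_steepness_nm: float = 15.0
    edge_amplitude: float = 0.0
    red_center_nm: float = 640.0
    red_width_nm: float = 50.0
    red_amplitude: float = 0.0
    uv_center_nm: float = 350.0
    uv_width_nm: float = 25.0
    uv_amplitude: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for nm in (self.edge_nm, self.red_center_nm, self.uv_center_nm):
            if not 300.0 <= nm <= 650.0:
                raise ValueError("spectral features must lie within 300-650 nm")


def tepal_params(noise_sd: float = 0.005) -> SpectrumParams:
    """Yellow-green tepal: UV-absorbing long-pass edge near 400 nm."""
    return SpectrumParams(
        baseline=0.05, edge_nm=400.0, edge_steepness_nm=15.0, edge_amplitude=0.45,
        red_amplitude=0.10, noise_sd=noise_sd,
    )


def labellum_params(noise_sd: float = 0.005) -> SpectrumParams:
    """Crimson labellum: low mid-range reflectance with a long-wavelength rise."""
    return SpectrumParams(
        baseline=0.04, edge_amplitude=0.0, red_center_nm=640.0, red_width_nm=45.0,
        red_amplitude=0.35, noise_sd=noise_sd,
    )


def gen_spectrum(params: SpectrumParams, seed: int | None = None, name: str = "synthetic") -> Spectrum:
    """Deterministic (under seed) synthetic reflectance on the standard grid."""
    rng = np.random.default_rng(seed)
    wl = STANDARD_GRID
    shape = params.baseline + params.edge_amplitude / (
        1.0 + np.exp(-(wl - params.edge_nm) / params.edge_steepness_nm)
    )
    shape = shape + params.red_amplitude * np.exp(
        -(((wl - params.red_center_nm) / params.red_width_nm) ** 2)
    )
    shape = shape + params.uv_amplitude * np.exp(
        -(((wl - params.uv_center_nm) / params.uv_width_nm) ** 2)
    )
    if params.noise_sd:
        shape = shape + rng.normal(0.0, params.noise_sd, wl.size)
    return Spectrum(wl, np.clip(shape, 0.0, 1.2), "reflectance", name)


@dataclass
class PopulationParams:
    """Sampling design for synthetic tagged-plant records."""

    n_plants: int = 67  # per year
    years: tuple = (2003, 2004)
    category_probs: tuple = CATEGORY_PROBS
    patch_probs: tuple = PATCH_PROBS
    patch_fruit_probs: tuple = PATCH_FRUIT_PROBS
    category_fruit_multipliers: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, probs in (("category", self.category_probs), ("patch", self.patch_probs)):
            probs = np.asarray(probs, dtype=float)
            if probs.size != 5 or np.any(probs < 0) or np.any(probs > 1):
                raise ValueError(f"{name} probabilities must be five values in [0,1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")


def gen_plant_records(pop_params: PopulationParams) -> list[PlantRecord]:
    """Independent category/patch/fruiting draws per plant-year, unique ids."""
    rng = np.random.default_rng(pop_params.seed)
    records = []
    for year in pop_params.years:
        cats = rng.choice(5, size=pop_params.n_plants, p=pop_params.category_probs) + 1
        patches = rng.choice(5, size=pop_params.n_plants, p=pop_params.patch_probs) + 1
        u = rng.random(pop_params.n_plants)
        for i in range(pop_params.n_plants):
            p_fruit = (
                pop_params.patch_fruit_probs[patches[i] - 1]
                * pop_params.category_fruit_multipliers[cats[i] - 1]
            )
            records.append(
                PlantRecord(
                    plant_id=f"Y{year}-{i + 1:04d}",
                    year=int(year),
                    category=int(cats[i]),
                    patch=int(patches[i]),
                    fruited=bool(u[i] < p_fruit),
                    treatment="natural",
                )
            )
    return records


def gen_marker_matrix(
    n_pops: int = 2,
    n_per_pop: int = 30,
    n_loci: int = 100,
    differentiation_level: float = 0.0,
    seed: int | None = None,
) -> MarkerMatrix:
    """Binary band matrix with expected AMOVA phi_PT ~ differentiation_level.

    Calibration: individual band values are Bernoulli(p_pop) draws, so the
    within-population variance component per locus is E[p(1-p)] and the
    among-population component is Var(p). Drawing p_pop around a shared mean
    p-bar with Var(p) = t * p-bar(1-p-bar) makes the total variance
    p-bar(1-p-bar) (the within component shrinks by exactly Var(p)), hence
    expected phi = t. Clipping to [0.01, 0.99] makes the mapping approximate
    at extreme frequencies.
    """
    if not 0.0 <= differentiation_level < 1.0:
        raise ValueError("differentiation_level must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p_bar = rng.uniform(0.2, 0.8, size=n_loci)
    sd = np.sqrt(differentiation_level * p_bar * (1.0 - p_bar))
    p_pop = np.clip(
        p_bar[None, :] + rng.normal(0.0, 1.0, size=(n_pops, n_loci)) * sd[None, :],
        0.01,
        0.99,
    )
    data = np.vstack(
        [rng.random((n_per_pop, n_loci)) < p_pop[g][None, :] for g in range(n_pops)]
    ).astype(np.int8)
    individuals = [
        f"pop{g + 1}_ind{i + 1:03d}" for g in range(n_pops) for i in range(n_per_pop)
    ]
    populations = [f"pop{g + 1}" for g in range(n_pops) for _ in range(n_per_pop)]
    return MarkerMatrix(data, individuals, populations)


def _jc_mutate(seq: np.ndarray, branch_length: float, rng) -> np.ndarray:
    """Evolve a sequence along one branch under the Jukes-Cantor model."""
    p_sub = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    out = seq.copy()
    hit = rng.random(seq.size) < p_sub
    idx = np.flatnonzero(hit)
    if idx.size:
        # substitute with one of the three other bases, uniformly
        cur = np.searchsorted(bases, out[idx])
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = bases[(cur + shift) % 4]
    return out


def gen_alignment(
    n_groups: int = 3,
    n_per_group: int = 4,
    length: int = 1000,
    d_within: float = 0.0,
    d_between: float = 0.0,
    seed: int | None = None,
) -> Alignment:
    """Star-topology Jukes-Cantor simulation targeting expected distances.

    Tip branch length is d_within/2 (so two tips of one group are d_within
    apart in expectation) and the root-to-group-ancestor branch is
    (d_between - d_within)/2, making cross-group tips d_between apart.
    Requires d_between >= d_within and both below JC saturation.
    """
    if d_between < d_within:
        raise ValueError("d_between must be >= d_within")
    for d in (d_within, d_between):
        if not 0.0 <= d < 0.75:
            raise ValueError("expected distances must lie in [0, 0.75)")
    rng = np.random.default_rng(seed)
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    root = bases[rng.integers(0, 4, size=length)]
    tip_branch = d_within / 2.0
    anc_branch = (d_between - d_within) / 2.0
    ids, groups, rows = [], [], []
    for g in range(n_groups):
        ancestor = _jc_mutate(root, anc_branch, rng)
        for i in range(n_per_group):
            ids.append(f"g{g + 1}_s{i + 1:02d}")
            groups.append(f"g{g + 1}")
            rows.append(_jc_mutate(ancestor, tip_branch, rng))
    return Alignment(ids, groups, np.vstack(rows))
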