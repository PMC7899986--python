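"""Spectral curves and the fixed ingredients of the bee-vision pipeline.

Everything downstream of this module works on :class:`Spectrum` objects:
flower reflectances read from delimited text, the CIE D65 illuminant
converted to relative photon flux, a flat achromatic adaptation background,
and honeybee photoreceptor sensitivity curves built from a visual-pigment
absorbance template.

The working wavelength window is 300-650 nm, the range over which flower
reflectance was measured at 10 nm steps; all integrations downstream use the
trapezoidal rule on this grid.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "STANDARD_GRID",
    "Spectrum",
    "ReceptorSet",
    "read_spectra",
    "write_spectra",
    "resample",
    "photon_flux",
    "illuminant_d65",
    "receptor_set",
    "flat_background",
]

#: 300-650 nm at 10 nm steps: the measurement grid of the reflectance data.
STANDARD_GRID = np.arange(300.0, 651.0, 10.0)

#: Default honeybee photoreceptor peak sensitivities (nm).
DEFAULT_LAMBDA_MAX = {"UV": 344.0, "B": 436.0, "G": 544.0}


@dataclass
class Spectrum:
    """A wavelength-indexed curve.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm.
    values
        Unitless values: reflectance fraction relative to the white standard,
        relative photon flux, or relative sensitivity, depending on ``kind``.
    kind
        One of ``reflectance``, ``illuminant``, ``sensitivity``.
    name
        Sample identifier (free text).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    name: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if self.wavelengths.size != self.values.size:
            raise ValueError("wavelengths and values differ in length")
        if self.wavelengths.size < 1:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite spectral values")
        if self.kind not in ("reflectance", "illuminant", "sensitivity"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "reflectance" and np.any(self.values < 0):
            raise ValueError(
                "negative reflectance; clean input first (read_spectra clips)"
            )

    def covers(self, lo: float = 300.0, hi: float = 650.0) -> bool:
        """Whether the grid spans [lo, hi] nm (required by the vision pipeline)."""
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavelengths.copy(), self.values.copy(), self.kind, self.name)


@dataclass
class ReceptorSet:
    """Sensitivity curves for the three honeybee receptor classes (UV, B, G)."""

    sensitivities: dict = field(default_factory=dict)  # class -> Spectrum
    lambda_max: dict = field(default_factory=dict)  # class -> nm

    def __post_init__(self) -> None:
        if set(self.sensitivities) != {"UV", "B", "G"}:
            raise ValueError("exactly three receptor classes UV, B, G required")
        for cls, spec in self.sensitivities.items():
            peak = np.interp(self.lambda_max[cls], spec.wavelengths, spec.values)
            if abs(peak - 1.0) > 1e-9:
                raise ValueError(f"{cls} sensitivity does not peak at 1.0 at lambda_max")

    def __getitem__(self, cls: str) -> Spectrum:
        return self.sensitivities[cls]


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_spectra(path) -> list[Spectrum]:
    """Read spectra from delimited text (comma or tab autodetected).

    The first column is the wavelength in nm, each further column one sample.
    Negative values are clipped to 0 with a warning; non-numeric cells,
    duplicate or non-increasing wavelengths are rejected naming the offending
    row.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(lines) < 3:
        raise ValueError(f"{path}: too few rows for a spectrum file")
    delim = _sniff_delimiter(lines[0])
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter=delim)
    header = next(reader)
    names = [h.strip() for h in header[1:]]
    if not names:
        raise ValueError(f"{path}: no sample columns")
    rows = []
    for i, row in enumerate(reader, start=2):
        vals = []
        for j, cell in enumerate(row):
            try:
                vals.append(float(cell))
            except ValueError:
                col = header[j] if j < len(header) else f"column {j + 1}"
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} in row {i} ({col})"
                ) from None
        rows.append((i, vals))
    wl = np.array([v[0] for _, v in rows])
    for k in range(1, len(wl)):
        if wl[k] == wl[k - 1]:
            raise ValueError(f"{path}: duplicate wavelength {wl[k]:g} at row {rows[k][0]}")
        if wl[k] < wl[k - 1]:
            raise ValueError(f"{path}: non-increasing wavelength at row {rows[k][0]}")
    data = np.array([v[1:] for _, v in rows])
    if data.shape[1] != len(names):
        raise ValueError(f"{path}: ragged rows")
    n_neg = int(np.sum(data < 0))
    if n_neg:
        warnings.warn(f"{path}: clipped {n_neg} negative reflectance value(s) to 0")
        data = np.clip(data, 0.0, None)
    return [Spectrum(wl, data[:, j], "reflectance", name) for j, name in enumerate(names)]


def write_spectra(path, spectra: list[Spectrum], delimiter: str = ",") -> None:
    """Write spectra sharing one grid to delimited text (inverse of read_spectra)."""
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("all spectra must share one wavelength grid")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["wavelength_nm"] + [s.name or f"s{i}" for i, s in enumerate(spectra)])
        for k in range(wl.size):
            w.writerow([f"{wl[k]:g}"] + [repr(float(s.values[k])) for s in spectra])


def resample(spectrum: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < spectrum.wavelengths[0] or grid[-1] > spectrum.wavelengths[-1]:
        raise ValueError(
            f"resample would extrapolate: requested [{grid[0]:g}, {grid[-1]:g}] nm, "
            f"source covers [{spectrum.wavelengths[0]:g}, {spectrum.wavelengths[-1]:g}] nm"
        )
    vals = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return Spectrum(grid, vals, spectrum.kind, spectrum.name)


def photon_flux(power: Spectrum) -> Spectrum:
    """Convert a spectral power distribution to relative photon flux.

    Photon energy is hc/lambda, so photon flux is proportional to power times
    wavelength; physical constants are dropped because they cancel under the
    von Kries normalization applied downstream.
    """
    return Spectrum(
        power.wavelengths, power.values * power.wavelengths, "illuminant", power.name
    )


def _load_d65_power() -> Spectrum:
    ref = resources.files("polmorph.data").joinpath("cie_d65_300_650.csv")
    wl, vals = [], []
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0] == "wavelength_nm":
                continue
            wl.append(float(row[0]))
            vals.append(float(row[1]))
    return Spectrum(np.array(wl), np.array(vals), "illuminant", "D65")


def illuminant_d65() -> Spectrum:
    """CIE D65 daylight on 300-650 nm as relative photon flux, 1.0 at 550 nm."""
    flux = photon_flux(_load_d65_power())
    anchor = np.interp(550.0, flux.wavelengths, flux.values)
    return Spectrum(flux.wavelengths, flux.values / anchor, "illuminant", "D65")


def _pigment_template(wl: np.ndarray, lmax: float) -> np.ndarray:
    """Rhodopsin (A1) absorbance template parameterized only by lambda-max.

    Alpha band: Govardovskii-style log-normal-like form in x = lmax/lambda;
    beta band: Gaussian at 189 + 0.315*lmax. The curve is normalized so the
    value at lmax is exactly 1.
    """
    wl = np.asarray(wl, dtype=float)

    def raw(lam):
        x = lmax / lam
        a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
        alpha = 1.0 / (
            np.exp(69.7 * (a - x))
            + np.exp(28.0 * (0.922 - x))
            + np.exp(-14.9 * (1.104 - x))
            + 0.674
        )
        b_amp = 0.26
        lm_beta = 189.0 + 0.315 * lmax
        b_width = -40.5 + 0.195 * lmax
        beta = b_amp * np.exp(-(((lam - lm_beta) / b_width) ** 2))
        return alpha + beta

    return raw(wl) / raw(np.array([lmax]))[0]


def receptor_set(lambda_max: dict | None = None) -> ReceptorSet:
    """Build honeybee UV/B/G sensitivity curves from the pigment template.

    Each curve is tabulated at 1 nm over 300-650 nm (with lambda-max inserted
    if fractional) and peaks at exactly 1.0 at its lambda-max.
    """
    lambda_max = dict(DEFAULT_LAMBDA_MAX if lambda_max is None else lambda_max)
    if set(lambda_max) != {"UV", "B", "G"}:
        raise ValueError("lambda_max must give UV, B and G peaks")
    sens = {}
    for cls, lmax in lambda_max.items():
        lmax = float(lmax)
        if not 300.0 <= lmax <= 650.0:
            raise ValueError(f"{cls} lambda_max {lmax:g} nm outside the 300-650 nm grid")
        grid = np.union1d(np.arange(300.0, 651.0), [lmax])
        sens[cls] = Spectrum(grid, _pigment_template(grid, lmax), "sensitivity", cls)
    return ReceptorSet(sens, lambda_max)


def flat_background(level: float = 0.10) -> Spectrum:
    """Constant achromatic adaptation background (default 10% reflectance)."""
    if not 0.0 < level <= 1.0:
        raise ValueError("background level must be in (0, 1]")
    return Spectrum(
        STANDARD_GRID, np.full(STANDARD_GRID.size, float(level)), "reflectance",
        f"flat{level:g}",
    )
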