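"""Opsin spectral sensitivities and opsin-effective photon-flux arithmetic.

Spectral sensitivity curves are generated from the Govardovskii A1
visual-pigment template (alpha plus beta band) at a configurable peak
wavelength, corrected for prereceptoral (lens) filtering, and integrated
against light spectra to produce opsin-effective photon fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "SpectralCurve",
    "Opsin",
    "LensFilter",
    "DEFAULT_LAMBDA_MAX",
    "default_grid",
    "default_lens",
    "govardovskii_a1",
    "nomogram_sensitivity",
    "effective_flux",
    "michelson_contrast",
    "read_spectrum",
    "write_spectrum",
]

#: Peak sensitivities (nm) of the four opsin classes handled throughout.
DEFAULT_LAMBDA_MAX = {"S": 365.0, "L": 556.0, "rod": 498.0, "mel": 480.0}


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly ascending wavelength sample points in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelength grid contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if wl[0] < 200.0 or wl[-1] > 1000.0:
            raise ValueError("wavelength grid must lie within 200-1000 nm")
        object.__setattr__(self, "wavelengths", wl)

    @property
    def lo(self) -> float:
        return float(self.wavelengths[0])

    @property
    def hi(self) -> float:
        return float(self.wavelengths[-1])

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class SpectralCurve:
    """Nonnegative values sampled on a wavelength grid.

    Values are either photon flux densities (photons/cm^2/s/nm) or unitless
    relative sensitivities; the arithmetic below does not care which.
    """

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.wavelengths.shape:
            raise ValueError("values and grid must have the same length")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectral values must be finite")
        if np.any(v < 0):
            raise ValueError("spectral values must be nonnegative")
        object.__setattr__(self, "values", v)

    def resample(self, grid: WavelengthGrid) -> "SpectralCurve":
        """Linear interpolation onto another grid (0 outside support)."""
        v = np.interp(grid.wavelengths, self.grid.wavelengths, self.values,
                      left=0.0, right=0.0)
        return SpectralCurve(grid, v)

    def scaled(self, factor: float) -> "SpectralCurve":
        return SpectralCurve(self.grid, self.values * factor)


@dataclass(frozen=True)
class Opsin:
    """A photopigment described by its A1-template peak wavelength."""

    name: str
    lambda_max: float = 0.0
    template_class: str = "A1"

    def __post_init__(self):
        if self.lambda_max == 0.0:
            if self.name not in DEFAULT_LAMBDA_MAX:
                raise ValueError(f"unknown opsin {self.name!r}: give lambda_max")
            object.__setattr__(self, "lambda_max", DEFAULT_LAMBDA_MAX[self.name])
        if self.template_class != "A1":
            raise ValueError("only the A1 template is supported")


@dataclass(frozen=True)
class LensFilter:
    """Prereceptoral transmission as a fraction per wavelength."""

    grid: WavelengthGrid
    transmission: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.transmission, dtype=float)
        if t.shape != self.grid.wavelengths.shape:
            raise ValueError("transmission and grid must have the same length")
        if np.any(t < 0) or np.any(t > 1) or not np.all(np.isfinite(t)):
            raise ValueError("transmission must lie in [0, 1]")
        object.__setattr__(self, "transmission", t)

    def resample(self, grid: WavelengthGrid) -> "LensFilter":
        t = np.interp(grid.wavelengths, self.grid.wavelengths, self.transmission)
        return LensFilter(grid, np.clip(t, 0.0, 1.0))


def default_grid(lo: float = 330.0, hi: float = 700.0, step: float = 1.0) -> WavelengthGrid:
    n = int(round((hi - lo) / step)) + 1
    return WavelengthGrid(np.linspace(lo, hi, n))


def default_lens(grid: WavelengthGrid | None = None,
                 midpoint_nm: float = 330.0,
                 width_nm: float = 15.0) -> LensFilter:
    """Smooth parametric stand-in for a UV-transmitting mouse lens.

    A logistic rise centred in the near-UV: transmission is ~0.5 at the
    midpoint and saturates at 1 through the visible range. Users with a
    measured lens table should build a :class:`LensFilter` from it instead.
    """
    grid = grid or default_grid()
    t = 1.0 / (1.0 + np.exp(-(grid.wavelengths - midpoint_nm) / width_nm))
    return LensFilter(grid, t)


def govardovskii_a1(wavelengths_nm: np.ndarray, lambda_max: float) -> np.ndarray:
    """Govardovskii et al. A1 pigment template (alpha + beta band), peak ~1.

    Parameters are those of the standard A1 template: the alpha band is a
    sum-of-exponentials sigmoid in x = lambda_max / lambda, and the beta
    band a Gaussian in wavelength whose position and width scale with
    lambda_max.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    x = lambda_max / wl
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)

    A_beta = 0.26
    lam_beta = 189.0 + 0.315 * lambda_max
    d_beta = -40.5 + 0.195 * lambda_max
    beta = A_beta * np.exp(-(((wl - lam_beta) / d_beta) ** 2))
    return alpha + beta


def nomogram_sensitivity(opsin: Opsin, grid: WavelengthGrid | None = None) -> SpectralCurve:
    """Relative spectral sensitivity of an opsin on a grid, normalized to peak 1.

    The peak of the returned curve is exactly 1 at the grid point closest to
    ``lambda_max`` (the raw template maximum is renormalized to the grid).
    """
    grid = grid or default_grid()
    if not (grid.lo <= opsin.lambda_max <= grid.hi):
        raise ValueError(
            f"lambda_max {opsin.lambda_max} nm outside grid "
            f"[{grid.lo}, {grid.hi}] nm")
    s = govardovskii_a1(grid.wavelengths, opsin.lambda_max)
    return SpectralCurve(grid, s / s.max())


def effective_flux(spectrum: SpectralCurve, sensitivity: SpectralCurve,
                   lens: LensFilter | None = None) -> float:
    """Opsin-effective photon flux: trapezoid of spectrum x sensitivity x lens.

    All inputs are resampled by linear interpolation onto the spectrum's
    grid. Grids that do not overlap are rejected.
    """
    grid = spectrum.grid
    if sensitivity.grid.hi < grid.lo or sensitivity.grid.lo > grid.hi:
        raise ValueError("sensitivity grid does not overlap the spectrum grid")
    sens = sensitivity.resample(grid).values
    if lens is None:
        trans = np.ones(len(grid))
    else:
        trans = lens.resample(grid).transmission
    integrand = spectrum.values * sens * trans
    return float(np.trapezoid(integrand, grid.wavelengths))


def michelson_contrast(bright: float, dim: float) -> float:
    """Signed Michelson contrast (bright - dim) / (bright + dim).

    Negative when ``dim > bright``. Rejects the degenerate both-zero case.
    """
    if bright < 0 or dim < 0:
        raise ValueError("fluxes must be nonnegative")
    total = bright + dim
    if total == 0:
        raise ValueError("Michelson contrast undefined for two zero fluxes")
    return (bright - dim) / total


def read_spectrum(path) -> SpectralCurve:
    """Read a two-column (wavelength_nm, value) text table.

    Whitespace- or comma-delimited; ``#`` comments ignored; an optional
    non-numeric header line is skipped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except (ValueError, IndexError):
                if rows:
                    raise ValueError(f"malformed spectrum line: {line!r}")
                continue  # header
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0])
    return SpectralCurve(WavelengthGrid(arr[order, 0]), arr[order, 1])


def write_spectrum(curve: SpectralCurve, path, header: str = "wavelength_nm,value") -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for wl, v in zip(curve.grid.wavelengths, curve.values):
            fh.write(f"{wl:.6g},{v:.10g}\n")
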