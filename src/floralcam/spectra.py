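"""Wavelength grids, sampled spectra, quadrature and daylight illuminants.

The quantities of interest are all sampled functions of wavelength: surface
reflectance R(lambda) as a fraction of a perfect diffuser, and relative
spectral power E(lambda) of an illuminant (arbitrary scale).  A camera
channel's response to a surface is an integral of products of such curves, so
everything downstream reduces to resampling onto a common grid and
trapezoidal integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._cie_data import CIE_S_COMPONENTS, CIE_S_WAVELENGTHS_NM

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "DEFAULT_GRID",
    "resample",
    "integrate",
    "cie_daylight_spd",
    "flat_spectrum",
    "TruncationWarning",
    "SuperWhiteWarning",
]


class TruncationWarning(UserWarning):
    """Resampling requested outside the source spectrum's support."""


class SuperWhiteWarning(UserWarning):
    """A reflectance spectrum exceeds the white standard by more than 5%."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid ``start, start+step, ..., stop`` in nm."""

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValueError("start_nm must be < stop_nm")
        if not self.step_nm > 0:
            raise ValueError("step_nm must be positive")
        n = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "step_nm must divide the interval exactly: "
                f"({self.start_nm}, {self.stop_nm}, {self.step_nm})"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1


#: Working grid covering both cameras' sensitivity range with margin.
DEFAULT_GRID = WavelengthGrid(300.0, 710.0, 1.0)


@dataclass(frozen=True, eq=False)
class Spectrum:
    """Values sampled on a :class:`WavelengthGrid`.

    ``kind`` is ``"reflectance"`` (fraction of a perfect diffuser, values
    expected in [0, ~1.05]) or ``"power"`` (relative spectral power,
    arbitrary nonnegative scale).
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.grid),):
            raise ValueError(
                f"values length {values.shape} does not match grid length "
                f"{len(self.grid)}"
            )
        if np.any(values < 0):
            raise ValueError("spectrum values must be nonnegative")
        if self.kind == "reflectance" and np.any(values > 1.05):
            warnings.warn(
                "reflectance exceeds 1.05 (above white standard); kept as-is",
                SuperWhiteWarning,
                stacklevel=2,
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def __mul__(self, other: "Spectrum | float") -> "Spectrum":
        if isinstance(other, Spectrum):
            if other.grid != self.grid:
                raise ValueError("grid mismatch in spectrum product")
            return Spectrum(self.grid, self.values * other.values, kind="power")
        return Spectrum(self.grid, self.values * float(other), kind=self.kind)

    __rmul__ = __mul__


def flat_spectrum(value: float, grid: WavelengthGrid = DEFAULT_GRID,
                  kind: str = "reflectance") -> Spectrum:
    """Spectrally flat curve, e.g. an ideal achromatic standard."""
    return Spectrum(grid, np.full(len(grid), float(value)), kind=kind)


def resample(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    Outside the source support values are set to 0 and a
    :class:`TruncationWarning` is issued; extrapolation is never attempted.
    """
    src = spectrum.wavelengths
    tgt = target.wavelengths
    if tgt[-1] < src[0] or tgt[0] > src[-1]:
        raise ValueError(
            f"no overlap between source grid [{src[0]}, {src[-1]}] nm and "
            f"target grid [{tgt[0]}, {tgt[-1]}] nm"
        )
    outside = (tgt < src[0]) | (tgt > src[-1])
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} target wavelengths outside the source "
            f"support [{src[0]}, {src[-1]}] nm were set to 0",
            TruncationWarning,
            stacklevel=2,
        )
    values = np.interp(tgt, src, spectrum.values, left=0.0, right=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SuperWhiteWarning)
        return Spectrum(target, values, kind=spectrum.kind)


def integrate(spectrum: Spectrum) -> float:
    """Trapezoidal integral over the grid, in value * nm."""
    if len(spectrum.grid) < 2:
        raise ValueError("integration requires at least 2 grid points")
    return float(np.trapezoid(spectrum.values, spectrum.wavelengths))


def _daylight_chromaticity(cct_kelvin: float) -> tuple[float, float]:
    t = cct_kelvin
    if t <= 7000.0:
        x = (0.244063 + 0.09911e3 / t + 2.9678e6 / t**2 - 4.6070e9 / t**3)
    else:
        x = (0.237040 + 0.24748e3 / t + 1.9018e6 / t**2 - 2.0064e9 / t**3)
    y = -3.000 * x * x + 2.870 * x - 0.275
    return x, y


def cie_daylight_spd(cct_kelvin: float, grid: WavelengthGrid = DEFAULT_GRID,
                     *, apply_cct_correction: bool = True) -> Spectrum:
    """Relative SPD of a CIE daylight-series illuminant at a nominal CCT.

    The SPD is the mean daylight component plus two characteristic vectors
    weighted by factors derived from the daylight-locus chromaticity, then
    normalised to 100 at 560 nm.  ``apply_cct_correction`` rescales the
    nominal CCT by 1.4388/1.4380 (the radiation-constant revision under which
    nominal 6500 K daylight is defined, i.e. D65 is computed at ~6504 K).
    """
    if not 4000.0 <= cct_kelvin <= 25000.0:
        raise ValueError("cct_kelvin must be within [4000, 25000] K")
    t = cct_kelvin * (1.4388 / 1.4380) if apply_cct_correction else cct_kelvin
    x, y = _daylight_chromaticity(t)
    m = 0.0241 + 0.2562 * x - 0.7341 * y
    m1 = (-1.3515 - 1.7703 * x + 5.9114 * y) / m
    m2 = (0.0300 - 31.4424 * x + 30.0717 * y) / m
    spd10 = (CIE_S_COMPONENTS[:, 0]
             + m1 * CIE_S_COMPONENTS[:, 1]
             + m2 * CIE_S_COMPONENTS[:, 2])
    # normalise on the native 10 nm table (560 nm is a table node), then
    # interpolate to the requested grid
    spd10 = 100.0 * spd10 / spd10[CIE_S_WAVELENGTHS_NM == 560.0][0]
    values = np.interp(grid.wavelengths, CIE_S_WAVELENGTHS_NM, spd10)
    return Spectrum(grid, np.clip(values, 0.0, None), kind="power")
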