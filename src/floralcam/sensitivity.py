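"""Gaussian-sum spectral-sensitivity models for camera colour channels.

A channel's relative spectral sensitivity S(lambda) is modelled as a sum of
one or two Gaussian terms

    S(lambda) = sum_k a_k * exp(-((lambda - b_k) / c_k)**2)

with amplitude a_k, centre b_k (nm) and width c_k (nm).  Fitting selects the
two-term form over the one-term form only when every coefficient of the
richer model is individually significant (its 95% confidence interval
excludes zero), so the extra term must earn its place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .spectra import Spectrum, WavelengthGrid, integrate

__all__ = [
    "GaussianTerm",
    "ChannelSensitivity",
    "evaluate_sensitivity",
    "normalise_sensitivity",
    "fit_sensitivity",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when no sensitivity or transfer model could be fitted."""


@dataclass(frozen=True)
class GaussianTerm:
    amplitude: float
    centre_nm: float
    width_nm: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")
        if not 250.0 <= self.centre_nm <= 800.0:
            raise ValueError("centre_nm must lie within 250-800 nm")

    def __call__(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavelengths_nm, float) - self.centre_nm) / self.width_nm
        return self.amplitude * np.exp(-z * z)


@dataclass(frozen=True, eq=False)
class ChannelSensitivity:
    """One- or two-term Gaussian sensitivity model for one colour channel.

    ``coefficient_ci`` optionally carries a 95% confidence interval
    ``(lo, hi)`` per coefficient in the order (a1, b1, c1[, a2, b2, c2]).
    """

    channel_id: str
    terms: tuple[GaussianTerm, ...]
    coefficient_ci: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.terms) <= 2:
            raise ValueError("a channel uses 1 or 2 Gaussian terms")
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def coefficients(self) -> np.ndarray:
        return np.array(
            [v for t in self.terms
             for v in (t.amplitude, t.centre_nm, t.width_nm)])

    def __call__(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(wavelengths_nm, dtype=float))
        for term in self.terms:
            out += term(wavelengths_nm)
        return out


def evaluate_sensitivity(sens: ChannelSensitivity,
                         grid: WavelengthGrid) -> Spectrum:
    """Sample the Gaussian-sum model on a wavelength grid."""
    return Spectrum(grid, sens(grid.wavelengths), kind="power")


def normalise_sensitivity(sens_spectrum: Spectrum) -> Spectrum:
    """Scale a sensitivity curve to unit area (integral of 1 over nm).

    Matches the convention of plotting channel sensitivities divided by the
    total area under each curve, which makes channels with different absolute
    quantum efficiencies comparable.
    """
    area = integrate(sens_spectrum)
    if area <= 0:
        raise ValueError("cannot normalise a zero-area sensitivity")
    return Spectrum(sens_spectrum.grid, sens_spectrum.values / area,
                    kind="power")


def _gauss_sum(wl: np.ndarray, *coefs: float) -> np.ndarray:
    out = np.zeros_like(wl, dtype=float)
    for a, b, c in zip(coefs[0::3], coefs[1::3], coefs[2::3]):
        out = out + a * np.exp(-(((wl - b) / c) ** 2))
    return out


def _fit_gauss_sum(wl: np.ndarray, y: np.ndarray, p0: np.ndarray):
    """curve_fit wrapper returning (coefs, se, ci95) or None on failure."""
    try:
        with warnings.catch_warnings():
            # degenerate covariance is detected and rejected below
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            coefs, pcov = optimize.curve_fit(_gauss_sum, wl, y, p0=p0,
                                             maxfev=20000)
    except (RuntimeError, ValueError):
        return None
    if not np.all(np.isfinite(pcov)):
        return None
    dof = max(len(y) - len(coefs), 1)
    tcrit = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    ci = np.stack([coefs - tcrit * se, coefs + tcrit * se], axis=1)
    return coefs, se, ci


def _initial_single(wl: np.ndarray, y: np.ndarray) -> np.ndarray:
    i = int(np.argmax(y))
    a0, b0 = y[i], wl[i]
    # FWHM estimate from the samples around the peak
    above = wl[y >= a0 / 2.0]
    fwhm = (above[-1] - above[0]) if above.size >= 2 else 50.0
    c0 = max(fwhm / 2.0, 5.0)
    return np.array([a0, b0, c0])


def fit_sensitivity(samples, channel_id: str = "channel") -> ChannelSensitivity:
    """Fit the Gaussian-sum model to (wavelength, sensitivity) samples.

    Both the one- and two-term models are fitted by nonlinear least squares;
    the two-term model is returned only if all six of its coefficients are
    individually significant at the 95% level.  At least 8 samples spanning
    the channel's support are required.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("samples must be an (n, 2) array of "
                         "(wavelength_nm, sensitivity)")
    if arr.shape[0] < 8:
        raise ValueError("fit_sensitivity needs at least 8 sample points")
    wl, y = arr[:, 0], arr[:, 1]

    fit1 = _fit_gauss_sum(wl, y, _initial_single(wl, y))

    # second term seeded at the largest residual peak of the 1-term fit
    if fit1 is not None:
        resid = y - _gauss_sum(wl, *fit1[0])
    else:
        resid = y
    j = int(np.argmax(np.abs(resid)))
    a2 = max(abs(resid[j]), 1e-3 * max(y.max(), 1e-12))
    p0_2 = np.concatenate([
        fit1[0] if fit1 is not None else _initial_single(wl, y),
        [a2, wl[j], 30.0],
    ])
    fit2 = _fit_gauss_sum(wl, y, p0_2)

    if fit1 is None and fit2 is None:
        raise FitError(
            "neither the 1-term nor the 2-term Gaussian model converged "
            f"for channel {channel_id!r} (n={len(y)}, "
            f"peak={y.max():.3g} at {wl[np.argmax(y)]:.1f} nm)")

    use2 = False
    if fit2 is not None:
        coefs2, _, ci2 = fit2
        significant = np.all((ci2[:, 0] > 0) | (ci2[:, 1] < 0))
        valid = (np.all(coefs2[0::3] > 0) and np.all(coefs2[2::3] > 0)
                 and np.all((coefs2[1::3] >= 250) & (coefs2[1::3] <= 800)))
        # degenerate-covariance guard: an essentially-zero amplitude can
        # carry a zero-width CI on a (near-)perfect fit; such a term adds
        # nothing and is treated as non-significant
        amps = coefs2[0::3]
        substantial = amps.min() > 1e-6 * amps.max()
        use2 = bool(significant and valid and substantial)
    chosen = fit2 if (use2 or fit1 is None) else fit1
    coefs, _, ci = chosen
    terms = tuple(
        GaussianTerm(float(a), float(b), float(abs(c)))
        for a, b, c in zip(coefs[0::3], coefs[1::3], coefs[2::3]))
    return ChannelSensitivity(
        channel_id=channel_id,
        terms=terms,
        coefficient_ci=tuple((float(lo), float(hi)) for lo, hi in ci),
    )
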