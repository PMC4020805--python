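"""Camera transfer functions, LUT inversion and image linearisation.

Consumer cameras map linear sensor exposure x (normalised to [0, 1]) to an
output pixel value q (also normalised) through a nonlinear transfer
function, here modelled as

    q(x) = a * exp(b * x)                       (single_exp)
    q(x) = a * exp(b * x) + c * exp(d * x)      (biexponential)

fitted to a grey-ramp characterisation series.  Linearisation inverts the
fitted function numerically into a 256-entry look-up table; the inverse has
no closed form for the biexponential, so one bisection code path serves both
forms.  Per-entry uncertainty comes from a seeded parametric bootstrap of
the fitted coefficients.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .image import CalibratedImage
from .sensitivity import FitError

__all__ = [
    "TransferFunction",
    "LinearLUT",
    "fit_transfer",
    "invert_to_lut",
    "linearise_image",
]

_MONOTONE_GRID = np.linspace(0.0, 1.0, 501)


def _eval_form(form: str, coefs, x):
    x = np.asarray(x, dtype=float)
    if form == "single_exp":
        a, b = coefs
        return a * np.exp(b * x)
    a, b, c, d = coefs
    return a * np.exp(b * x) + c * np.exp(d * x)


def _is_monotone(form: str, coefs) -> bool:
    y = _eval_form(form, coefs, _MONOTONE_GRID)
    return bool(np.all(np.diff(y) > 0))


@dataclass(frozen=True)
class TransferFunction:
    """Fitted exposure -> pixel nonlinearity, both axes normalised to [0, 1].

    ``ci95`` holds a 95% confidence interval (lo, hi) per coefficient in the
    order (a, b) or (a, b, c, d).
    """

    form: str
    coefficients: tuple[float, ...]
    ci95: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.form not in ("single_exp", "biexponential"):
            raise ValueError("form must be 'single_exp' or 'biexponential'")
        n = 2 if self.form == "single_exp" else 4
        if len(self.coefficients) != n:
            raise ValueError(f"{self.form} takes {n} coefficients")
        if not _is_monotone(self.form, self.coefficients):
            raise ValueError("transfer function must be strictly increasing "
                             "on [0, 1]")
        # a marginally negative black offset is the normal outcome of an
        # unconstrained fit to a noisy series; the LUT inversion clamps it
        if self(0.0) < -0.02:
            raise ValueError("transfer function must satisfy f(0) >= 0 "
                             "(small fit jitter tolerated)")
        if self(1.0) > 1.05:
            raise ValueError("transfer function must satisfy f(1) <= 1.05")

    def __call__(self, x):
        return _eval_form(self.form, self.coefficients, x)

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "single_exp":
            a, b = self.coefficients
            return a * b * np.exp(b * x)
        a, b, c, d = self.coefficients
        return a * b * np.exp(b * x) + c * d * np.exp(d * x)

    def inverse_scalar(self, q: float, tol: float = 1e-9) -> float:
        """Numerical inverse on [0, 1]; targets outside range are clamped."""
        lo_val, hi_val = float(self(0.0)), float(self(1.0))
        if q <= lo_val:
            return 0.0
        if q >= hi_val:
            return 1.0
        lo, hi = 0.0, 1.0
        while hi - lo > tol * 1e-3:
            mid = 0.5 * (lo + hi)
            if self(mid) < q:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


@dataclass(eq=False)
class LinearLUT:
    """256-entry map from 8-bit pixel level to relative linear exposure.

    ``uncertainty`` is the per-entry SD from the coefficient bootstrap;
    ``clamped`` marks levels outside the invertible range of the transfer
    function (below its black offset or above its maximum);
    ``noise_floor_level`` is the lowest pixel level whose linear value
    clears the noise floor.
    """

    entries: np.ndarray
    uncertainty: np.ndarray
    clamped: np.ndarray
    noise_floor_level: int

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        self.clamped = np.asarray(self.clamped, dtype=bool)
        if self.entries.shape != (256,):
            raise ValueError("a LUT has exactly 256 entries")
        if self.uncertainty.shape != (256,) or self.clamped.shape != (256,):
            raise ValueError("uncertainty and clamped must have 256 entries")
        if np.any(np.diff(self.entries) < 0):
            raise ValueError("LUT entries must be non-decreasing")

    @property
    def relative_uncertainty(self) -> np.ndarray:
        """SD relative to the linear value (uninformative where value ~ 0)."""
        floor = max(float(self.entries[-1]) * 1e-6, 1e-12)
        return self.uncertainty / np.maximum(self.entries, floor)


def _series_array(series) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("series must be (n, 2+) of (rel_exposure, "
                         "mean_pixel[, sd_pixel])")
    x, q = arr[:, 0], arr[:, 1]
    if len(x) < 6:
        raise ValueError("fit_transfer needs at least 6 exposure steps")
    if x.min() > 0.05 or x.max() < 0.95:
        raise ValueError("exposure series must span at least [0.05, 0.95]")
    if q.max() > 1.5:  # accept pixel levels and normalise
        q = q / 255.0
    return x, q


def _fit_form(form: str, x: np.ndarray, q: np.ndarray):
    """Return (coefs, ci95, sse) for the best converged fit, or None."""
    # log-linear seed for the dominant exponential
    pos = q > 1e-6
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(q[pos]), 1)
        a0, b0 = float(np.exp(intercept)), float(slope)
    else:
        a0, b0 = 0.1, 2.0
    if form == "single_exp":
        seeds = [np.array([a0, b0]), np.array([q[0] + 1e-3, 1.0])]
        model = lambda xx, a, b: a * np.exp(b * xx)
    else:
        seeds = [
            np.array([a0, b0, -a0, -2.0]),       # compressive, near-zero offset
            np.array([a0, b0, a0 * 0.1, b0 + 2.0]),  # two growing terms
            np.array([1.0, 0.1, -1.0, -2.0]),
            np.array([0.02, 3.0, 0.02, 1.0]),
        ]
        model = lambda xx, a, b, c, d: a * np.exp(b * xx) + c * np.exp(d * xx)
    best = None
    for p0 in seeds:
        try:
            with warnings.catch_warnings():
                # degenerate covariance is detected and rejected below
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                coefs, pcov = optimize.curve_fit(model, x, q, p0=p0,
                                                 maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        if not (np.all(np.isfinite(coefs)) and np.all(np.isfinite(pcov))):
            continue
        if not _is_monotone(form, coefs):
            continue
        f0 = float(_eval_form(form, coefs, 0.0))
        f1 = float(_eval_form(form, coefs, 1.0))
        if f0 < -0.02 or f1 > 1.05:  # outside the physical range contract
            continue
        sse = float(np.sum((model(x, *coefs) - q) ** 2))
        if best is None or sse < best[2] - 1e-15:
            dof = max(len(x) - len(coefs), 1)
            tcrit = stats.t.ppf(0.975, dof)
            se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
            ci = tuple((float(c - tcrit * s), float(c + tcrit * s))
                       for c, s in zip(coefs, se))
            best = (tuple(float(c) for c in coefs), ci, sse)
    return best


def fit_transfer(series, form: str = "auto") -> TransferFunction:
    """Fit a transfer function to a grey-ramp characterisation series.

    ``series`` pairs relative exposure with mean pixel value (normalised or
    in 0-255 levels).  With ``form="auto"`` the biexponential is retained
    only when all four of its coefficients are individually significant at
    the 95% level; otherwise the single-exponential is returned.  Fits that
    are non-monotonic on [0, 1] are rejected.
    """
    if form not in ("single_exp", "biexponential", "auto"):
        raise ValueError("form must be single_exp, biexponential or auto")
    x, q = _series_array(series)

    fits = {}
    for f in ("single_exp", "biexponential"):
        if form in (f, "auto"):
            fits[f] = _fit_form(f, x, q)

    if form != "auto":
        fit = fits[form]
        if fit is None:
            raise FitError(
                f"no monotone {form} fit converged on the series "
                f"(n={len(x)}, exposure range [{x.min():.3g}, {x.max():.3g}])")
        coefs, ci, _ = fit
        return TransferFunction(form, coefs, ci)

    bi = fits["biexponential"]
    single_sse = fits["single_exp"][2] if fits["single_exp"] else np.inf
    if bi is not None:
        coefs, ci, sse = bi
        significant = all(lo > 0 or hi < 0 for lo, hi in ci)
        # parsimony tie-break: on (near-)perfect single-exp data the biexp
        # degenerates and its covariance no longer measures significance
        improves = sse < single_sse * (1.0 - 1e-9) - 1e-14
        if significant and improves:
            return TransferFunction("biexponential", coefs, ci)
    single = fits["single_exp"]
    if single is not None:
        coefs, ci, _ = single
        return TransferFunction("single_exp", coefs, ci)
    if bi is not None:  # significant or not, better than nothing
        coefs, ci, _ = bi
        return TransferFunction("biexponential", coefs, ci)
    raise FitError("neither transfer form produced a monotone converged fit")


def _invert_batch(form: str, coef_sets: np.ndarray,
                  targets: np.ndarray) -> np.ndarray:
    """Vectorised bisection: x with f(x) = target, clamped to [0, 1].

    ``coef_sets`` is (m, k); ``targets`` is (t,); returns (m, t).
    """
    m = coef_sets.shape[0]
    t = targets.shape[0]
    lo = np.zeros((m, t))
    hi = np.ones((m, t))
    tgt = np.broadcast_to(targets, (m, t))

    def f(xs):
        if form == "single_exp":
            a, b = coef_sets[:, :1], coef_sets[:, 1:2]
            return a * np.exp(b * xs)
        a, b = coef_sets[:, :1], coef_sets[:, 1:2]
        c, d = coef_sets[:, 2:3], coef_sets[:, 3:4]
        return a * np.exp(b * xs) + c * np.exp(d * xs)

    f0 = f(lo[:, :1])
    f1 = f(hi[:, :1])
    below = tgt <= f0
    above = tgt >= f1
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        take_lo = fmid < tgt
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    x = 0.5 * (lo + hi)
    x = np.where(below, 0.0, x)
    x = np.where(above, 1.0, x)
    return x


def invert_to_lut(tf: TransferFunction, *, n_samples: int = 1000,
                  seed: int = 0, noise_floor: float = 0.09,
                  max_level: int = 245) -> LinearLUT:
    """Invert a transfer function into a 256-entry linearisation LUT.

    Entries are found by bisection to ~1e-9; targets below the black offset
    f(0) or above f(1) are clamped to 0 / 1 and marked ``clamped``.
    Per-entry uncertainty is the SD of the inverse over ``n_samples``
    draws of the coefficients from independent normals matching their 95%
    confidence intervals (seeded; draws producing a non-monotone curve are
    discarded).  ``noise_floor`` is the fraction of the full linear range
    (taken at ``max_level``) below which recovered values count as
    noise-dominated.
    """
    targets = np.arange(256) / 255.0
    coefs = np.array(tf.coefficients, dtype=float)
    entries = _invert_batch(tf.form, coefs[None, :], targets)[0]
    f0, f1 = float(tf(0.0)), float(tf(1.0))
    clamped = (targets < f0) | (targets > f1)

    if tf.ci95 is not None and n_samples > 0:
        rng = np.random.default_rng(seed)
        se = np.array([(hi - lo) / (2 * 1.96) for lo, hi in tf.ci95])
        draws = coefs[None, :] + se[None, :] * rng.standard_normal(
            (int(n_samples * 1.2) + 8, len(coefs)))
        keep = np.array([_is_monotone(tf.form, row) for row in draws])
        draws = draws[keep][:n_samples]
        if len(draws) == 0:
            uncertainty = np.zeros(256)
        else:
            inv = _invert_batch(tf.form, draws, targets)
            uncertainty = inv.std(axis=0)
    else:
        uncertainty = np.zeros(256)

    entries = np.maximum.accumulate(entries)  # guard against bisection jitter
    full_range = entries[max_level]
    floor_value = noise_floor * full_range
    above = np.nonzero(entries >= floor_value)[0]
    noise_floor_level = int(above[0]) if len(above) else 255
    return LinearLUT(entries, uncertainty, clamped, noise_floor_level)


def linearise_image(image: np.ndarray, luts, *,
                    max_level: int = 245,
                    channel_ids: tuple[str, ...] | None = None
                    ) -> CalibratedImage:
    """Apply per-channel LUTs to an 8-bit image.

    Returns a linear-scale :class:`CalibratedImage` with per-pixel
    uncertainty and with pixels above ``max_level`` flagged clipped (the
    exposure ceiling itself is the calibrated white level and stays valid)
    and pixels whose linear value falls below the LUT's noise floor flagged
    low-signal.  Non-8-bit input is an error: rescaling other bit depths
    silently would corrupt the radiometry.
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("linearise_image expects 8-bit (uint8) input")
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ValueError("image must be (H, W) or (H, W, C)")
    luts = list(luts) if not isinstance(luts, LinearLUT) else [luts]
    if image.shape[2] != len(luts):
        raise ValueError(
            f"image has {image.shape[2]} channels but {len(luts)} LUTs given")

    channels = np.empty(image.shape, dtype=float)
    uncertainty = np.empty(image.shape, dtype=float)
    low_signal = np.empty(image.shape, dtype=bool)
    for ci, lut in enumerate(luts):
        channels[..., ci] = lut.entries[image[..., ci]]
        uncertainty[..., ci] = lut.uncertainty[image[..., ci]]
        low_signal[..., ci] = image[..., ci] < lut.noise_floor_level
    clipped = image > max_level
    return CalibratedImage(channels, "linear", clipped, low_signal,
                           uncertainty, channel_ids)
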