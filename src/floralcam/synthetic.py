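"""Synthetic scenes with known ground truth for end-to-end validation.

Everything here is *synthetic*: the camera profiles imitate the shape of
real DSLR characterisations (Gaussian channel sensitivities, compressive
exponential transfer curves) but their coefficients are invented, and the
petal reflectance spectra are parametric Gaussian-band curves imitating
yellow and UV-reflective/absorbing floral classes.  Fixtures always ship
their ground truth so any pipeline stage can be scored without external
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .camera import (CameraProfile, ExposureSetting, NoiseSpec,
                     exposure_for_white, predict_relative_reflectance,
                     render_scene)
from .recovery import StandardSpec
from .sensitivity import ChannelSensitivity, GaussianTerm
from .spectra import (DEFAULT_GRID, Spectrum, WavelengthGrid, cie_daylight_spd,
                      flat_spectrum)
from .transfer import TransferFunction

__all__ = [
    "UV_GRID",
    "SIX_SWATCH_REFLECTANCES",
    "synthetic_visible_profile",
    "synthetic_uv_profile",
    "petal_spectrum",
    "make_grey_series",
    "make_swatch_frame",
    "make_flower_scene",
    "FlowerScene",
]

#: UV camera band: Baader-U-style passband reaching the sensor.
UV_GRID = WavelengthGrid(320.0, 395.0, 1.0)

#: Nominal reflectances of the six neutral Colour Checker swatches
#: (black to white), as fractions.
SIX_SWATCH_REFLECTANCES = (0.0310, 0.0911, 0.195, 0.372, 0.609, 0.948)


def _ci(coefs, rel=0.02):
    return tuple((c - rel * abs(c), c + rel * abs(c)) for c in coefs)


def synthetic_visible_profile() -> CameraProfile:
    """Synthetic three-channel visible-band camera (invented coefficients).

    Each channel gets a compressive biexponential transfer (distinct
    coefficients per channel, as real cameras show) with +/-2% coefficient
    CIs standing in for a characterisation's uncertainty.
    """
    sens = {
        "red": ChannelSensitivity("red", (GaussianTerm(1.0, 600.0, 45.0),
                                          GaussianTerm(0.25, 530.0, 30.0))),
        "green": ChannelSensitivity("green", (GaussianTerm(1.0, 530.0, 40.0),)),
        "blue": ChannelSensitivity("blue", (GaussianTerm(0.9, 460.0, 35.0),)),
    }
    tf_coefs = {
        "red": (1.05, 0.10, -1.05, -2.2),
        "green": (1.10, 0.08, -1.10, -2.0),
        "blue": (1.00, 0.12, -1.00, -2.4),
    }
    transfers = {cid: TransferFunction("biexponential", c, _ci(c))
                 for cid, c in tf_coefs.items()}
    exposure = ExposureSetting((1.0, 1.0, 1.0))
    return CameraProfile("synthetic-visible", ("red", "green", "blue"), sens,
                         transfers, exposure,
                         provenance="synthetic profile; coefficients invented")


def synthetic_uv_profile() -> CameraProfile:
    """Synthetic single-channel UV camera with a single-exp transfer."""
    sens = {"uv": ChannelSensitivity("uv", (GaussianTerm(1.0, 360.0, 25.0),))}
    coefs = (0.05, 3.0)
    transfers = {"uv": TransferFunction("single_exp", coefs, _ci(coefs))}
    return CameraProfile("synthetic-uv", ("uv",), sens, transfers,
                         ExposureSetting((1.0,)),
                         provenance="synthetic profile; coefficients invented")


# -- parametric reflectance spectra ---------------------------------------

def petal_spectrum(kind: str, grid: WavelengthGrid = DEFAULT_GRID,
                   amplitude: float = 1.0) -> Spectrum:
    """Gaussian-band reflectance curves imitating floral colour classes.

    ``yellow``: bright at long visible wavelengths, dark in blue/UV.
    ``uv_reflective``: a UV bump on a modest visible base.
    ``uv_absorbing``: bright visible, near-zero UV.
    """
    wl = grid.wavelengths
    if kind == "yellow":
        r = 0.08 + 0.80 * np.exp(-(((wl - 700.0) / 140.0) ** 2))
    elif kind == "uv_reflective":
        r = 0.10 + 0.55 * np.exp(-(((wl - 360.0) / 40.0) ** 2))
    elif kind == "uv_absorbing":
        r = 0.03 + 0.75 * np.exp(-(((wl - 640.0) / 120.0) ** 2))
    else:
        raise ValueError(f"unknown petal spectrum kind {kind!r}")
    return Spectrum(grid, np.clip(amplitude * r, 0.0, 1.0))


# -- characterisation series ----------------------------------------------

def make_grey_series(tf: TransferFunction, n_steps: int = 12, *,
                     noise_rel: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Grey-ramp characterisation series for feeding ``fit_transfer``.

    Relative exposures are log-spaced over [0.02, 1.0]; pixel values come
    from the transfer function with optional multiplicative Gaussian noise
    of relative SD ``noise_rel``.
    """
    if n_steps < 6:
        raise ValueError("a characterisation series needs >= 6 steps")
    rng = np.random.default_rng(seed)
    x = np.logspace(np.log10(0.02), 0.0, n_steps)
    q = tf(x)
    sd = noise_rel * q
    if noise_rel > 0:
        # an 8-bit sensor cannot report above full scale
        q = np.clip(q * (1.0 + noise_rel * rng.standard_normal(n_steps)),
                    0.0, 1.0)
    return pd.DataFrame({"rel_exposure": x, "mean_pixel": q, "sd_pixel": sd})


# -- swatch frame ----------------------------------------------------------

def make_swatch_frame(reflectances=SIX_SWATCH_REFLECTANCES,
                      profile: CameraProfile | None = None, *,
                      illuminant: Spectrum | None = None,
                      noise: NoiseSpec | None = None, seed: int = 0):
    """Render a neutral-swatch strip plus a white standard through a camera.

    The frame imitates the achromatic column of a Colour Checker: a vertical
    strip of spectrally flat swatches (dark at the bottom, bright at the
    top) next to an ideal white reference.  Exposure is standardised so the
    white standard reads exactly ``max_level`` (245) in every channel.

    Returns ``(image, truth)`` where ``truth`` maps swatch ROIs to nominal
    reflectances and carries the standards list and the exposure-bearing
    profile.
    """
    profile = profile or synthetic_visible_profile()
    grid = DEFAULT_GRID
    illuminant = illuminant or cie_daylight_spd(6500.0, grid)
    reflectances = tuple(float(r) for r in reflectances)
    if any(not 0 < r <= 1 for r in reflectances):
        raise ValueError("swatch reflectances must be in (0, 1]")

    white = flat_spectrum(1.0, grid)
    profile = profile.with_exposure(
        exposure_for_white(profile, illuminant, white))

    n = len(reflectances)
    pitch, sw_h, sw_w = 40, 30, 60
    height = 20 + pitch * n
    width = 150
    shape = (height, width)
    regions = []
    swatch_rois = {}
    # bottom-to-top: darkest swatch at the bottom
    for k, refl in enumerate(reflectances):
        r0 = height - 10 - pitch * k - sw_h
        roi = (r0, r0 + sw_h, 10, 10 + sw_w)
        mask = np.zeros(shape, bool)
        mask[roi[0]:roi[1], roi[2]:roi[3]] = True
        regions.append((mask, flat_spectrum(refl, grid)))
        swatch_rois[f"swatch_{k}"] = {"roi": roi, "reflectance": refl}
    white_roi = (10, 60, 80, 140)
    wmask = np.zeros(shape, bool)
    wmask[white_roi[0]:white_roi[1], white_roi[2]:white_roi[3]] = True
    covered = np.zeros(shape, bool)
    for m, _ in regions:
        covered |= m
    background = ~(covered | wmask)
    scene = ([(background, flat_spectrum(0.30, grid))]
             + regions + [(wmask, white)])
    image = render_scene(scene, profile, illuminant, noise=noise, seed=seed)
    standards = [StandardSpec("white_spectralon", 1.0, white_roi)]
    truth = {"swatches": swatch_rois, "standards": standards,
             "profile": profile, "illuminant": illuminant,
             "white_roi": white_roi}
    return image, truth


# -- flower scenes ---------------------------------------------------------

@dataclass(eq=False)
class FlowerScene:
    """A synthetic flower frame with spectra bound to labelled regions.

    ``regions`` are (label, mask, Spectrum) with later entries taking
    precedence where they overlap (UV marks sit inside petals);
    ``petal_bbox`` is a rectangle inside the petal area sized for grid
    sampling.
    """

    shape: tuple[int, int]
    regions: list
    standards: list
    background: Spectrum
    petal_bbox: tuple[int, int, int, int]
    template: str

    def reflectance_map(self):
        covered = np.zeros(self.shape, bool)
        for _, mask, _ in self.regions:
            covered |= mask
        for std in self.standards:
            covered |= std.mask(self.shape)
        entries = [(~covered, self.background)]
        for std in self.standards:
            entries.append((std.mask(self.shape),
                            flat_spectrum(std.nominal_reflectance,
                                          self.background.grid)))
        entries += [(mask, spec) for _, mask, spec in self.regions]
        return entries

    def render(self, profile: CameraProfile, illuminant: Spectrum, *,
               noise: NoiseSpec | None = None, seed: int = 0) -> np.ndarray:
        return render_scene(self.reflectance_map(), profile, illuminant,
                            noise=noise, seed=seed)

    def ground_truth(self, profile: CameraProfile,
                     illuminant: Spectrum) -> np.ndarray:
        """Per-pixel predicted relative reflectance (vs an ideal white)."""
        white = flat_spectrum(1.0, illuminant.grid)
        out = np.zeros(self.shape + (profile.n_channels,))
        for mask, spec in self.reflectance_map():
            for ci, cid in enumerate(profile.channel_ids):
                out[..., ci][mask] = predict_relative_reflectance(
                    profile.sensitivities[cid], illuminant, spec, white)
        return out


def _disc(shape, centre, radius):
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius ** 2


def make_flower_scene(template: str = "bullseye", *, size: int = 512,
                      grid: WavelengthGrid = DEFAULT_GRID,
                      mark_contrast: float = 1.0,
                      seed: int = 0) -> FlowerScene:
    """Parametric flower layouts with known spectra per region.

    ``plain``: a single-spectrum flower disc.  ``bullseye``: UV-reflective
    petals with a UV-absorbing centre (the floral-guide pattern many
    pollinators use).  ``gradient``: concentric rings blending between two
    spectra.  ``mark_contrast`` scales the UV amplitude of the bullseye
    centre relative to the petals (1 = full contrast).
    """
    if template not in ("plain", "bullseye", "gradient"):
        raise ValueError(f"unknown template {template!r}")
    if size < 400:
        raise ValueError("canvas must be at least 400 px to fit the grids")
    shape = (size, size)
    centre = (size // 2, size // 2)
    flower = _disc(shape, centre, int(size * 0.45))
    regions = []
    if template == "plain":
        regions.append(("petals", flower, petal_spectrum("yellow", grid)))
    elif template == "bullseye":
        inner = _disc(shape, centre, int(size * 0.10))
        petals = petal_spectrum("uv_reflective", grid)
        wl = grid.wavelengths
        centre_vals = (petals.values
                       - mark_contrast * 0.55
                       * np.exp(-(((wl - 360.0) / 40.0) ** 2)))
        regions.append(("petals", flower & ~inner, petals))
        regions.append(("uv_mark", inner,
                        Spectrum(grid, np.clip(centre_vals, 0.0, 1.0))))
    else:  # gradient
        rr, cc = np.ogrid[:size, :size]
        dist = np.sqrt((rr - centre[0]) ** 2 + (cc - centre[1]) ** 2)
        n_rings = 6
        radius = size * 0.45
        inner_spec = petal_spectrum("uv_reflective", grid)
        outer_spec = petal_spectrum("yellow", grid)
        for k in range(n_rings):
            lo, hi = radius * k / n_rings, radius * (k + 1) / n_rings
            ring = flower & (dist >= lo) & (dist < hi + 1e-9)
            w = k / (n_rings - 1)
            vals = (1 - w) * inner_spec.values + w * outer_spec.values
            regions.append((f"ring_{k}", ring, Spectrum(grid, vals)))

    margin = int(size * 0.04)
    std_h = int(size * 0.10)
    standards = [
        StandardSpec("white_spectralon", 1.0,
                     (margin, margin + std_h, margin, margin + std_h)),
        StandardSpec("grey_33", 0.33,
                     (margin, margin + std_h, 2 * margin + std_h,
                      2 * margin + 2 * std_h), valid_band_nm=(300.0, 400.0)),
        StandardSpec("checker_white", 0.95,
                     (margin, margin + std_h, 3 * margin + 2 * std_h,
                      3 * margin + 3 * std_h), valid_band_nm=(400.0, 710.0)),
    ]
    # a 4x3 grid of 40 px cells (160 x 120) inside the petal annulus,
    # below the bullseye centre
    b_r0 = centre[0] + int(size * 0.11)
    b_c0 = centre[1] - 60
    petal_bbox = (b_r0, b_r0 + 160, b_c0, b_c0 + 120)
    return FlowerScene(shape, regions, standards,
                       flat_spectrum(0.10, grid), petal_bbox, template)
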