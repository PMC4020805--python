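"""Forward camera model: spectra in, 8-bit nonlinear pixel values out.

The linear response of channel i to a surface with reflectance R under
illuminant E is the integral over wavelength of S_i * E * R.  An
:class:`ExposureSetting` converts that integral into relative linear
exposure in [0, 1]; the channel's transfer function then applies the
camera's nonlinearity, and the result is quantised to 8 bits.  Rendering
synthetic scenes through a *known* nonlinearity is what lets every later
pipeline stage be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensitivity import ChannelSensitivity
from .spectra import Spectrum, integrate
from .transfer import TransferFunction

__all__ = [
    "ExposureSetting",
    "NoiseSpec",
    "CameraProfile",
    "predict_response",
    "predict_relative_reflectance",
    "exposure_for_white",
    "render_scene",
]


@dataclass(frozen=True)
class ExposureSetting:
    """Per-channel scale from predicted linear response to relative exposure.

    ``max_level`` is the pixel level the brightest in-frame calibration
    standard is exposed to (default 245 of 255), deliberately below
    saturation so that averaged responses never include clipped pixels.
    """

    scale_per_channel: tuple[float, ...]
    max_level: int = 245
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale_per_channel):
            raise ValueError("exposure scales must be positive")
        if not 0 < self.max_level < 2 ** self.bit_depth:
            raise ValueError("max_level must lie inside the encoding range")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive sensor noise, in intensity levels on the linear signal.

    ``read_sd`` is signal-independent read noise; ``shot_coefficient``
    scales a sqrt(signal) shot-noise term.
    """

    read_sd: float = 1.0
    shot_coefficient: float = 0.5

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(read_sd=0.0, shot_coefficient=0.0)


@dataclass(frozen=True)
class CameraProfile:
    """Everything needed to render through (or invert) one camera."""

    name: str
    channel_ids: tuple[str, ...]
    sensitivities: dict[str, ChannelSensitivity]
    transfers: dict[str, TransferFunction]
    exposure: ExposureSetting
    provenance: str = ""

    def __post_init__(self) -> None:
        for cid in self.channel_ids:
            if cid not in self.sensitivities or cid not in self.transfers:
                raise ValueError(f"profile missing channel {cid!r}")
        if len(self.exposure.scale_per_channel) != len(self.channel_ids):
            raise ValueError("exposure scales do not match channel count")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def with_exposure(self, exposure: ExposureSetting) -> "CameraProfile":
        return CameraProfile(self.name, self.channel_ids, self.sensitivities,
                             self.transfers, exposure, self.provenance)


def predict_response(sens: ChannelSensitivity, illuminant: Spectrum,
                     reflectance: Spectrum) -> float:
    """Predicted linear channel response: integral of S * E * R over nm."""
    if reflectance.grid != illuminant.grid:
        raise ValueError("illuminant and reflectance must share a grid")
    s = sens(illuminant.wavelengths)
    product = Spectrum(illuminant.grid,
                       s * illuminant.values * reflectance.values,
                       kind="power")
    return integrate(product)


def predict_relative_reflectance(sens: ChannelSensitivity,
                                 illuminant: Spectrum,
                                 reflectance: Spectrum,
                                 white_reference: Spectrum) -> float:
    """Channel response relative to a white reference.

    For a perfect white reference this is the channel-weighted total
    reflectance of the surface, the quantity a calibrated camera frame
    reports per pixel.
    """
    denom = predict_response(sens, illuminant, white_reference)
    if denom <= 0:
        raise ValueError("white reference yields zero response under S*E")
    return predict_response(sens, illuminant, reflectance) / denom


def exposure_for_white(profile: CameraProfile, illuminant: Spectrum,
                       white: Spectrum, max_level: int = 245) -> ExposureSetting:
    """Exposure scales that place ``white`` exactly at ``max_level``.

    This is the in-frame exposure-standardisation rule: each channel is
    scaled independently so the brightest achromatic standard reads
    ``max_level`` (default 245), avoiding software white balance.
    """
    scales = []
    for cid in profile.channel_ids:
        tf = profile.transfers[cid]
        x_target = tf.inverse_scalar(max_level / 255.0)
        response = predict_response(profile.sensitivities[cid], illuminant,
                                    white)
        if response <= 0:
            raise ValueError(f"white standard invisible to channel {cid!r}")
        scales.append(x_target / response)
    return ExposureSetting(tuple(scales), max_level=max_level)


def render_scene(reflectance_map, profile: CameraProfile,
                 illuminant: Spectrum, *, noise: NoiseSpec | None = None,
                 seed: int | None = 0) -> np.ndarray:
    """Render a scene of per-region reflectance spectra to an 8-bit image.

    ``reflectance_map`` is a list of ``(mask, Spectrum)`` pairs whose masks
    tile the canvas (every pixel must be covered).  Per channel: linear
    response from the spectra, exposure scaling, additive read + shot noise
    on the linear signal, the channel's nonlinear transfer, then quantisation
    to 8 bits with clipping at 255.
    """
    noise = noise or NoiseSpec.off()
    masks = [np.asarray(m, bool) for m, _ in reflectance_map]
    if not masks:
        raise ValueError("reflectance_map is empty")
    shape = masks[0].shape
    covered = np.zeros(shape, dtype=bool)
    for m in masks:
        covered |= m
    if not covered.all():
        n = int((~covered).sum())
        raise ValueError(f"{n} scene pixels have no assigned spectrum")

    rng = np.random.default_rng(seed)
    out = np.zeros(shape + (profile.n_channels,), dtype=np.uint8)
    for ci, cid in enumerate(profile.channel_ids):
        sens = profile.sensitivities[cid]
        tf = profile.transfers[cid]
        scale = profile.exposure.scale_per_channel[ci]
        x = np.zeros(shape, dtype=float)
        for mask, spectrum in reflectance_map:
            x[mask] = scale * predict_response(sens, illuminant, spectrum)
        if noise.read_sd > 0 or noise.shot_coefficient > 0:
            levels = 255.0 * x
            sd = np.sqrt(noise.read_sd ** 2
                         + (noise.shot_coefficient ** 2) * np.clip(levels, 0,
                                                                   None))
            x = x + sd * rng.standard_normal(shape) / 255.0
        x = np.clip(x, 0.0, 1.0)
        q = tf(x)
        out[..., ci] = np.clip(np.rint(255.0 * q), 0, 255).astype(np.uint8)
    return out
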