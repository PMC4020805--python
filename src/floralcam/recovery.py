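"""Reflectance recovery against in-frame achromatic standards.

After linearisation, pixel values are proportional to exposure but still in
arbitrary per-channel units.  Dividing each channel by the linear response
of an in-frame standard of known reflectance converts the frame to
reflectance fractions without any software white balance: each channel is
standardised independently, exactly as a per-channel exposure calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import CalibratedImage

__all__ = [
    "StandardSpec",
    "calibrate_exposure",
    "to_reflectance",
    "saturation_check",
]

#: label -> (nominal reflectance fraction, valid band in nm)
KNOWN_STANDARDS = {
    "white_spectralon": (1.00, (250.0, 830.0)),
    "grey_33": (0.33, (300.0, 400.0)),
    "checker_white": (0.95, (400.0, 710.0)),
}


@dataclass(frozen=True)
class StandardSpec:
    """An in-frame achromatic calibration target.

    ``roi`` is a (row0, row1, col0, col1) half-open rectangle in pixel
    coordinates (0-based, origin top-left).
    """

    label: str
    nominal_reflectance: float
    roi: tuple[int, int, int, int]
    valid_band_nm: tuple[float, float] = (300.0, 710.0)

    def __post_init__(self) -> None:
        if not 0 < self.nominal_reflectance <= 1:
            raise ValueError("nominal_reflectance must be in (0, 1]")
        r0, r1, c0, c1 = self.roi
        if r1 <= r0 or c1 <= c0:
            raise ValueError("roi must be non-empty")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        r0, r1, c0, c1 = self.roi
        m[r0:r1, c0:c1] = True
        return m


def _roi_stats(image: CalibratedImage, std: StandardSpec,
               channel: int) -> tuple[float, float, int] | None:
    """(mean, sd, n) of valid pixels in the standard ROI, or None."""
    r0, r1, c0, c1 = std.roi
    vals = image.channels[r0:r1, c0:c1, channel]
    ok = image.valid[r0:r1, c0:c1, channel]
    n = int(ok.sum())
    if n == 0:
        return None
    v = vals[ok]
    return float(v.mean()), float(v.std(ddof=1)) if n > 1 else 0.0, n


def calibrate_exposure(image: CalibratedImage,
                       standards: list[StandardSpec]) -> np.ndarray:
    """Per-channel scale factors mapping linear values to reflectance.

    For each channel, each usable (unclipped, above-noise-floor) standard
    proposes ``scale = nominal / mean(linear ROI)``; multiple standards are
    combined by inverse-variance weighting.  All standards unusable in a
    channel is an error — the frame cannot be calibrated.
    """
    if image.scale != "linear":
        raise ValueError("calibrate_exposure expects a linear-scale image")
    if not standards:
        raise ValueError("at least one standard is required")
    scales = np.empty(image.n_channels)
    for ch in range(image.n_channels):
        estimates = []
        for std in standards:
            st = _roi_stats(image, std, ch)
            if st is None:
                continue
            mean, sd, n = st
            if mean <= 0:
                continue
            scale = std.nominal_reflectance / mean
            # variance of the scale via the delta method on the ROI mean
            var_mean = (sd ** 2) / n if n > 1 else 0.0
            var_scale = (std.nominal_reflectance / mean ** 2) ** 2 * var_mean
            estimates.append((scale, var_scale))
        if not estimates:
            cid = (image.channel_ids[ch] if image.channel_ids else str(ch))
            raise ValueError(
                f"channel {cid}: every standard ROI is clipped or "
                "noise-dominated; the frame cannot be calibrated")
        s = np.array([e[0] for e in estimates])
        v = np.array([e[1] for e in estimates])
        if np.any(v <= 0):
            # a noise-free standard pins the scale exactly
            scales[ch] = s[v <= 0].mean()
        else:
            w = 1.0 / v
            scales[ch] = float(np.sum(w * s) / np.sum(w))
    return scales


def to_reflectance(image: CalibratedImage,
                   scales: np.ndarray) -> CalibratedImage:
    """Convert a linear frame to reflectance scale.

    Values above 1 (super-white, brighter than the standard) are kept, not
    clamped: they remain flagged through the clipping mask where relevant.
    Uncertainty scales with the same per-channel factor.
    """
    scales = np.asarray(scales, dtype=float)
    if scales.shape != (image.n_channels,):
        raise ValueError("one scale per channel is required")
    channels = image.channels * scales[None, None, :]
    uncertainty = (image.uncertainty * scales[None, None, :]
                   if image.uncertainty is not None else None)
    return CalibratedImage(channels, "reflectance", image.clipped.copy(),
                           image.low_signal.copy(), uncertainty,
                           image.channel_ids)


def saturation_check(nonlinear_image: np.ndarray,
                     standards: list[StandardSpec],
                     regions: dict[str, tuple[int, int, int, int]],
                     *, max_level: int = 245) -> dict[str, list[dict]]:
    """Advisory check for vendor-boosted channels in the *non-linear* image.

    Saturated hues (deep yellows/oranges) can be rendered by camera firmware
    with a channel response above that of a near-white standard, which no
    physically plausible reflectance can produce.  Any sample region whose
    mean non-linear channel value exceeds the white-class standard's mean is
    reported per channel; regions dominated by clipped pixels are reported
    as clipped instead and excluded from the boost diagnosis.
    """
    img = np.asarray(nonlinear_image)
    if img.dtype != np.uint8:
        raise ValueError("saturation_check expects the 8-bit camera image")
    if img.ndim == 2:
        img = img[:, :, None]
    whites = [s for s in standards
              if s.label in ("white_spectralon", "checker_white")
              or s.nominal_reflectance >= 0.9]
    if not whites:
        raise ValueError("a white-class standard (>= 90% reflectance) is "
                         "required for the saturation check")
    report: dict[str, list[dict]] = {"boosted": [], "clipped": []}
    for ch in range(img.shape[2]):
        white_means = []
        for std in whites:
            r0, r1, c0, c1 = std.roi
            patch = img[r0:r1, c0:c1, ch].astype(float)
            unclipped = patch[patch <= max_level]
            if unclipped.size:
                white_means.append(unclipped.mean())
        if not white_means:
            continue
        white_level = max(white_means)
        for label, (r0, r1, c0, c1) in regions.items():
            patch = img[r0:r1, c0:c1, ch].astype(float)
            frac_clipped = float((patch > max_level).mean())
            entry = {"region": label, "channel": ch,
                     "mean_level": float(patch.mean()),
                     "white_level": float(white_level)}
            if frac_clipped > 0.5:
                report["clipped"].append(entry | {"frac_clipped": frac_clipped})
            elif patch.mean() > white_level:
                report["boosted"].append(entry)
    return report
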