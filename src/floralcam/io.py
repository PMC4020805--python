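"""File formats: spectra CSV, characterisation series, LUTs, profiles, images.

All on-disk formats are plain text or standard image containers:
two-column CSV for spectra (``wavelength_nm,value``), CSV for
characterisation series and LUTs, YAML for camera profiles, 8-bit PNG/TIFF
for camera frames and 32-bit float TIFF for recovered reflectance maps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .camera import CameraProfile, ExposureSetting
from .image import CalibratedImage
from .recovery import StandardSpec
from .sensitivity import ChannelSensitivity, GaussianTerm
from .spectra import Spectrum, WavelengthGrid
from .transfer import LinearLUT, TransferFunction

__all__ = [
    "load_spectrum", "save_spectrum",
    "load_series", "save_series",
    "load_lut", "save_lut",
    "load_profile", "save_profile",
    "load_image", "save_image", "save_reflectance_map",
    "load_standards", "save_standards",
]


def load_spectrum(path, *, percent: bool = False,
                  kind: str = "reflectance") -> Spectrum:
    """Read a two-column ``wavelength_nm,value`` CSV.

    ``percent=True`` divides values by 100 (spectrophotometer exports often
    report percent reflectance).  Requires a uniform wavelength step.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "wavelength_nm" not in cols:
        raise ValueError(f"{path}: expected a 'wavelength_nm' column")
    value_col = [c for c in cols if c != "wavelength_nm"][0]
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    values = df[value_col].to_numpy(dtype=float)
    if percent:
        values = values / 100.0
    steps = np.diff(wl)
    if len(wl) < 2 or not np.allclose(steps, steps[0]):
        raise ValueError(f"{path}: wavelengths must be uniformly spaced")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))
    return Spectrum(grid, values, kind=kind)


def save_spectrum(spectrum: Spectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                  "value": spectrum.values}).to_csv(path, index=False)


def load_series(path) -> np.ndarray:
    """Characterisation series CSV: rel_exposure,mean_pixel[,sd_pixel]."""
    df = pd.read_csv(path)
    required = {"rel_exposure", "mean_pixel"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    cols = ["rel_exposure", "mean_pixel"]
    if "sd_pixel" in df.columns:
        cols.append("sd_pixel")
    return df[cols].to_numpy(dtype=float)


def save_series(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False)


def save_lut(lut: LinearLUT, path) -> None:
    flag = np.where(lut.clamped, "clamped", "")
    flag = np.where((np.arange(256) < lut.noise_floor_level)
                    & ~lut.clamped, "low_signal", flag)
    pd.DataFrame({"level": np.arange(256), "linear_value": lut.entries,
                  "sd": lut.uncertainty, "flag": flag}).to_csv(path,
                                                              index=False)


def load_lut(path) -> LinearLUT:
    df = pd.read_csv(path, keep_default_na=False)
    if len(df) != 256:
        raise ValueError(f"{path}: a LUT file must have 256 rows")
    flags = df["flag"].astype(str).to_numpy()
    low = np.nonzero(flags == "low_signal")[0]
    clamped = flags == "clamped"
    entries = df["linear_value"].to_numpy(dtype=float)
    if len(low):
        floor_level = int(low[-1]) + 1
    else:
        floor_level = int(np.nonzero(~clamped)[0][0]) if (~clamped).any() else 0
    return LinearLUT(entries, df["sd"].to_numpy(dtype=float), clamped,
                     floor_level)


def _tf_to_dict(tf: TransferFunction) -> dict:
    return {"form": tf.form, "coefficients": list(tf.coefficients),
            "ci95": [list(c) for c in tf.ci95] if tf.ci95 else None}


def _tf_from_dict(d: dict) -> TransferFunction:
    ci = d.get("ci95")
    return TransferFunction(d["form"], tuple(d["coefficients"]),
                            tuple(tuple(c) for c in ci) if ci else None)


def _sens_to_dict(s: ChannelSensitivity) -> dict:
    return {
        "channel_id": s.channel_id,
        "terms": [[t.amplitude, t.centre_nm, t.width_nm] for t in s.terms],
        "coefficient_ci": ([list(c) for c in s.coefficient_ci]
                           if s.coefficient_ci else None),
    }


def _sens_from_dict(d: dict) -> ChannelSensitivity:
    ci = d.get("coefficient_ci")
    return ChannelSensitivity(
        d["channel_id"],
        tuple(GaussianTerm(*t) for t in d["terms"]),
        tuple(tuple(c) for c in ci) if ci else None,
    )


def save_profile(profile: CameraProfile, path) -> None:
    doc = {
        "name": profile.name,
        "provenance": profile.provenance,
        "channel_ids": list(profile.channel_ids),
        "sensitivities": {cid: _sens_to_dict(s)
                          for cid, s in profile.sensitivities.items()},
        "transfers": {cid: _tf_to_dict(t)
                      for cid, t in profile.transfers.items()},
        "exposure": {
            "scale_per_channel": list(profile.exposure.scale_per_channel),
            "max_level": profile.exposure.max_level,
            "bit_depth": profile.exposure.bit_depth,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_profile(path) -> CameraProfile:
    doc = yaml.safe_load(Path(path).read_text())
    exp = doc["exposure"]
    return CameraProfile(
        name=doc["name"],
        channel_ids=tuple(doc["channel_ids"]),
        sensitivities={cid: _sens_from_dict(d)
                       for cid, d in doc["sensitivities"].items()},
        transfers={cid: _tf_from_dict(d)
                   for cid, d in doc["transfers"].items()},
        exposure=ExposureSetting(tuple(exp["scale_per_channel"]),
                                 exp["max_level"], exp["bit_depth"]),
        provenance=doc.get("provenance", ""),
    )


def save_standards(standards: list[StandardSpec], path) -> None:
    doc = [{"label": s.label, "nominal_reflectance": s.nominal_reflectance,
            "roi": list(s.roi), "valid_band_nm": list(s.valid_band_nm)}
           for s in standards]
    Path(path).write_text(yaml.safe_dump(doc))


def load_standards(path) -> list[StandardSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    return [StandardSpec(d["label"], d["nominal_reflectance"],
                         tuple(d["roi"]), tuple(d["valid_band_nm"]))
            for d in doc]


def load_image(path) -> np.ndarray:
    """Load an 8-bit PNG/TIFF frame as (H, W[, C]) uint8."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image data, got {arr.dtype}")
    return arr


def save_image(image: np.ndarray, path) -> None:
    image = np.asarray(image)
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, image)
    else:
        squeezed = image[..., 0] if (image.ndim == 3
                                     and image.shape[2] == 1) else image
        Image.fromarray(squeezed).save(path)


def save_reflectance_map(image: CalibratedImage, stem) -> list[Path]:
    """Write per-channel float32 TIFFs plus PNG flag masks.

    Returns the written paths; ``stem`` is the common filename prefix.
    """
    stem = Path(stem)
    written = []
    ids = image.channel_ids or tuple(str(i) for i in range(image.n_channels))
    for ci, cid in enumerate(ids):
        p = stem.with_name(f"{stem.name}_{cid}.tif")
        tifffile.imwrite(p, image.channels[..., ci].astype(np.float32))
        written.append(p)
    flags = (image.clipped.any(axis=2).astype(np.uint8) * 255)
    low = (image.low_signal.any(axis=2).astype(np.uint8) * 255)
    for name, arr in (("clipped", flags), ("low_signal", low)):
        p = stem.with_name(f"{stem.name}_{name}.png")
        Image.fromarray(arr).save(p)
        written.append(p)
    return written
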