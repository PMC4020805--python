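"""Container for linearised / reflectance-scaled image data."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["CalibratedImage"]


@dataclass(eq=False)
class CalibratedImage:
    """Per-channel real-valued pixel data with flags and uncertainty.

    ``channels`` has shape (H, W, C).  ``scale`` is ``"linear"`` (relative
    exposure, dimensionless in [0, 1]) or ``"reflectance"`` (fraction of the
    calibration standard; values slightly above 1 are tolerated and
    flagged).  ``clipped`` marks pixels at or above the exposure ceiling in
    the source 8-bit image; ``low_signal`` marks pixels in the noise-
    dominated bottom of the transfer curve where recovered values are
    unreliable.
    """

    channels: np.ndarray
    scale: str
    clipped: np.ndarray
    low_signal: np.ndarray
    uncertainty: np.ndarray | None = None
    channel_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3:
            raise ValueError("channels must have shape (H, W, C)")
        for name in ("clipped", "low_signal"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.shape != self.channels.shape:
                raise ValueError(f"{name} mask shape must match channels")
            setattr(self, name, arr)
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if self.uncertainty.shape != self.channels.shape:
                raise ValueError("uncertainty shape must match channels")
        if self.scale not in ("linear", "reflectance"):
            raise ValueError("scale must be 'linear' or 'reflectance'")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[2]

    @property
    def valid(self) -> np.ndarray:
        """Pixels safe to average: neither clipped nor noise-dominated."""
        return ~(self.clipped | self.low_signal)

    def copy_with(self, **changes) -> "CalibratedImage":
        return replace(self, **changes)
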