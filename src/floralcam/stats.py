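"""Region sampling and camera-vs-spectrophotometer comparison statistics.

A calibrated image is compared against spectrophotometer-predicted channel
responses by sampling square pixel regions (point sampling at fixed
centres, or pseudo-random selection of cells from a grid laid over a petal)
and running rank-based two-sample tests, with Shapiro-Wilk normality checks
justifying the use of rank statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .image import CalibratedImage

__all__ = [
    "RegionSample",
    "GridScheme",
    "point_sample",
    "grid_sample",
    "compare_methods",
    "normality_check",
    "variability_summary",
]


@dataclass(eq=False)
class RegionSample:
    """Summary of calibrated values over one pixel region and channel."""

    region_id: str
    channel: int
    pixel_count: int
    mean: float
    sd: float
    values: np.ndarray
    flags_excluded: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.pixel_count != len(self.values) + self.flags_excluded:
            raise ValueError("pixel_count must equal retained + excluded")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class GridScheme:
    """Pseudo-random cell selection from a rows x cols grid over a petal.

    The two schemes in routine use are 4x3 (scheme A) and 6x2 (scheme B);
    ``n_selected`` distinct cells are drawn without replacement.
    """

    rows: int
    cols: int
    cell_size_px: int
    n_selected: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size_px <= 0:
            raise ValueError("cell_size_px must be positive")
        if not 1 <= self.n_selected <= self.rows * self.cols:
            raise ValueError("n_selected must be within 1..rows*cols")

    @classmethod
    def scheme_a(cls, cell_size_px: int = 40, **kw) -> "GridScheme":
        return cls(4, 3, cell_size_px, **kw)

    @classmethod
    def scheme_b(cls, cell_size_px: int = 30, **kw) -> "GridScheme":
        return cls(6, 2, cell_size_px, **kw)


def _sample_square(image: CalibratedImage, region_id: str, r0: int, r1: int,
                   c0: int, c1: int, channel: int) -> RegionSample:
    vals = image.channels[r0:r1, c0:c1, channel]
    ok = image.valid[r0:r1, c0:c1, channel]
    kept = vals[ok]
    n_total = vals.size
    mean = float(kept.mean()) if kept.size else float("nan")
    sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    return RegionSample(region_id, channel, n_total, mean, sd, kept,
                        n_total - kept.size)


def point_sample(image: CalibratedImage, centres, half_size: int = 7,
                 channels=None) -> list[RegionSample]:
    """Square samples of side ``2*half_size + 1`` centred on given pixels.

    The default half_size of 7 gives the standard 15x15 = 225-pixel square.
    Clipped and low-signal pixels are excluded from the statistics and
    counted in ``flags_excluded``.
    """
    h, w, c = image.channels.shape
    channels = range(c) if channels is None else list(np.atleast_1d(channels))
    out = []
    for k, (row, col) in enumerate(centres):
        r0, r1 = row - half_size, row + half_size + 1
        c0, c1 = col - half_size, col + half_size + 1
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError(
                f"sample square at centre ({row}, {col}) with half_size "
                f"{half_size} falls outside the {h}x{w} image")
        for ch in channels:
            out.append(_sample_square(image, f"point_{k}", r0, r1, c0, c1,
                                      int(ch)))
    return out


def grid_sample(image: CalibratedImage, petal_bbox, scheme: GridScheme,
                channels=None) -> list[RegionSample]:
    """Pseudo-randomly select grid cells over a petal bounding box.

    ``petal_bbox`` is (row0, col0) of the grid origin; the grid spans
    ``rows*cell`` by ``cols*cell`` pixels from there.  A 4-tuple
    (row0, row1, col0, col1) is also accepted and must accommodate the grid.
    Cell selection without replacement is driven by the scheme's seed.
    """
    h, w, _ = image.channels.shape
    cell = scheme.cell_size_px
    need_h, need_w = scheme.rows * cell, scheme.cols * cell
    bbox = tuple(int(v) for v in petal_bbox)
    if len(bbox) == 2:
        r0, c0 = bbox
        r1, c1 = r0 + need_h, c0 + need_w
    else:
        r0, r1, c0, c1 = bbox
    if r1 - r0 < need_h or c1 - c0 < need_w:
        max_cell = min((r1 - r0) // scheme.rows, (c1 - c0) // scheme.cols)
        raise ValueError(
            f"bbox too small for a {scheme.rows}x{scheme.cols} grid of "
            f"{cell}px cells; the largest cell size that fits is {max_cell}")
    if r0 < 0 or c0 < 0 or r0 + need_h > h or c0 + need_w > w:
        raise ValueError("grid falls outside the image")

    rng = np.random.default_rng(scheme.seed)
    chosen = rng.choice(scheme.rows * scheme.cols, size=scheme.n_selected,
                        replace=False)
    channels_ = (range(image.n_channels) if channels is None
                 else list(np.atleast_1d(channels)))
    out = []
    for idx in sorted(int(i) for i in chosen):
        gr, gc = divmod(idx, scheme.cols)
        rr0 = r0 + gr * cell
        cc0 = c0 + gc * cell
        for ch in channels_:
            out.append(_sample_square(image, f"cell_{gr}_{gc}", rr0,
                                      rr0 + cell, cc0, cc0 + cell, int(ch)))
    return out


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test: exact null for combined n <= 20 (no ties),
    normal approximation with continuity correction otherwise."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) + len(b) <= 20 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_methods(camera_samples: list[RegionSample], predicted,
                    *, mode: str = "means") -> dict:
    """Compare camera-recovered values against predicted responses.

    ``predicted`` is a list of per-reading predicted relative reflectances
    (one per spectrophotometer reading).  With ``mode="means"`` the camera
    side contributes one value per sampled region (the default, matching a
    region-vs-reading comparison); ``mode="pixels"`` pools the retained
    per-pixel values instead.  Results are reported per channel without
    multiplicity correction, plus a Holm-adjusted column as an extension.
    """
    if mode not in ("means", "pixels"):
        raise ValueError("mode must be 'means' or 'pixels'")
    predicted = np.asarray(predicted, dtype=float)
    channels = sorted({s.channel for s in camera_samples})
    rows = []
    for ch in channels:
        chs = [s for s in camera_samples if s.channel == ch]
        if mode == "means":
            cam = np.array([s.mean for s in chs])
        else:
            cam = np.concatenate([s.values for s in chs]) if chs else \
                np.array([])
        cam = cam[np.isfinite(cam)]
        if len(cam) < 3 or len(predicted) < 3:
            raise ValueError("compare_methods needs >= 3 values per side")
        warning = None
        if np.all(cam == cam[0]) and np.all(predicted == cam[0]):
            stat, p = float("nan"), 1.0
            warning = ("both samples are a single tied value; the rank test "
                       "is degenerate and p is reported as 1")
        else:
            stat, p = _wilcoxon_rank_sum(cam, predicted)
        rows.append({
            "channel": ch,
            "n_camera": int(len(cam)),
            "n_predicted": int(len(predicted)),
            "camera_mean": float(np.mean(cam)),
            "camera_sd": float(np.std(cam, ddof=1)) if len(cam) > 1 else 0.0,
            "predicted_mean": float(np.mean(predicted)),
            "predicted_sd": (float(np.std(predicted, ddof=1))
                             if len(predicted) > 1 else 0.0),
            "direction": ("camera_higher"
                          if np.mean(cam) > np.mean(predicted)
                          else "camera_lower"),
            "statistic": stat,
            "p_value": float(p),
            "warning": warning,
        })
    # Holm adjustment across channels (reported as an extension)
    ps = np.array([r["p_value"] for r in rows])
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * ps[i])
        adj[i] = min(running, 1.0)
    for r, p_adj in zip(rows, adj):
        r["p_holm"] = float(p_adj)
    return {"test": "wilcoxon_rank_sum", "mode": mode, "channels": rows}


def normality_check(sample: RegionSample) -> dict:
    """Shapiro-Wilk normality test on the retained per-pixel values."""
    v = sample.values
    if not 3 <= len(v) <= 5000:
        raise ValueError("normality_check requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("normality_check is undefined for a constant sample")
    w, p = sps.shapiro(v)
    return {"region_id": sample.region_id, "channel": sample.channel,
            "n": int(len(v)), "W": float(w), "p_value": float(p),
            "normal_at_005": bool(p > 0.05)}


def variability_summary(samples_per_channel: dict, *, bins: int = 20) -> dict:
    """Per-channel dispersion of region means, with a channel ranking.

    ``samples_per_channel`` maps a channel label to its list of
    RegionSamples (>= 2 regions each).  Dispersion is the SD of the region
    means; channels are ranked from most to least variable, with ties
    declared when dispersions agree to within 1e-12.
    """
    summary = {}
    for label, samples in samples_per_channel.items():
        means = np.array([s.mean for s in samples])
        means = means[np.isfinite(means)]
        if len(means) < 2:
            raise ValueError(
                f"channel {label!r}: variability needs >= 2 regions")
        pooled_var = float(np.mean([s.sd ** 2 for s in samples]))
        hist, edges = np.histogram(means, bins=bins)
        summary[label] = {
            "n_regions": int(len(means)),
            "mean_of_means": float(means.mean()),
            "sd_of_means": float(means.std(ddof=1)),
            "pooled_within_sd": float(np.sqrt(pooled_var)),
            "histogram": hist.tolist(),
            "bin_edges": edges.tolist(),
        }
    disp = {k: v["sd_of_means"] for k, v in summary.items()}
    ranked = sorted(disp, key=disp.get, reverse=True)
    ranks, current = {}, 0
    prev = None
    for i, k in enumerate(ranked):
        if prev is None or abs(disp[k] - prev) > 1e-12:
            current = i + 1
        ranks[k] = current
        prev = disp[k]
    return {"channels": summary, "dispersion_rank": ranks}
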