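"""Per-pixel temporal statistics, hotspot detection, and ΔI/I trace extraction.

The activity map is built from the per-pixel temporal mean

    μ = (1/N) Σ_k I_k

and the per-pixel temporal standard deviation of the (optionally
normalized) intensity

    σ = sqrt( (1/N) Σ_k (I_k − μ)² )

over the N frames of a recording, using the population normalization 1/N.
Pixels whose σ rises well above the map's own floor form "hotspots" —
localized regions whose intensity fluctuates with the cell's activity.
ROI traces are expressed as ΔI/I: the ROI mean minus the per-frame
background mean, divided by that background mean.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk

from .io import ImageStack, Trace

__all__ = [
    "ActivityMap",
    "Roi",
    "Hotspot",
    "temporal_stats",
    "detect_hotspots",
    "extract_trace",
    "z_profile",
]

_CHUNK = 1024  # frames per pass when accumulating temporal statistics

ROI_LABELS = ("hotspot", "control", "bundle", "background")


@dataclasses.dataclass
class Roi:
    """A labeled circular region of interest.

    ``center`` is a (row, col) pair in pixels (0-based, row-major);
    ``radius`` is in pixels.  The disk must lie fully inside the image it
    is applied to.
    """

    center: tuple[float, float]
    radius: float
    label: str = "hotspot"
    z_index: int = 0

    def __post_init__(self) -> None:
        self.center = (float(self.center[0]), float(self.center[1]))
        if not self.radius >= 1:
            raise ValueError("roi radius must be >= 1 px")
        if self.label not in ROI_LABELS:
            raise ValueError(f"unknown roi label {self.label!r}")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        r, c = self.center
        if (
            r - self.radius < -0.5
            or c - self.radius < -0.5
            or r + self.radius > shape[0] - 0.5
            or c + self.radius > shape[1] - 0.5
        ):
            raise ValueError(
                f"roi disk (center={self.center}, radius={self.radius}) "
                f"extends outside image of shape {shape}"
            )
        m = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk((r, c), self.radius + 0.5, shape=shape)
        m[rr, cc] = True
        return m


@dataclasses.dataclass
class ActivityMap:
    """Paired temporal mean (μ) and SD (σ) matrices plus the analysis mask."""

    mu: np.ndarray
    sigma: np.ndarray
    mask: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        if self.mu.shape != self.sigma.shape or self.mu.shape != self.mask.shape:
            raise ValueError("mu, sigma and mask must share one shape")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


@dataclasses.dataclass
class Hotspot:
    """A detected activity hotspot: its ROI and summary statistics."""

    roi: Roi
    peak_sigma: float
    area_px: int
    centroid: tuple[float, float]


def _background_mask(
    background: Roi | np.ndarray | None, shape: tuple[int, int]
) -> Optional[np.ndarray]:
    if background is None:
        return None
    if isinstance(background, Roi):
        return background.mask(shape)
    bg = np.asarray(background, dtype=bool)
    if bg.shape != shape:
        raise ValueError("background mask shape does not match frames")
    if not bg.any():
        raise ValueError("background mask is empty")
    return bg


def _frame_norm_factors(
    frames: np.ndarray, bg: Optional[np.ndarray]
) -> np.ndarray:
    """Per-frame spatial mean over the background region (whole frame if none)."""
    n = frames.shape[0]
    factors = np.empty(n, dtype=float)
    for i0 in range(0, n, _CHUNK):
        block = frames[i0 : i0 + _CHUNK].astype(np.float64, copy=False)
        if bg is None:
            factors[i0 : i0 + block.shape[0]] = block.mean(axis=(1, 2))
        else:
            factors[i0 : i0 + block.shape[0]] = block[:, bg].mean(axis=1)
    if np.any(factors == 0):
        raise ValueError("background region has zero mean in at least one frame")
    return factors


def temporal_stats(
    stack: ImageStack,
    normalize: bool = True,
    background: Roi | np.ndarray | None = None,
    mask: Optional[np.ndarray] = None,
) -> ActivityMap:
    """Per-pixel temporal mean and population SD of a recording.

    With ``normalize`` set, each frame is first divided by its spatial mean
    over the ``background`` region (the whole frame when no background is
    given), cancelling global illumination drift.  The SD uses the
    population normalization 1/N.  Two passes over the data are made in
    fixed-size chunks, so stacks much larger than memory headroom are fine.
    """
    frames = stack.frames
    n, h, w = frames.shape
    bg = _background_mask(background, (h, w))
    factors = _frame_norm_factors(frames, bg) if normalize else np.ones(n)

    s1 = np.zeros((h, w), dtype=np.float64)
    for i0 in range(0, n, _CHUNK):
        block = frames[i0 : i0 + _CHUNK].astype(np.float64)
        block /= factors[i0 : i0 + block.shape[0], None, None]
        s1 += block.sum(axis=0)
    mu = s1 / n

    s2 = np.zeros((h, w), dtype=np.float64)
    for i0 in range(0, n, _CHUNK):
        block = frames[i0 : i0 + _CHUNK].astype(np.float64)
        block /= factors[i0 : i0 + block.shape[0], None, None]
        block -= mu
        s2 += (block * block).sum(axis=0)
    sigma = np.sqrt(np.clip(s2 / n, 0.0, None))

    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    return ActivityMap(mu=mu, sigma=sigma, mask=mask, normalized=normalize)


def detect_hotspots(
    amap: ActivityMap,
    k_sigma: float = 3.0,
    min_area: int = 4,
    roi_radius: float = 5.0,
) -> list[Hotspot]:
    """Threshold the σ map and group supra-threshold pixels into hotspots.

    Pixels with ``σ > mean(σ|mask) + k_sigma · sd(σ|mask)`` are grouped by
    8-connectivity; components of at least ``min_area`` pixels become
    hotspots whose ROI is a disk of ``roi_radius`` centered at the
    σ-weighted centroid (clamped so the disk stays inside the image).
    Returned sorted by peak σ, descending; ties broken by (row, col) order
    of the centroid.
    """
    if not amap.mask.any():
        raise ValueError("analysis mask is empty")
    vals = amap.sigma[amap.mask]
    thr = vals.mean() + k_sigma * vals.std()
    binary = (amap.sigma > thr) & amap.mask
    labels, n_comp = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    h, w = amap.sigma.shape
    hotspots: list[Hotspot] = []
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        rr, cc = np.nonzero(comp)
        weights = amap.sigma[rr, cc]
        centroid = (
            float(np.average(rr, weights=weights)),
            float(np.average(cc, weights=weights)),
        )
        center = (
            float(np.clip(centroid[0], roi_radius, h - 1 - roi_radius)),
            float(np.clip(centroid[1], roi_radius, w - 1 - roi_radius)),
        )
        hotspots.append(
            Hotspot(
                roi=Roi(center=center, radius=roi_radius, label="hotspot"),
                peak_sigma=float(weights.max()),
                area_px=area,
                centroid=centroid,
            )
        )
    hotspots.sort(key=lambda hs: (-hs.peak_sigma, hs.centroid[0], hs.centroid[1]))
    return hotspots


def _roi_means(frames: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n = frames.shape[0]
    out = np.empty(n, dtype=float)
    for i0 in range(0, n, _CHUNK):
        out[i0 : i0 + min(_CHUNK, n - i0)] = (
            frames[i0 : i0 + _CHUNK][:, mask].astype(np.float64).mean(axis=1)
        )
    return out


def extract_trace(stack: ImageStack, roi: Roi, background: Roi) -> Trace:
    """ΔI/I trace of an ROI, normalized per frame to a background ROI.

    For each frame k:

        ΔI/I[k] = (mean(I_k | roi) − mean(I_k | background)) / mean(I_k | background)

    The two disks must be disjoint; a zero background mean in any frame is
    an error.
    """
    shape = stack.frame_shape
    roi_mask = roi.mask(shape)
    bg_mask = background.mask(shape)
    if (roi_mask & bg_mask).any():
        raise ValueError("roi and background disks overlap")
    roi_means = _roi_means(stack.frames, roi_mask)
    bg_means = _roi_means(stack.frames, bg_mask)
    if np.any(bg_means == 0):
        raise ValueError("background mean is zero in at least one frame")
    values = (roi_means - bg_means) / bg_means
    return Trace(values=values, sample_rate=stack.frame_rate, kind="delta_i_over_i")


def z_profile(
    hotspot_traces: Iterable[tuple[int, Trace]],
    bundle: Trace,
    max_lag: Optional[int] = None,
    min_overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """Maximal shifted correlation of each per-depth trace with the bundle.

    Returns a table with columns ``z_index``, ``max_corr``, ``lag``
    (samples), one row per axial section, mirroring the depth profiles
    measured by refocusing the same x-y ROI through the soma.
    """
    from .signal_analysis import max_shift_correlation

    rows = []
    for z, trace in hotspot_traces:
        if trace.sample_rate != bundle.sample_rate:
            raise ValueError(f"sample-rate mismatch at z={z}")
        res = max_shift_correlation(
            bundle, trace, max_lag=max_lag, min_overlap_frac=min_overlap_frac
        )
        rows.append({"z_index": int(z), "max_corr": res.max_corr, "lag": res.lag})
    return pd.DataFrame(rows, columns=["z_index", "max_corr", "lag"])
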