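"""Visualization: over-exposure blob score.

Saturated regions carry no diagnostic information, and saturation is a
common signature of the scope tip touching the tract wall — an event to be
avoided.  Per frame:

1. mask pixels with intensity strictly above the saturation threshold
   (default 245);
2. denoise: 3x3 morphological opening, then drop connected components
   (8-connectivity) smaller than a minimum area;
3. for each surviving blob, measure its area as a percent of the frame and
   the distance d from the frame centre O to the blob centroid C;
4. weight the area by how central the blob is, relative to the frame's
   half-diagonal r:

       w = 1    for 0 <= d <= r/3
       w = 2/3  for r/3 < d < 2r/3
       w = 1/3  for 2r/3 <= d <= r

   (a central washout obscures more of the working view than a peripheral
   one);
5. the frame's weighted area wA is the maximum w * area over its blobs, or
   0 when no blob survives.

The session score is ``Visualization = (1 - mean(wA) / 100) * 100``, so a
saturation-free video scores 100 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_opening
from skimage.measure import label, regionprops

from .config import ExposureConfig
from .errors import ComputationError
from .video_io import FrameSample, FrameStream, sample_frames


def half_diagonal(height: int, width: int) -> float:
    """Half the frame diagonal, measured between pixel centres."""
    return math.hypot(width - 1, height - 1) / 2.0


def frame_center(height: int, width: int) -> tuple[float, float]:
    """Frame centre O in (row, col) pixel-centre coordinates."""
    return ((height - 1) / 2.0, (width - 1) / 2.0)


def overexposure_mask(frame: "FrameSample | np.ndarray",
                      cfg: ExposureConfig | None = None) -> np.ndarray:
    """Binary mask of pixels strictly above the saturation threshold."""
    cfg = cfg or ExposureConfig()
    pixels = frame.pixels if isinstance(frame, FrameSample) else np.asarray(frame)
    return (pixels > cfg.saturation_threshold).astype(np.uint8)


def weight_for_distance(d: float, r: float,
                        cfg: ExposureConfig | None = None) -> float:
    """Centre-distance weight for a blob centroid at distance d from O."""
    cfg = cfg or ExposureConfig()
    if r <= 0:
        raise ValueError("half-diagonal r must be positive")
    if d < 0 or d > r * (1 + 1e-9):
        raise ValueError(f"distance d={d} outside [0, r={r}]")
    lo, hi = cfg.weight_breaks
    w_in, w_mid, w_out = cfg.weights
    if d <= lo * r:
        return w_in
    if d < hi * r:
        return w_mid
    return w_out


@dataclass(frozen=True)
class BlobMeasurement:
    """One over-exposed blob after denoising."""

    centroid: tuple[float, float]  # (row, col) pixel coordinates, C
    area_percent: float            # percent of frame area
    distance: float                # |OC| in pixels, d
    weight: float                  # w from the annulus bands
    weighted_area: float           # w * area_percent


def denoise_and_blobs(mask: np.ndarray,
                      cfg: ExposureConfig | None = None) -> list[BlobMeasurement]:
    """Denoise a saturation mask and measure its connected components.

    Opening removes salt noise; components below ``min_blob_area`` percent
    of the frame are discarded.  Centroids are unweighted means of member
    pixel coordinates.
    """
    cfg = cfg or ExposureConfig()
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    # Pixels outside the frame count as unsaturated, so the opening trims
    # blobs at the frame edge (scipy's zero border convention).
    footprint = np.ones((cfg.opening_size, cfg.opening_size), dtype=bool)
    opened = binary_opening(mask.astype(bool), structure=footprint)
    labeled = label(opened, connectivity=2)
    n_pixels = mask.size
    center = frame_center(*mask.shape)
    r = half_diagonal(*mask.shape)
    min_pixels = cfg.min_blob_area / 100.0 * n_pixels
    blobs: list[BlobMeasurement] = []
    for region in regionprops(labeled):
        if region.area < min_pixels:
            continue
        cy, cx = region.centroid
        d = math.hypot(cy - center[0], cx - center[1])
        d = min(d, r)  # guard against fp rounding at the extreme corner
        w = weight_for_distance(d, r, cfg)
        area_pct = 100.0 * region.area / n_pixels
        blobs.append(BlobMeasurement(centroid=(cy, cx), area_percent=area_pct,
                                     distance=d, weight=w,
                                     weighted_area=w * area_pct))
    return blobs


def frame_exposure(frame: "FrameSample | np.ndarray",
                   cfg: ExposureConfig | None = None) -> float:
    """Weighted over-exposed area wA of one frame, percent in [0, 100].

    With multiple blobs the maximum weighted area is chosen; a frame with
    no surviving blob contributes 0.
    """
    cfg = cfg or ExposureConfig()
    blobs = denoise_and_blobs(overexposure_mask(frame, cfg), cfg)
    if not blobs:
        return 0.0
    return min(100.0, max(b.weighted_area for b in blobs))


@dataclass(frozen=True)
class ExposureSample:
    timestamp: float
    weighted_area: float  # wA_i, percent


@dataclass(frozen=True)
class ExposureTrace:
    samples: tuple[ExposureSample, ...]
    session_score: float

    @property
    def weighted_areas(self) -> np.ndarray:
        return np.array([s.weighted_area for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestamp_s": [s.timestamp for s in self.samples],
            "weighted_area_percent": [s.weighted_area for s in self.samples],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def visualization(stream_or_frames: "FrameStream | Iterable[FrameSample]",
                  cfg: ExposureConfig | None = None) -> ExposureTrace:
    """Session Visualization score from per-frame weighted areas.

    By default frames are sampled at the same 0.3 s cadence as the motion
    metric so the two traces align; set ``cfg.full_rate`` to evaluate every
    frame.  The score is clamped to [0, 100].
    """
    cfg = cfg or ExposureConfig()
    if isinstance(stream_or_frames, FrameStream):
        if cfg.full_rate:
            frames: Sequence[FrameSample] = list(stream_or_frames)
        else:
            frames = sample_frames(stream_or_frames, cfg.interval)
    else:
        frames = list(stream_or_frames)
    if not frames:
        raise ComputationError("visualization undefined: no frames")
    samples = tuple(
        ExposureSample(timestamp=f.timestamp, weighted_area=frame_exposure(f, cfg))
        for f in frames)
    mean_wa = float(np.mean([s.weighted_area for s in samples]))
    score = min(100.0, max(0.0, (1.0 - mean_wa / 100.0) * 100.0))
    return ExposureTrace(samples=samples, session_score=score)
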