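"""Fine Movement: frame-differencing motion score.

The scope-tip speed is proxied by how much of the image changes over a
0.3 s interval.  For each sampled frame pair the pipeline is

    D_i(x, y)  = |I_i(x, y) - I_{i-0.3s}(x, y)|          (absolute difference)
    BW_i(x, y) = 1 if D_i(x, y) > DTh else 0             (binarize, DTh = 50)
    A_i        = 100 * sum(BW_i) / (width * height)      (coverage percent)

and the per-pair score is 100 when A_i lies inside the band
[eps_low, eps_high] (boundaries inclusive) and 0 otherwise: only an
appropriate moving speed scores, too slow or too fast scores zero.  The
session Fine Movement score is the arithmetic mean of the per-pair scores,
zero-score pairs included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import MotionConfig
from .errors import ComputationError
from .video_io import FramePair, FrameStream, sample_pairs


def difference_image(pair_or_current: "FramePair | np.ndarray",
                     previous: np.ndarray | None = None) -> np.ndarray:
    """Elementwise absolute grayscale difference of a frame pair.

    Accepts either a :class:`FramePair` or two raw 2-D arrays.  Symmetric in
    its operands; output is uint8 in [0, 255].
    """
    if isinstance(pair_or_current, FramePair):
        a = pair_or_current.current.pixels
        b = pair_or_current.previous.pixels
    else:
        if previous is None:
            raise TypeError("previous frame required when passing raw arrays")
        a, b = np.asarray(pair_or_current), np.asarray(previous)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return np.abs(a.astype(np.int16) - b.astype(np.int16)).astype(np.uint8)


def binarize(diff: np.ndarray, threshold: int = 50) -> np.ndarray:
    """Binary change mask: 1 where the difference strictly exceeds DTh."""
    if not 0 < threshold < 255:
        raise ValueError("threshold must lie in (0, 255)")
    return (np.asarray(diff) > threshold).astype(np.uint8)


def coverage(mask: np.ndarray) -> float:
    """Percentage of frame pixels set in a binary mask."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def frame_score(coverage_percent: float, cfg: MotionConfig | None = None) -> float:
    """Per-pair band score: 100 inside [eps_low, eps_high], else 0."""
    cfg = cfg or MotionConfig()
    return 100.0 if cfg.eps_low <= coverage_percent <= cfg.eps_high else 0.0


@dataclass(frozen=True)
class MotionSample:
    timestamp: float
    coverage: float  # A_i, percent
    score: float     # 0 or 100


@dataclass(frozen=True)
class MotionTrace:
    """Per-pair coverage/score series plus the session aggregate."""

    samples: tuple[MotionSample, ...]
    session_score: float

    @property
    def coverages(self) -> np.ndarray:
        return np.array([s.coverage for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestamp_s": [s.timestamp for s in self.samples],
            "coverage_percent": [s.coverage for s in self.samples],
            "frame_score": [s.score for s in self.samples],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"session_score": self.session_score,
                   "samples": self.to_frame().to_dict(orient="records")}
        Path(path).write_text(json.dumps(payload))


def fine_movement(stream_or_pairs: "FrameStream | Iterable[FramePair]",
                  cfg: MotionConfig | None = None) -> MotionTrace:
    """Score a whole session.

    Accepts a :class:`FrameStream` (pairs are sampled at ``cfg.interval``)
    or a pre-sampled pair sequence.  Raises :class:`ComputationError` when
    no pair can be formed (stream shorter than one interval).
    """
    cfg = cfg or MotionConfig()
    if isinstance(stream_or_pairs, FrameStream):
        pairs: Sequence[FramePair] = sample_pairs(stream_or_pairs, cfg.interval)
    else:
        pairs = list(stream_or_pairs)
    if not pairs:
        raise ComputationError("fine movement undefined: no frame pairs")
    samples = []
    for pair in pairs:
        cov = coverage(binarize(difference_image(pair), cfg.diff_threshold))
        samples.append(MotionSample(timestamp=pair.current.timestamp,
                                    coverage=cov,
                                    score=frame_score(cov, cfg)))
    session = float(np.mean([s.score for s in samples]))
    return MotionTrace(samples=tuple(samples), session_score=session)
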