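"""Synthetic endoscopy sessions with closed-form ground truth.

The generator renders grayscale frame sequences that look nothing like a
kidney but exercise every measurement path of the scoring pipeline with
*exact* expectations:

* **Motion** is realized by construction: the scene is piecewise constant
  over each differencing interval, and at each interval boundary exactly
  ``round(f/100 * N)`` background pixels (f = commanded percent, N = frame
  pixels) are toggled by ±70 grayscale units — always beyond the DTh = 50
  difference threshold, never into saturation.  The measured coverage A_i
  therefore equals the commanded fraction to within rounding.
* **Over-exposure** is injected as solid saturated (255) elliptical blobs
  whose pixel sets are chosen by exact count (the ``round(area% * N/100)``
  pixels nearest an elliptical distance from the commanded centroid), with
  the centroid placed at a commanded fraction of the half-diagonal so the
  centre-distance weight is known analytically.
* **Targets** are small bright (non-saturated) stone sprites appearing at
  known times, mirrored in the emitted annotation log.

Event times are snapped to interval boundaries, and blob/stone pixels are
excluded from motion toggling, so :class:`GroundTruth` — computed from the
scene spec alone, never from rendered frames — is sharp rather than
statistical.  The background is a vessel-like texture of dark random
curves on a mid-gray field, confined to [60, 185] so toggles stay inside
[0, 245].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.ndimage import gaussian_filter

from .config import RunConfig
from .errors import SchemaError
from .tasks import SessionAnnotation, duration_score, efficiency, target_detection
from .video_io import FrameStream, from_arrays, write_frame_dir

BG_LOW, BG_HIGH = 60, 185     # background gray range; ±70 toggles stay in [0,255]
TOGGLE = 70                   # per-pixel change at a boundary, > DTh
STONE_VALUE = 220             # bright but below the 245 saturation threshold
STONE_BG_CAP = 160            # bg under stones capped so stone appearance diffs > DTh
STONE_AREA_PERCENT = 0.15     # sprite size, % of frame


class BlobEvent(BaseModel):
    """A saturated blob present over [start_s, end_s), geometry commanded."""

    start_s: float = Field(ge=0.0)
    end_s: float = Field(gt=0.0)
    area_percent: float = Field(gt=0.0, le=50.0)
    center_frac: float = Field(ge=0.0, le=0.95,
                               description="centroid distance from frame centre, "
                                           "as a fraction of the half-diagonal r")
    angle_deg: float = Field(default=36.87,
                             description="direction of the centroid offset; the "
                                         "default points at the bottom-right corner "
                                         "of a 4:3 frame")
    axis_ratio: float = Field(default=1.6, ge=1.0)
    orientation_deg: float = Field(default=0.0)

    @model_validator(mode="after")
    def _order(self) -> "BlobEvent":
        if self.end_s <= self.start_s:
            raise ValueError("blob end_s must exceed start_s")
        return self


class StoneEvent(BaseModel):
    """A detected artificial stone appearing at a known time."""

    target_id: str
    time_s: float = Field(ge=0.0)


class SyntheticSceneSpec(BaseModel):
    """Complete ground-truth description of a synthetic session."""

    session_id: str = "synthetic"
    subject_group: str = Field(default="professional",
                               pattern="^(professional|trainee)$")
    trial_index: int = Field(default=0, ge=0)
    width: int = Field(default=160, ge=16)
    height: int = Field(default=120, ge=16)
    fps: float = Field(default=10.0, gt=0.0)
    duration_s: float = Field(default=12.0, gt=0.0)
    interval: float = Field(default=0.3, gt=0.0)
    motion_profile: list[float] = Field(default_factory=list,
                                        description="commanded changed-pixel % per interval")
    blob_events: list[BlobEvent] = Field(default_factory=list)
    stone_events: list[StoneEvent] = Field(default_factory=list)
    total_targets: int = Field(default=3, ge=1)
    session_time_min: float | None = Field(default=None, gt=0.0,
                                           description="procedure wall-clock time; "
                                                       "defaults to the clip length")
    seed: int = Field(default=0, ge=0)

    @property
    def n_intervals(self) -> int:
        return int(math.floor(self.duration_s / self.interval + 1e-9))

    @property
    def frames_per_interval(self) -> int:
        return int(round(self.interval * self.fps))

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSceneSpec":
        if abs(self.interval * self.fps - round(self.interval * self.fps)) > 1e-6:
            raise ValueError("interval * fps must be integral for exact construction")
        if self.frames_per_interval < 1:
            raise ValueError("fps too low for the differencing interval")
        if self.n_intervals < 1:
            raise ValueError("duration shorter than one interval")
        if self.motion_profile and len(self.motion_profile) != self.n_intervals:
            raise ValueError(
                f"motion_profile length {len(self.motion_profile)} != "
                f"{self.n_intervals} intervals")
        for f in self.motion_profile:
            if not 0.0 <= f <= 100.0:
                raise ValueError("motion fractions must lie in [0, 100]")
        for ev in self.blob_events:
            if ev.start_s > self.duration_s:
                raise ValueError("blob event starts after the session ends")
        for ev in self.stone_events:
            if ev.time_s > self.duration_s:
                raise ValueError("stone event after the session ends")
        ids = [e.target_id for e in self.stone_events]
        if len(ids) != len(set(ids)):
            raise ValueError("stone target_ids must be unique")
        if len(ids) > self.total_targets:
            raise ValueError("more stone events than total_targets")
        return self

    # -- snapped event geometry ------------------------------------------

    def snap_segment(self, t: float) -> int:
        """Interval-boundary index nearest t, clipped to [0, n_intervals]."""
        return min(self.n_intervals, max(0, int(round(t / self.interval))))

    def blob_segments(self, ev: BlobEvent) -> tuple[int, int]:
        """Active segment span [s0, s1) of a blob event after snapping."""
        s0 = self.snap_segment(ev.start_s)
        s1 = max(s0 + 1, int(round(ev.end_s / self.interval)))
        return s0, min(s1, self.n_intervals + 1)

    def blob_pixel_count(self, ev: BlobEvent) -> int:
        return max(1, int(round(ev.area_percent / 100.0 * self.n_pixels)))

    @property
    def stone_pixel_count(self) -> int:
        return max(1, int(round(STONE_AREA_PERCENT / 100.0 * self.n_pixels)))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSceneSpec":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise SchemaError(f"cannot read scene spec {path}: {exc}") from exc
        try:
            return cls.model_validate(payload)
        except ValueError as exc:
            raise SchemaError(f"invalid scene spec {path}: {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2, exclude_none=True))


def blob_weight(center_frac: float, cfg: RunConfig | None = None) -> float:
    """Analytic centre-distance weight for a commanded centroid fraction."""
    cfg = cfg or RunConfig()
    lo, hi = cfg.exposure.weight_breaks
    w_in, w_mid, w_out = cfg.exposure.weights
    if center_frac <= lo:
        return w_in
    if center_frac < hi:
        return w_mid
    return w_out


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expectations for one synthetic session.

    Derived entirely from the scene spec (pixel counts are exact by
    construction); the renderer is never consulted.
    """

    expected_coverage: tuple[float, ...]       # A_i per interval, k = 1..K
    expected_weighted_area: tuple[float, ...]  # wA per sampled frame, k = 0..K
    expected_target_detection: float
    session_time_min: float
    n_pixels: int

    def expected_scores(self, cfg: RunConfig | None = None) -> dict[str, float]:
        cfg = cfg or RunConfig()
        in_band = [cfg.motion.eps_low <= a <= cfg.motion.eps_high
                   for a in self.expected_coverage]
        fm = 100.0 * float(np.mean(in_band))
        vis = 100.0 - float(np.mean(self.expected_weighted_area))
        dur = duration_score(self.session_time_min, cfg.efficiency)
        eff = efficiency(self.expected_target_detection, dur)
        return {"fine_movement": fm, "visualization": vis,
                "target_detection": self.expected_target_detection,
                "duration": dur, "efficiency": eff}

    def to_json(self, path: str | Path, cfg: RunConfig | None = None) -> None:
        payload = {
            "expected_coverage_percent": list(self.expected_coverage),
            "expected_weighted_area_percent": list(self.expected_weighted_area),
            "expected_target_detection": self.expected_target_detection,
            "session_time_min": self.session_time_min,
            "n_pixels": self.n_pixels,
            "expected_scores_default_config": self.expected_scores(cfg),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def ground_truth(spec: SyntheticSceneSpec,
                 cfg: RunConfig | None = None) -> GroundTruth:
    """Compute the analytic expectations for a scene spec."""
    n_px = spec.n_pixels
    K = spec.n_intervals
    stone_segs = sorted(spec.snap_segment(ev.time_s) for ev in spec.stone_events)

    coverage = []
    for k in range(1, K + 1):
        changed = 0
        if spec.motion_profile:
            changed += int(round(spec.motion_profile[k - 1] / 100.0 * n_px))
        for ev in spec.blob_events:
            s0, s1 = spec.blob_segments(ev)
            if k == s0 or k == s1:  # blob appears or disappears at boundary k
                changed += spec.blob_pixel_count(ev)
        changed += spec.stone_pixel_count * stone_segs.count(k)
        coverage.append(100.0 * changed / n_px)

    weighted = []
    for k in range(0, K + 1):
        wa = 0.0
        for ev in spec.blob_events:
            s0, s1 = spec.blob_segments(ev)
            if s0 <= k < s1:
                area = 100.0 * spec.blob_pixel_count(ev) / n_px
                wa = max(wa, blob_weight(ev.center_frac, cfg) * area)
        weighted.append(wa)

    td = 100.0 * len(spec.stone_events) / spec.total_targets
    t_min = spec.session_time_min or spec.duration_s / 60.0
    return GroundTruth(expected_coverage=tuple(coverage),
                       expected_weighted_area=tuple(weighted),
                       expected_target_detection=td,
                       session_time_min=t_min,
                       n_pixels=n_px)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _exact_blob_pixels(height: int, width: int, center_rc: tuple[float, float],
                       n: int, axis_ratio: float,
                       orientation_deg: float) -> np.ndarray:
    """Flat indices of the n pixels nearest an elliptical distance from center.

    Exact-count selection: the blob always contains n pixels even when the
    commanded ellipse would clip the frame edge (selection then fills
    inward).  Ties are broken by flat index, so the set is deterministic.
    """
    rows, cols = np.indices((height, width))
    dr = rows - center_rc[0]
    dc = cols - center_rc[1]
    theta = math.radians(orientation_deg)
    u = dc * math.cos(theta) + dr * math.sin(theta)   # along major axis
    v = -dc * math.sin(theta) + dr * math.cos(theta)
    dist = (u / axis_ratio) ** 2 + v ** 2
    order = np.argsort(dist.ravel(), kind="stable")
    return order[:n]


def _vessel_background(height: int, width: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Mid-gray field with dark meandering curves, mimicking mucosal vessels."""
    img = np.full((height, width), 150.0)
    img += rng.normal(0.0, 12.0, size=img.shape)
    n_vessels = max(6, (height * width) // 2500)
    for _ in range(n_vessels):
        r = rng.uniform(0, height)
        c = rng.uniform(0, width)
        ang = rng.uniform(0, 2 * math.pi)
        for _step in range(rng.integers(20, 60)):
            ang += rng.normal(0, 0.35)
            r = min(height - 1, max(0, r + math.sin(ang)))
            c = min(width - 1, max(0, c + math.cos(ang)))
            img[int(r), int(c)] = 75.0
    img = gaussian_filter(img, sigma=0.8)
    lo, hi = img.min(), img.max()
    img = BG_LOW + (img - lo) / max(hi - lo, 1e-9) * (BG_HIGH - BG_LOW)
    return np.clip(np.round(img), BG_LOW, BG_HIGH).astype(np.uint8)


def _toggle(values: np.ndarray) -> np.ndarray:
    """±70 toggle keeping values inside [BG_LOW-2, BG_HIGH+12] ⊂ [0, 245)."""
    return np.where(values < 128, values + TOGGLE, values - TOGGLE)


@dataclass
class RenderedSession:
    """A rendered synthetic session: frames, annotation log and oracle."""

    spec: SyntheticSceneSpec
    stream: FrameStream
    annotation: SessionAnnotation
    truth: GroundTruth


def render(spec: SyntheticSceneSpec, cfg: RunConfig | None = None) -> RenderedSession:
    """Render a scene spec into frames + annotation + ground truth.

    Deterministic: the same spec (which includes the seed) yields
    bit-identical frames.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    n_px = spec.n_pixels
    K = spec.n_intervals
    step = spec.frames_per_interval
    n_frames = step * K + 1  # inclusive endpoint so the last pair spans K-1 -> K

    # --- static geometry -------------------------------------------------
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    r = math.hypot(w - 1, h - 1) / 2.0
    blob_pixels: list[np.ndarray] = []
    occupied = np.zeros(n_px, dtype=bool)
    for ev in spec.blob_events:
        ang = math.radians(ev.angle_deg)
        c_rc = (center[0] + ev.center_frac * r * math.sin(ang),
                center[1] + ev.center_frac * r * math.cos(ang))
        px = _exact_blob_pixels(h, w, c_rc, spec.blob_pixel_count(ev),
                                ev.axis_ratio, ev.orientation_deg)
        if occupied[px].any():
            raise SchemaError("blob events overlap spatially; adjust geometry")
        occupied[px] = True
        blob_pixels.append(px)

    stone_pixels: list[np.ndarray] = []
    for ev in spec.stone_events:
        placed = None
        for _attempt in range(200):
            c_rc = (rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w))
            px = _exact_blob_pixels(h, w, c_rc, spec.stone_pixel_count, 1.0, 0.0)
            if not occupied[px].any():
                placed = px
                break
        if placed is None:
            raise SchemaError("cannot place stone sprite without overlap")
        occupied[placed] = True
        stone_pixels.append(placed)

    # --- background segments ---------------------------------------------
    base = _vessel_background(h, w, rng).ravel()
    for px in stone_pixels:  # keep stone-appearance diffs above DTh
        base[px] = np.minimum(base[px], STONE_BG_CAP)
    free_idx = np.flatnonzero(~occupied)

    segments = [base.copy()]
    profile = spec.motion_profile or [0.0] * K
    for k in range(1, K + 1):
        seg = segments[-1].copy()
        n_changed = int(round(profile[k - 1] / 100.0 * n_px))
        if n_changed > free_idx.size:
            raise SchemaError(
                f"interval {k}: commanded fraction {profile[k - 1]}% exceeds "
                f"the pixels available outside blobs and stones")
        if n_changed:
            chosen = rng.choice(free_idx, size=n_changed, replace=False)
            seg[chosen] = _toggle(seg[chosen])
        segments.append(seg)

    # --- composite frames -------------------------------------------------
    stone_segs = [spec.snap_segment(ev.time_s) for ev in spec.stone_events]
    blob_spans = [spec.blob_segments(ev) for ev in spec.blob_events]
    composed: list[np.ndarray] = []
    for k in range(K + 1):
        img = segments[k].copy()
        for px, s_appear in zip(stone_pixels, stone_segs):
            if k >= s_appear:
                img[px] = STONE_VALUE
        for px, (s0, s1) in zip(blob_pixels, blob_spans):
            if s0 <= k < s1:
                img[px] = 255
        composed.append(img.reshape(h, w).astype(np.uint8))

    frames = [composed[min(j // step, K)] for j in range(n_frames)]
    stream = from_arrays(frames, fps=spec.fps,
                         source=f"synthetic:{spec.session_id}")

    annotation = SessionAnnotation(
        session_id=spec.session_id,
        subject_group=spec.subject_group,
        trial_index=spec.trial_index,
        total_targets=spec.total_targets,
        detected_events=[{"target_id": ev.target_id,
                          "time_s": round(spec.snap_segment(ev.time_s)
                                          * spec.interval, 9)}
                         for ev in spec.stone_events],
        session_time_min=spec.session_time_min or spec.duration_s / 60.0,
    )
    return RenderedSession(spec=spec, stream=stream, annotation=annotation,
                           truth=ground_truth(spec, cfg))


def write_session(session: RenderedSession, out_dir: str | Path,
                  cfg: RunConfig | None = None) -> Path:
    """Write a rendered session to disk: PNG frames + JSON sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_frame_dir(session.stream, out_dir / "frames")
    session.annotation.to_json(out_dir / "annotation.json")
    session.truth.to_json(out_dir / "ground_truth.json", cfg)
    session.spec.to_json(out_dir / "scene_spec.json")
    return out_dir


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def profile_presets(kind: str, seed: int = 0, trial_index: int = 0,
                    width: int = 160, height: int = 120, fps: float = 10.0,
                    duration_s: float = 12.0) -> SyntheticSceneSpec:
    """Scene specs emulating the two study groups at desk scale.

    The *professional* preset moves the scope smoothly at an in-band speed,
    shows only rare small central washouts, exposes all three stones and
    finishes around the reported 4.3 min group mean.  The *trainee* preset
    alternates near-static and abrupt out-of-band motion, suffers frequent
    larger and more peripheral washouts, usually misses a stone and runs
    around the reported 15.4 min mean (over the 5 min budget).  Per-trial
    jitter is seeded so groups have within-group variance.
    """
    kind_code = {"professional": 1, "trainee": 2}.get(kind)
    if kind_code is None:
        raise ValueError(f"unknown preset kind {kind!r}")
    rng = np.random.default_rng([kind_code, seed, trial_index])
    base = SyntheticSceneSpec(width=width, height=height, fps=fps,
                              duration_s=duration_s)
    K = base.n_intervals
    dur = duration_s

    if kind == "professional":
        f = 7.0 + 4.0 * np.sin(2 * np.pi * np.arange(K) / max(K, 1)) \
            + rng.normal(0.0, 1.0, size=K)
        f = np.clip(f, 1.5, 18.0)
        pauses = rng.choice(K, size=max(1, K // 20), replace=False)
        f[pauses] = 0.1  # brief careful pauses, below eps_low
        blob = BlobEvent(start_s=0.25 * dur, end_s=0.45 * dur,
                         area_percent=float(1.2 + rng.uniform(0.0, 0.6)),
                         center_frac=float(rng.uniform(0.08, 0.16)))
        blobs = [blob]
        stones = [StoneEvent(target_id=f"stone_{i}", time_s=t * dur)
                  for i, t in enumerate((0.2, 0.5, 0.8))]
        t_min = float(np.clip(4.3 + rng.normal(0.0, 0.3), 3.5, 4.95))
        group = "professional"
    else:
        f = np.where(np.arange(K) % 2 == 0,
                     rng.uniform(0.0, 0.3, size=K),
                     rng.uniform(28.0, 45.0, size=K))
        ok = rng.choice(K, size=max(1, K // 10), replace=False)
        f[ok] = rng.uniform(5.0, 15.0, size=ok.size)  # occasional good moves
        blobs = [
            BlobEvent(start_s=0.10 * dur, end_s=0.60 * dur,
                      area_percent=float(10.0 + rng.uniform(0.0, 4.0)),
                      center_frac=float(rng.uniform(0.45, 0.55)),
                      angle_deg=36.87),
            BlobEvent(start_s=0.65 * dur, end_s=0.90 * dur,
                      area_percent=float(1.6 + rng.uniform(0.0, 0.6)),
                      center_frac=float(rng.uniform(0.74, 0.80)),
                      angle_deg=36.87 + 180.0),  # opposite corner, no overlap
        ]
        n_detected = 2 if rng.random() < 0.75 else 3
        stones = [StoneEvent(target_id=f"stone_{i}", time_s=t * dur)
                  for i, t in enumerate((0.3, 0.7, 0.9)[:n_detected])]
        t_min = float(np.clip(15.4 + rng.normal(0.0, 1.2), 12.0, 19.0))
        group = "trainee"

    return SyntheticSceneSpec(
        session_id=f"{kind}_{trial_index:02d}",
        subject_group=group,
        trial_index=trial_index,
        width=width, height=height, fps=fps, duration_s=duration_s,
        motion_profile=[float(x) for x in f],
        blob_events=blobs,
        stone_events=stones,
        total_targets=3,
        session_time_min=t_min,
        seed=int(rng.integers(0, 2 ** 31)),
    )
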