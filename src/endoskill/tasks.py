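"""Target Detection and Efficiency from the session annotation log.

These two metrics do not look at pixels: the annotation log records which
of the placed artificial stones the subject exposed (with timestamps) and
how long the procedure took.  Target Detection is the detected fraction in
percent; the Duration score rewards finishing under the Tmax = 5 min
budget,

    Duration = 100 * (Tmax - T) / Tmax        (clamped at 0 when T >= Tmax)

and Efficiency averages Target Detection with the (trial-averaged)
Duration score.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, ValidationError, model_validator

from .config import EfficiencyConfig
from .errors import SchemaError


class DetectionEvent(BaseModel):
    target_id: str
    time_s: float = Field(ge=0.0, description="seconds from session start")


class SessionAnnotation(BaseModel):
    """One trial's annotation log.

    ``session_time_min`` may be given directly or derived from
    ``session_start_s``/``session_end_s``.
    """

    session_id: str
    subject_group: str = Field(pattern="^(professional|trainee)$")
    trial_index: int = Field(ge=0)
    total_targets: int = Field(default=3, ge=1)
    detected_events: list[DetectionEvent] = Field(default_factory=list)
    session_time_min: float | None = Field(default=None, gt=0.0)
    session_start_s: float | None = None
    session_end_s: float | None = None

    @model_validator(mode="after")
    def _finalize(self) -> "SessionAnnotation":
        ids = [e.target_id for e in self.detected_events]
        if len(ids) != len(set(ids)):
            raise ValueError("detected target_ids must be unique")
        if len(ids) > self.total_targets:
            raise ValueError("more detections than placed targets")
        if self.session_time_min is None:
            if self.session_start_s is None or self.session_end_s is None:
                raise ValueError(
                    "either session_time_min or session_start_s/session_end_s required")
            span = self.session_end_s - self.session_start_s
            if span <= 0:
                raise ValueError("session_end_s must exceed session_start_s")
            object.__setattr__(self, "session_time_min", span / 60.0)
        return self

    @property
    def detected_count(self) -> int:
        return len(self.detected_events)

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionAnnotation":
        path = Path(path)
        try:
            payload = json.loads(path.read_text())
        except OSError as exc:
            raise SchemaError(f"cannot read annotation {path}: {exc}") from exc
        except json.JSONDecodeError as exc:
            raise SchemaError(
                f"annotation {path} is not valid JSON "
                f"(line {exc.lineno}, column {exc.colno}): {exc.msg}") from exc
        try:
            return cls.model_validate(payload)
        except ValidationError as exc:
            lines = "; ".join(
                f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                for err in exc.errors())
            raise SchemaError(f"annotation {path} failed validation: {lines}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2, exclude_none=True))


def target_detection(annotation: SessionAnnotation) -> float:
    """Percent of placed stones the subject exposed."""
    if annotation.total_targets < 1:
        raise ValueError("total_targets must be at least 1")
    return 100.0 * annotation.detected_count / annotation.total_targets


def duration_score(t_minutes: float, cfg: EfficiencyConfig | None = None) -> float:
    """Duration score in percent; strictly decreasing in T below Tmax."""
    cfg = cfg or EfficiencyConfig()
    if t_minutes <= 0:
        raise ValueError("session time must be positive")
    raw = 100.0 * (cfg.t_max - t_minutes) / cfg.t_max
    return max(0.0, raw) if cfg.clamp_negative else raw


def efficiency(td_percent: float, durations: "float | Sequence[float]") -> float:
    """Two-term mean of Target Detection and the mean Duration score."""
    dur = float(np.mean(np.atleast_1d(np.asarray(durations, dtype=float))))
    return (td_percent + dur) / 2.0
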