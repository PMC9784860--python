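"""Frame-level video input.

Sources are either a standard container (MP4/AVI/MKV, decoded through
imageio when a capable plugin is present) or a directory of sequentially
numbered 8-bit image frames (PNG/TIFF/JPEG), the format the synthetic
generator writes.  Every frame is converted to grayscale on ingest using
ITU-R BT.601 luma weights (0.299, 0.587, 0.114) and carries a timestamp of
``index / fps`` seconds from session start.

Frames are never resized: all downstream percentages are relative to the
native frame area, which makes the metrics resolution independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import EmptyStreamError, StreamReadError

_LUMA = np.array([0.299, 0.587, 0.114])
_FRAME_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")
_CONTAINER_EXTS = (".mp4", ".avi", ".mkv", ".mov")
META_FILENAME = "stream_meta.json"


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse an image to 8-bit grayscale.

    2-D input is returned as uint8 unchanged (idempotent); RGB(A) input is
    reduced with BT.601 luma weights and rounded half-up to the nearest
    integer.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        gray = arr[..., :3].astype(np.float64) @ _LUMA
        return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)
    raise StreamReadError(f"unsupported frame shape {arr.shape}")


@dataclass(frozen=True)
class FrameSample:
    """One grayscale frame with its position in the stream."""

    index: int
    timestamp: float  # seconds from session start
    pixels: np.ndarray  # uint8, shape (height, width)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be non-negative")
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")


@dataclass(frozen=True)
class FramePair:
    """Two frames separated by (approximately) the differencing interval."""

    current: FrameSample
    previous: FrameSample
    interval: float = 0.3

    def __post_init__(self) -> None:
        if self.current.pixels.shape != self.previous.pixels.shape:
            raise ValueError("paired frames must share dimensions")


@dataclass(frozen=True)
class StreamMeta:
    fps: float
    frame_count: int
    source: str

    @property
    def duration(self) -> float:
        return self.frame_count / self.fps


@dataclass
class FrameStream:
    """A re-iterable grayscale frame sequence with stream metadata."""

    meta: StreamMeta
    _frames: Sequence[np.ndarray] = field(repr=False)

    def __iter__(self) -> Iterator[FrameSample]:
        for i, px in enumerate(self._frames):
            yield FrameSample(index=i, timestamp=i / self.meta.fps, pixels=px)

    def __len__(self) -> int:
        return self.meta.frame_count

    def frame(self, index: int) -> FrameSample:
        return FrameSample(index=index, timestamp=index / self.meta.fps,
                           pixels=self._frames[index])


def from_arrays(frames: Iterable[np.ndarray], fps: float,
                source: str = "<memory>") -> FrameStream:
    """Wrap in-memory frame arrays (grayscale or RGB) as a FrameStream."""
    gray = [to_grayscale(f) for f in frames]
    if not gray:
        raise EmptyStreamError(f"{source}: zero frames")
    return FrameStream(StreamMeta(fps=fps, frame_count=len(gray), source=source), gray)


def _list_frame_files(directory: Path) -> list[Path]:
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in _FRAME_EXTS)
    return files


def open_stream(source: str | Path, kind: str | None = None,
                fps: float | None = None) -> FrameStream:
    """Open a video container or frame directory as grayscale frames.

    Parameters
    ----------
    source
        Path to a container file or a directory of zero-padded frame images.
    kind
        ``"container"`` or ``"frame_dir"``; inferred from the path when None.
    fps
        Frame rate for frame directories (containers carry their own).  When
        None, a ``stream_meta.json`` sidecar in the directory is consulted,
        falling back to 60 fps (the capture-device default).
    """
    path = Path(source)
    if not path.exists():
        raise StreamReadError(f"source does not exist: {path}")
    if kind is None:
        kind = "frame_dir" if path.is_dir() else "container"
    if kind == "frame_dir":
        return _open_frame_dir(path, fps)
    if kind == "container":
        return _open_container(path, fps)
    raise ValueError(f"unknown stream kind: {kind!r}")


def _open_frame_dir(path: Path, fps: float | None) -> FrameStream:
    if not path.is_dir():
        raise StreamReadError(f"not a directory: {path}")
    if fps is None:
        meta_file = path / META_FILENAME
        if meta_file.exists():
            fps = float(json.loads(meta_file.read_text())["fps"])
        else:
            fps = 60.0
    files = _list_frame_files(path)
    if not files:
        raise EmptyStreamError(f"no frame images in {path}")
    frames = []
    for f in files:
        try:
            frames.append(to_grayscale(iio.imread(f)))
        except (OSError, ValueError) as exc:
            raise StreamReadError(f"cannot decode frame {f}: {exc}") from exc
    shapes = {fr.shape for fr in frames}
    if len(shapes) > 1:
        raise StreamReadError(f"inconsistent frame dimensions in {path}: {shapes}")
    return FrameStream(StreamMeta(fps=fps, frame_count=len(frames),
                                  source=str(path)), frames)


def _open_container(path: Path, fps: float | None) -> FrameStream:
    try:
        meta = iio.immeta(path)
        frames = [to_grayscale(f) for f in iio.imiter(path)]
    except Exception as exc:  # plugin missing or codec unsupported
        raise StreamReadError(
            f"cannot decode container {path}: {exc}. "
            "Container decoding needs an ffmpeg-capable imageio plugin; "
            "alternatively extract the frames to a directory of PNGs."
        ) from exc
    if not frames:
        raise EmptyStreamError(f"container has zero frames: {path}")
    rate = fps or float(meta.get("fps", 0.0)) or 60.0
    return FrameStream(StreamMeta(fps=rate, frame_count=len(frames),
                                  source=str(path)), frames)


def write_frame_dir(stream: FrameStream | Iterable[np.ndarray],
                    directory: str | Path, fps: float | None = None) -> Path:
    """Write frames as zero-padded 8-bit PNGs plus a fps sidecar.

    Round-trips exactly: re-reading reproduces pixel values bit for bit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(stream, FrameStream):
        frames = [s.pixels for s in stream]
        fps = stream.meta.fps if fps is None else fps
    else:
        frames = [to_grayscale(f) for f in stream]
        if fps is None:
            raise ValueError("fps required when writing raw arrays")
    width = max(5, len(str(len(frames) - 1)))
    for i, px in enumerate(frames):
        iio.imwrite(directory / f"frame_{i:0{width}d}.png", px)
    (directory / META_FILENAME).write_text(
        json.dumps({"fps": fps, "frame_count": len(frames)}))
    return directory


def sample_pairs(stream: FrameStream, interval: float = 0.3) -> list[FramePair]:
    """Pair frames a fixed time interval apart, stepping disjointly.

    For each sampling time ``t = k * interval`` (k >= 1) up to the stream
    end, the frame nearest ``t`` is paired with the frame nearest
    ``t - interval`` (nearest-frame rounding bounds the timestamp error by
    half a native frame period).  A trailing partial interval is dropped; a
    stream shorter than one interval yields an empty list.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    meta = stream.meta
    n_pairs = int(math.floor(meta.duration / interval + 1e-9))
    pairs: list[FramePair] = []
    last = meta.frame_count - 1
    for k in range(1, n_pairs + 1):
        i_cur = min(last, int(round(k * interval * meta.fps)))
        i_prev = min(last, int(round((k - 1) * interval * meta.fps)))
        pairs.append(FramePair(current=stream.frame(i_cur),
                               previous=stream.frame(i_prev),
                               interval=interval))
    return pairs


def sample_frames(stream: FrameStream, interval: float = 0.3) -> list[FrameSample]:
    """Frames nearest ``t = k * interval`` for k = 0 .. floor(duration/interval)."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    meta = stream.meta
    n = int(math.floor(meta.duration / interval + 1e-9))
    last = meta.frame_count - 1
    return [stream.frame(min(last, int(round(k * interval * meta.fps))))
            for k in range(n + 1)]
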