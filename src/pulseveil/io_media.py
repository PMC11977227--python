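"""Lossless video and PPG input/output.

Lossy compression destroys exactly the sub-quantization color fluctuations
that carry the blood-volume pulse, and it also blunts the concealment filters
being studied, so persistence here is strictly lossless: a video is a
directory of numbered PNG frames plus a JSON sidecar recording the frame rate,
frame count and channel order. Reading back a written video is bit-identical.

Channel order is RGB everywhere inside the package. PNG is natively RGB, so
no conversion happens in this module; any future adapter for a BGR source
must convert at the boundary and say so.

Ground-truth photoplethysmogram (PPG) records are two-column CSV
(time_s, value) with a ``# rate_hz=<float>`` header line; a single-column
file is accepted when the rate is passed explicitly.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

from .errors import DimensionError, EmptyInputError, FormatError

#: A frame is a plain H×W×3 uint8 array in RGB order.
Frame = np.ndarray

SIDECAR_NAME = "video.json"
FRAME_PATTERN = "frame_{:06d}.png"


def _check_frame(pixels: np.ndarray) -> np.ndarray:
    a = np.asarray(pixels)
    if a.ndim != 3 or a.shape[2] != 3:
        raise DimensionError(f"frame must be H×W×3, got shape {a.shape}")
    if a.dtype != np.uint8:
        if np.issubdtype(a.dtype, np.integer) and a.min() >= 0 and a.max() <= 255:
            a = a.astype(np.uint8)
        else:
            raise DimensionError(f"frame dtype must be uint8, got {a.dtype}")
    return a


@dataclass
class VideoSequence:
    """An ordered stack of equally sized RGB frames at a fixed frame rate.

    ``frames`` is a (T, H, W, 3) uint8 array; ``frame_rate`` is in Hz.
    """

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[3] != 3:
            raise DimensionError(f"frames must be T×H×W×3, got {self.frames.shape}")
        if self.frames.shape[0] == 0:
            raise EmptyInputError("video has zero frames")
        if self.frames.dtype != np.uint8:
            if not (np.issubdtype(self.frames.dtype, np.integer)
                    and self.frames.min() >= 0 and self.frames.max() <= 255):
                raise DimensionError(f"frames dtype must be uint8, got {self.frames.dtype}")
            self.frames = self.frames.astype(np.uint8)
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, t: int) -> Frame:
        return self.frames[t]

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Length of the video in seconds."""
        return len(self) / self.frame_rate

    @classmethod
    def from_frames(cls, frames: list[np.ndarray], frame_rate: float) -> "VideoSequence":
        if not frames:
            raise EmptyInputError("no frames given")
        checked = [_check_frame(f) for f in frames]
        shapes = {f.shape for f in checked}
        if len(shapes) != 1:
            raise DimensionError(f"frames differ in shape: {sorted(shapes)}")
        return cls(np.stack(checked), frame_rate)


@dataclass
class PPGRecord:
    """A contact photoplethysmogram: samples at a fixed rate, arbitrary units."""

    samples: np.ndarray
    sample_rate: float
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise EmptyInputError("PPG record is empty")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise FormatError(f"non-finite PPG sample at index {bad}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_offset + np.arange(len(self)) / self.sample_rate


def write_video(video: VideoSequence, path: str | Path) -> Path:
    """Persist a video losslessly as a PNG frame directory with a JSON sidecar.

    Returns the directory path. ``read_video`` on the result is bit-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(video):
        iio.imwrite(path / FRAME_PATTERN.format(t), frame)
    sidecar = {
        "frame_rate": float(video.frame_rate),
        "n_frames": len(video),
        "channel_order": "RGB",
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def read_video(path: str | Path, frame_rate: float | None = None) -> VideoSequence:
    """Read a PNG frame directory (with or without sidecar) as a VideoSequence.

    Without a sidecar, ``frame_rate`` must be given and frames are taken in
    lexicographic order of the PNG file names. Pixel values are returned
    exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if not path.is_dir():
        raise FormatError(f"expected a frame directory, got a file: {path}")
    sidecar_path = path / SIDECAR_NAME
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        rate = float(meta["frame_rate"])
        if meta.get("channel_order", "RGB") != "RGB":
            raise FormatError(f"unsupported channel order {meta['channel_order']!r}")
    elif frame_rate is not None:
        rate = float(frame_rate)
    else:
        raise FormatError(f"no {SIDECAR_NAME} sidecar in {path} and no frame_rate given")
    files = sorted(path.glob("*.png"))
    if not files:
        raise EmptyInputError(f"no PNG frames in {path}")
    frames = []
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as exc:  # pragma: no cover - imageio error text varies
            raise FormatError(f"cannot decode {f}: {exc}") from exc
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        frames.append(img[..., :3])
    video = VideoSequence.from_frames(frames, rate)
    if sidecar_path.exists() and len(video) != int(meta["n_frames"]):
        raise FormatError(
            f"sidecar declares {meta['n_frames']} frames but {len(video)} PNGs found"
        )
    return video


_RATE_RE = re.compile(r"#\s*rate_hz\s*=\s*([0-9.eE+-]+)")


def write_ppg(ppg: PPGRecord, path: str | Path) -> Path:
    """Write a PPG record as two-column CSV with a ``# rate_hz=`` header."""
    path = Path(path)
    lines = [f"# rate_hz={float(ppg.sample_rate)!r}", "time_s,value"]
    for t, v in zip(ppg.times, ppg.samples):
        lines.append(f"{float(t)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_ppg(path: str | Path, sample_rate: float | None = None) -> PPGRecord:
    """Read a PPG CSV. The rate comes from the ``# rate_hz=`` header unless
    given explicitly; rows with non-numeric or non-finite values are rejected
    with the offending row number."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    rate = sample_rate
    values: list[float] = []
    first_content = True
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _RATE_RE.match(line)
            if m and rate is None:
                rate = float(m.group(1))
            continue
        fields = line.split(",")
        token = fields[-1].strip()
        try:
            v = float(token)
        except ValueError:
            if first_content:  # column-header line
                first_content = False
                continue
            raise FormatError(f"non-numeric value {token!r} at row {lineno} of {path}")
        first_content = False
        if not math.isfinite(v):
            raise FormatError(f"non-finite value at row {lineno} of {path}")
        values.append(v)
    if rate is None:
        raise FormatError(f"{path} has no '# rate_hz=' header and no sample_rate was given")
    if not values:
        raise EmptyInputError(f"no samples in {path}")
    return PPGRecord(np.array(values), rate)
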