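"""Frames on disk: the interchange convention between simulation and
analysis is a directory of 8-bit grayscale images whose filenames encode
the frame index and period label, e.g. ``frame_000123_night.png``.  A
sidecar schedule CSV, when present, is authoritative for timing."""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

__all__ = ["Frame", "frame_filename", "parse_frame_filename", "write_frame",
           "read_frame", "read_frame_dir"]

_FRAME_RE = re.compile(r"frame_(\d+)_(day|night)\.(png|tiff?|bmp|jpe?g)$", re.I)


@dataclass
class Frame:
    """One capture: grayscale image plus its index, timestamp and period."""

    image: np.ndarray
    index: int
    period: str
    timestamp: Optional[datetime] = None


def frame_filename(index: int, period: str, fmt: str = "PNG") -> str:
    ext = {"PNG": "png", "TIFF": "tiff", "BMP": "bmp", "JPG": "jpg"}[fmt.upper()]
    return f"frame_{index:06d}_{period}.{ext}"


def parse_frame_filename(name: str) -> tuple[int, str]:
    m = _FRAME_RE.search(Path(name).name)
    if m is None:
        raise ValueError(f"filename {name!r} does not encode a frame")
    return int(m.group(1)), m.group(2).lower()


def write_frame(frame: Frame, out_dir, fmt: str = "PNG") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / frame_filename(frame.index, frame.period, fmt)
    iio.imwrite(path, frame.image)
    return path


def read_frame(path) -> Frame:
    index, period = parse_frame_filename(str(path))
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse incidental RGB to gray
        img = np.round(img[..., :3].mean(axis=2)).astype(np.uint8)
    return Frame(image=img.astype(np.uint8), index=index, period=period)


def read_frame_dir(directory) -> list[Frame]:
    """Read every frame-named image in a directory, sorted by index."""
    directory = Path(directory)
    frames = []
    for p in sorted(directory.iterdir()):
        try:
            parse_frame_filename(p.name)
        except ValueError:
            continue
        frames.append(read_frame(p))
    frames.sort(key=lambda f: f.index)
    return frames
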