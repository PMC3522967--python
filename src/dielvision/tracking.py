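"""Adaptive region-of-interest (AROI) tracking of a single organ.

A growing, nutating organ quickly escapes a fixed analysis window.  The
AROI keeps a constant margin around the rectangle circumscribing the
segmented blob (RC): after each frame the ROI is recomputed as RC
expanded by MGX pixels left and right and MGY pixels top and bottom —
MGX/MGY being the maximum expected per-frame growth/displacement along
each axis — and clamped to the image.  As long as the true per-frame
change stays within those margins the organ never leaves the ROI.

Blob identity across frames is largest-area, with nearest-centroid
tie-breaking when candidate areas are within 10% of each other.  If the
ROI comes up empty (the organ slipped out, e.g. past a clamped edge) the
full frame is re-segmented once and the blob nearest the last known
centroid is adopted; a frame where that also fails is recorded as
missing, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import Frame
from .features import motion_vector
from .segmentation import Blob, PipelineConfig, segment_frame

__all__ = ["AROIState", "OrganTrack", "expand_rc", "init_roi", "update_aroi",
           "track_sequence"]

Rect = tuple[int, int, int, int]  # inclusive (x_min, y_min, x_max, y_max)


def _clamp(rect: Rect, bounds: tuple[int, int]) -> Rect:
    h, w = bounds
    x0, y0, x1, y1 = rect
    return (max(x0, 0), max(y0, 0), min(x1, w - 1), min(y1, h - 1))


def expand_rc(rc: Rect, mgx: int, mgy: int, bounds: tuple[int, int]) -> Rect:
    """Symmetric outward expansion of RC by the growth margins, clamped
    to the image."""
    x0, y0, x1, y1 = rc
    return _clamp((x0 - mgx, y0 - mgy, x1 + mgx, y1 + mgy), bounds)


@dataclass(frozen=True)
class AROIState:
    """Tracker state after one frame."""

    roi: Rect
    rc: Rect  # last blob's circumscribed rectangle
    mgx: int
    mgy: int
    bounds: tuple[int, int]  # image (H, W)
    centroid: tuple[float, float]
    blob: Optional[Blob] = None


@dataclass
class OrganTrack:
    """Per-frame feature series of one tracked organ.

    ``table`` has one row per frame with the measured shape features,
    the blob rectangle and the ROI used; frames where tracking failed
    have ``missing=True`` and NaN measurements.
    """

    table: pd.DataFrame

    COLUMNS = [
        "index", "period", "missing", "area", "perimeter", "length", "angle",
        "cx", "cy", "compactness",
        "rc_x0", "rc_y0", "rc_x1", "rc_y1",
        "roi_x0", "roi_y0", "roi_x1", "roi_y1",
    ]

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["cx", "cy"]].to_numpy()

    def motion_vector(self) -> np.ndarray:
        """Centroid displacement from the first valid frame (MV)."""
        pts = self.centroids.copy()
        valid = ~self.table["missing"].to_numpy()
        if not valid.any():
            raise ValueError("track has no valid frames")
        first = int(np.argmax(valid))
        pts[0] = pts[first] if first != 0 else pts[0]
        mv = motion_vector(pts)
        mv[~valid] = np.nan
        return mv

    def series(self, column: str) -> np.ndarray:
        return self.table[column].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OrganTrack":
        return cls(table=pd.read_csv(path))


def _select_blob(
    blobs: Sequence[Blob], prev_centroid: Optional[tuple[float, float]]
) -> Optional[Blob]:
    if not blobs:
        return None
    ordered = sorted(blobs, key=lambda b: -b.features.area)
    best = ordered[0]
    if prev_centroid is None or len(ordered) == 1:
        return best
    # nearest centroid among blobs within 10% of the largest area
    close = [b for b in ordered if b.features.area >= 0.9 * best.features.area]
    if len(close) == 1:
        return best
    px, py = prev_centroid
    return min(close, key=lambda b: (b.centroid[0] - px) ** 2 + (b.centroid[1] - py) ** 2)


def _image_of(frame: Union[Frame, np.ndarray]) -> np.ndarray:
    return frame.image if isinstance(frame, Frame) else np.asarray(frame)


def init_roi(
    frame: Union[Frame, np.ndarray],
    user_rect: Rect,
    config: PipelineConfig,
    mgx: int = 20,
    mgy: int = 20,
) -> AROIState:
    """Initialize tracking from a user-selected rectangle.

    The largest blob segmented inside the rectangle becomes the tracked
    organ; the initial ROI is its circumscribed rectangle expanded by
    (MGX, MGY).
    """
    if mgx < 0 or mgy < 0:
        raise ValueError("margins must be >= 0")
    img = _image_of(frame)
    bounds = img.shape
    x0, y0, x1, y1 = user_rect
    if not (0 <= x0 <= x1 < bounds[1] and 0 <= y0 <= y1 < bounds[0]):
        raise ValueError(f"user rectangle {user_rect} outside image {bounds}")
    blobs = segment_frame(img, config, roi=user_rect)
    blob = _select_blob(blobs, None)
    if blob is None:
        raise ValueError("no blob found inside the initial ROI")
    roi = expand_rc(blob.bbox, mgx, mgy, bounds)
    return AROIState(roi=roi, rc=blob.bbox, mgx=mgx, mgy=mgy, bounds=bounds,
                     centroid=blob.centroid, blob=blob)


def update_aroi(
    state: AROIState,
    frame: Union[Frame, np.ndarray],
    config: PipelineConfig,
) -> AROIState:
    """Advance the tracker by one frame.

    Segmentation is restricted to the current ROI; on an empty ROI the
    full frame is re-segmented once (recovery) before failing.
    """
    img = _image_of(frame)
    blobs = segment_frame(img, config, roi=state.roi)
    blob = _select_blob(blobs, state.centroid)
    if blob is None:  # recovery: organ may have left a clamped ROI
        blobs = segment_frame(img, config)
        blob = _select_blob(blobs, state.centroid)
    if blob is None:
        raise ValueError("organ lost: no blob in ROI nor in full frame")
    roi = expand_rc(blob.bbox, state.mgx, state.mgy, state.bounds)
    return replace(state, roi=roi, rc=blob.bbox, centroid=blob.centroid, blob=blob)


def track_sequence(
    frames: Sequence[Union[Frame, np.ndarray]],
    initial_roi: Rect,
    config: PipelineConfig,
    mgx: int = 20,
    mgy: int = 20,
) -> OrganTrack:
    """Track one organ through a whole sequence.

    Frames where both the ROI and the recovery pass found no blob are
    flagged missing and the state is carried over unchanged.
    """
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    rows = []
    state = init_roi(frames[0], initial_roi, config, mgx=mgx, mgy=mgy)
    for i, frame in enumerate(frames):
        period = frame.period if isinstance(frame, Frame) else ""
        index = frame.index if isinstance(frame, Frame) else i
        if i > 0:
            try:
                state = update_aroi(state, frame, config)
            except ValueError:
                rows.append(dict(index=index, period=period, missing=True,
                                 area=np.nan, perimeter=np.nan, length=np.nan,
                                 angle=np.nan, cx=np.nan, cy=np.nan,
                                 compactness=np.nan,
                                 rc_x0=np.nan, rc_y0=np.nan, rc_x1=np.nan,
                                 rc_y1=np.nan,
                                 roi_x0=state.roi[0], roi_y0=state.roi[1],
                                 roi_x1=state.roi[2], roi_y1=state.roi[3]))
                continue
        f = state.blob.features
        rows.append(dict(index=index, period=period, missing=False,
                         area=f.area, perimeter=f.perimeter, length=f.length,
                         angle=f.angle, cx=f.centroid[0], cy=f.centroid[1],
                         compactness=f.compactness,
                         rc_x0=state.rc[0], rc_y0=state.rc[1],
                         rc_x1=state.rc[2], rc_y1=state.rc[3],
                         roi_x0=state.roi[0], roi_y0=state.roi[1],
                         roi_x1=state.roi[2], roi_y1=state.roi[3]))
    return OrganTrack(table=pd.DataFrame(rows, columns=OrganTrack.COLUMNS))
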