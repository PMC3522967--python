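"""Metric calibration from a circle-grid target.

The target is a 10 x 10 grid of circles of 5 mm radius at 10 mm
center-to-center pitch, photographed at each of a set of planes at known
distances from the camera.  Per plane, circle centers are detected and a
pixel-to-millimetre scale fitted from the known pitch; at analysis time
the scale for an arbitrary sample distance is obtained by linear
interpolation between the two bracketing calibrated planes (no
extrapolation).  Only a scale (per axis, since CCIR video pixels need
not be square) is stored — no distortion model.

Center detection reuses the segmentation chain: Otsu thresholding with
automatic polarity, connected components, filtering by area consistency
and near-circular compactness, centers as intensity-weighted centroids.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import segmentation as seg
from .features import compactness

__all__ = [
    "CalibrationTarget",
    "PlaneCalibration",
    "CalibrationModel",
    "render_grid",
    "detect_grid_circles",
    "fit_plane_scale",
    "scale_at_distance",
]


@dataclass(frozen=True)
class CalibrationTarget:
    """Geometry of the printed circle-grid target.

    The default emulates a 10 x 10 grid of 5 mm-radius circles with a
    10 mm separation between circle edges, i.e. a 20 mm center-to-center
    pitch (a 10 mm center pitch would make 5 mm-radius circles touch,
    which no printable target does and blob detection could not
    resolve).
    """

    rows: int = 10
    cols: int = 10
    circle_radius_mm: float = 5.0
    pitch_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid needs at least 2 rows and 2 columns")
        if self.pitch_mm <= 2 * self.circle_radius_mm:
            raise ValueError("pitch must exceed the circle diameter (no overlap)")


@dataclass(frozen=True)
class PlaneCalibration:
    """Fitted scale for one calibration plane."""

    plane_distance_mm: float
    scale_x: float  # mm per pixel
    scale_y: float
    residual: float  # RMS grid-fit error, mm

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("scales must be positive")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


@dataclass
class CalibrationModel:
    """Ordered per-plane calibrations; queries interpolate linearly."""

    planes: list[PlaneCalibration] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = [p.plane_distance_mm for p in self.planes]
        if len(set(d)) != len(d):
            raise ValueError("duplicate plane distances")
        self.planes = sorted(self.planes, key=lambda p: p.plane_distance_mm)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([p.__dict__ for p in self.planes], fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls(planes=[PlaneCalibration(**d) for d in json.load(fh)])


def render_grid(
    target: CalibrationTarget,
    scale_mm_per_px: float,
    margin_px: int = 20,
    dark_on_light: bool = True,
    bg_level: int = 220,
    fg_level: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the target at a given scale.

    Returns the 8-bit image and the true centers, an (rows*cols, 2)
    array of (x, y) pixel coordinates in row-major grid order.
    """
    if scale_mm_per_px <= 0:
        raise ValueError("scale must be positive")
    pitch_px = target.pitch_mm / scale_mm_per_px
    r_px = target.circle_radius_mm / scale_mm_per_px
    w = int(math.ceil((target.cols - 1) * pitch_px + 2 * r_px)) + 2 * margin_px
    h = int(math.ceil((target.rows - 1) * pitch_px + 2 * r_px)) + 2 * margin_px
    x0 = margin_px + r_px
    y0 = margin_px + r_px
    centers = np.array(
        [
            (x0 + c * pitch_px, y0 + r * pitch_px)
            for r in range(target.rows)
            for c in range(target.cols)
        ]
    )
    img = np.full((h, w), bg_level if dark_on_light else fg_level, dtype=float)
    circle_val = fg_level if dark_on_light else bg_level
    for cx, cy in centers:  # rasterize within each circle's bounding box
        x0, x1 = int(cx - r_px) - 1, int(cx + r_px) + 2
        y0, y1 = int(cy - r_px) - 1, int(cy + r_px) + 2
        yy, xx = np.mgrid[max(y0, 0) : min(y1, h), max(x0, 0) : min(x1, w)]
        sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
        img[max(y0, 0) : min(y1, h), max(x0, 0) : min(x1, w)][sel] = circle_val
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0, noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), centers


def _order_row_major(centers: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Sort centers into row-major grid order by clustering y then x."""
    order = np.argsort(centers[:, 1], kind="stable")
    out = []
    for r in range(rows):
        row = centers[order[r * cols : (r + 1) * cols]]
        out.append(row[np.argsort(row[:, 0], kind="stable")])
    return np.vstack(out)


def detect_grid_circles(
    image: np.ndarray,
    target: CalibrationTarget = CalibrationTarget(),
) -> np.ndarray:
    """Detect the grid's circle centers, ordered row-major.

    Polarity is chosen automatically: circles cover a minority of the
    frame, so the Otsu class with the smaller pixel count is taken as
    foreground.  Candidate blobs are kept when their compactness is
    near-circular (< 1.3) and their area within a factor 2 of the
    median candidate; centers are intensity-weighted centroids of the
    polarity-corrected image.
    """
    img = np.asarray(image)
    level = seg.threshold_otsu(img)
    bright = img > level
    invert = bright.mean() > 0.5  # circles are the minority class
    work = (255 - img.astype(int)).astype(np.uint8) if invert else img
    mask = work > seg.threshold_otsu(work)
    blobs = seg.extract_blobs(mask)
    if not blobs:
        raise ValueError("no circles detected (0 candidate blobs)")
    round_blobs = [b for b in blobs if b.features.compactness < 1.3]
    if round_blobs:
        areas = np.array([b.features.area for b in round_blobs])
        med = np.median(areas)
        round_blobs = [
            b for b in round_blobs if med / 2 <= b.features.area <= med * 2
        ]
    expected = target.rows * target.cols
    if len(round_blobs) != expected:
        raise ValueError(
            f"detected {len(round_blobs)} circles, expected {expected} "
            f"({len(blobs)} candidate blobs before filtering)"
        )
    centers = []
    base = work.astype(float)
    floor = float(np.percentile(base[~mask], 50)) if (~mask).any() else 0.0
    for b in round_blobs:
        ys, xs = np.nonzero(b.mask)
        ys, xs = ys + b.bbox[1], xs + b.bbox[0]
        wgt = np.maximum(base[ys, xs] - floor, 1e-9)
        centers.append((np.average(xs, weights=wgt), np.average(ys, weights=wgt)))
    return _order_row_major(np.array(centers), target.rows, target.cols)


def fit_plane_scale(
    centers: np.ndarray,
    target: CalibrationTarget,
    plane_distance_mm: float = 0.0,
) -> PlaneCalibration:
    """Fit the mm-per-pixel scale of one plane from detected centers.

    ``scale_x`` is the pitch divided by the mean horizontal neighbour
    spacing within rows, ``scale_y`` the analogue down columns.  The
    residual is the RMS deviation of the centers from the ideal grid
    after a least-squares similarity fit, reported in mm.
    """
    centers = np.asarray(centers, dtype=float)
    expected = target.rows * target.cols
    if centers.shape != (expected, 2):
        raise ValueError(f"need {expected} centers in row-major order")
    sv = np.linalg.svd(centers - centers.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-6 * sv[0]:
        raise ValueError("degenerate (collinear) centers")
    grid = centers.reshape(target.rows, target.cols, 2)
    dx = np.diff(grid[:, :, 0], axis=1).mean()
    dy = np.diff(grid[:, :, 1], axis=0).mean()
    if dx <= 0 or dy <= 0:
        raise ValueError("degenerate center layout (non-increasing spacing)")
    scale_x = target.pitch_mm / dx
    scale_y = target.pitch_mm / dy

    # similarity fit (complex least squares z_px ~ alpha * z_mm + beta)
    ideal = np.array(
        [
            (c * target.pitch_mm, r * target.pitch_mm)
            for r in range(target.rows)
            for c in range(target.cols)
        ]
    )
    z_mm = ideal[:, 0] + 1j * ideal[:, 1]
    z_px = centers[:, 0] + 1j * centers[:, 1]
    A = np.column_stack([z_mm, np.ones_like(z_mm)])
    coef, *_ = np.linalg.lstsq(A, z_px, rcond=None)
    alpha = coef[0]
    if abs(alpha) < 1e-12:
        raise ValueError("degenerate (collinear) centers")
    resid_px = np.abs(z_px - A @ coef)
    residual_mm = float(np.sqrt(np.mean(resid_px**2)) / abs(alpha))
    return PlaneCalibration(
        plane_distance_mm=plane_distance_mm,
        scale_x=scale_x,
        scale_y=scale_y,
        residual=residual_mm,
    )


def scale_at_distance(
    model: CalibrationModel, distance_mm: float
) -> tuple[float, float]:
    """Interpolate (scale_x, scale_y) at a sample distance.

    The distance must lie within the calibrated plane range; querying an
    exact plane distance returns that plane's scales.
    """
    if not model.planes:
        raise ValueError("empty calibration model")
    d = [p.plane_distance_mm for p in model.planes]
    if not (d[0] <= distance_mm <= d[-1]):
        raise ValueError(
            f"distance {distance_mm} mm outside calibrated range [{d[0]}, {d[-1]}]"
        )
    sx = float(np.interp(distance_mm, d, [p.scale_x for p in model.planes]))
    sy = float(np.interp(distance_mm, d, [p.scale_y for p in model.planes]))
    return sx, sy
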