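"""Configurable segmentation chain: preprocessing -> histogram
thresholding -> blob detection -> blob filtering.

The chain mirrors a classical grayscale pipeline for high-contrast
chamber imagery: up to four smoothing/morphology operations, an optional
edge detector (never used as the mask — segmentation always proceeds by
thresholding), one of three global histogram thresholds (Otsu's
between-class variance, Kapur's maximum entropy, Kittler-Illingworth's
minimum error), 8-connected component extraction and interval filters on
area, compactness, length and perimeter.

All three threshold criteria are evaluated over every candidate split
level 0..254 of the 256-bin histogram; foreground is ``pixel > level``.
Ties are broken toward the lowest optimal level so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage.measure import label as sklabel

from .features import ShapeFeatures, compute_shape

__all__ = [
    "PipelineConfig",
    "PreprocessingOp",
    "Blob",
    "apply_preprocessing",
    "threshold_otsu",
    "threshold_kapur",
    "threshold_kittler",
    "compute_threshold",
    "binarize",
    "extract_blobs",
    "filter_blobs",
    "segment_frame",
]

_FILTER_OPS = {"average", "median", "laplacian", "sharpen", "custom_mask"}
_MORPH_OPS = {"dilation", "erosion", "opening", "closing"}
_EDGE_OPS = {"roberts", "sobel"}
_THRESHOLD_METHODS = {"otsu", "kapur", "kittler", "fixed"}


@dataclass(frozen=True)
class PreprocessingOp:
    """One preprocessing step: a filter or a grayscale morphology op."""

    name: str
    kernel_size: int = 3
    iterations: int = 1
    mask: Optional[tuple] = None  # custom_mask coefficients, row-major

    def __post_init__(self) -> None:
        if self.name not in _FILTER_OPS | _MORPH_OPS:
            raise ValueError(f"unknown preprocessing op {self.name!r}")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.name == "custom_mask":
            if self.mask is None:
                raise ValueError("custom_mask requires mask coefficients")
            m = np.asarray(self.mask, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] not in (3, 5, 7):
                raise ValueError("custom mask must be 3x3, 5x5 or 7x7")


@dataclass
class BlobFilters:
    """Interval bounds on blob descriptors; None means unbounded."""

    min_area: Optional[float] = None
    max_area: Optional[float] = None
    min_compactness: Optional[float] = None
    max_compactness: Optional[float] = None
    min_length: Optional[float] = None
    max_length: Optional[float] = None
    min_perimeter: Optional[float] = None
    max_perimeter: Optional[float] = None

    def __post_init__(self) -> None:
        for attr in ("area", "compactness", "length", "perimeter"):
            lo = getattr(self, f"min_{attr}")
            hi = getattr(self, f"max_{attr}")
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"min_{attr} > max_{attr}")


@dataclass
class PipelineConfig:
    """Full segmentation configuration.

    At most four preprocessing operations may be configured (the chain's
    stated limit); the edge detector is optional extra preprocessing and
    never replaces thresholding.  ``invert`` flips foreground polarity
    for dark-object-on-light-background imagery.
    """

    preprocessing: list[PreprocessingOp] = field(default_factory=list)
    edge_detector: Optional[str] = None
    threshold_method: str = "otsu"
    fixed_level: Optional[int] = None
    blob_filters: BlobFilters = field(default_factory=BlobFilters)
    invert: bool = False

    def __post_init__(self) -> None:
        if len(self.preprocessing) > 4:
            raise ValueError("at most 4 preprocessing operations allowed")
        if self.edge_detector is not None and self.edge_detector not in _EDGE_OPS:
            raise ValueError(f"edge_detector must be one of {sorted(_EDGE_OPS)}")
        if self.threshold_method not in _THRESHOLD_METHODS:
            raise ValueError(
                f"threshold_method must be one of {sorted(_THRESHOLD_METHODS)}"
            )
        if self.threshold_method == "fixed" and self.fixed_level is None:
            raise ValueError("fixed thresholding requires fixed_level")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ops = [
            op if isinstance(op, PreprocessingOp) else PreprocessingOp(**op)
            for op in d.get("preprocessing", [])
        ]
        d["preprocessing"] = ops
        bf = d.get("blob_filters", {})
        if not isinstance(bf, BlobFilters):
            bf = BlobFilters(**bf)
        d["blob_filters"] = bf
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class Blob:
    """A connected foreground component with its measured descriptors.

    The bounding rectangle is inclusive: (x_min, y_min, x_max, y_max) in
    pixel coordinates with origin at the top-left pixel center.  ``mask``
    is cropped to the bounding rectangle; add (x_min, y_min) to recover
    frame coordinates (features already report them globally).
    """

    label: int
    mask: np.ndarray  # boolean mask cropped to bbox
    features: ShapeFeatures
    bbox: tuple[int, int, int, int]

    @property
    def area(self) -> float:
        return self.features.area

    @property
    def centroid(self) -> tuple[float, float]:
        return self.features.centroid


def _check_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return img


def apply_preprocessing(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Apply the configured preprocessing chain; output stays 8-bit."""
    img = _check_gray(image).astype(float)
    for op in config.preprocessing:
        k = op.kernel_size
        for _ in range(op.iterations):
            if op.name == "average":
                img = ndi.uniform_filter(img, size=k, mode="nearest")
            elif op.name == "median":
                img = ndi.median_filter(img, size=k, mode="nearest")
            elif op.name == "laplacian":
                img = ndi.laplace(img, mode="nearest")
            elif op.name == "sharpen":
                img = img - ndi.laplace(img, mode="nearest")
            elif op.name == "custom_mask":
                img = ndi.convolve(
                    img, np.asarray(op.mask, dtype=float), mode="nearest"
                )
            elif op.name == "dilation":
                img = ndi.grey_dilation(img, size=(k, k), mode="nearest")
            elif op.name == "erosion":
                img = ndi.grey_erosion(img, size=(k, k), mode="nearest")
            elif op.name == "opening":
                img = ndi.grey_opening(img, size=(k, k), mode="nearest")
            elif op.name == "closing":
                img = ndi.grey_closing(img, size=(k, k), mode="nearest")
    if config.edge_detector == "roberts":
        img = skfilters.roberts(img / 255.0) * 255.0
    elif config.edge_detector == "sobel":
        img = skfilters.sobel(img / 255.0) * 255.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _lowest_argbest(crit: np.ndarray, maximize: bool) -> int:
    """Lowest level attaining the optimum, with a relative tolerance so
    float noise between algebraically tied levels cannot break the
    lowest-level tie rule."""
    finite = crit[np.isfinite(crit)]
    best = finite.max() if maximize else finite.min()
    tol = 1e-9 * max(1.0, abs(best))
    ok = crit >= best - tol if maximize else crit <= best + tol
    ok &= np.isfinite(crit)
    return int(np.argmax(ok))


def _histogram(image: np.ndarray) -> np.ndarray:
    img = _check_gray(image)
    hist = np.bincount(img.astype(np.uint8).ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("image has fewer than 2 distinct gray levels")
    return hist


def threshold_otsu(image: np.ndarray) -> int:
    """Otsu's threshold: level maximizing between-class variance.

    Foreground is ``pixel > level``; the lowest level attaining the
    maximum is returned.
    """
    hist = _histogram(image)
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1]  # weight of class {<= t}, t = 0..254
    w1 = total - w0
    csum = np.cumsum(hist * np.arange(256))[:-1]
    mu_total = (hist * np.arange(256)).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (mu_total - csum) / w1
        crit = w0 * w1 * (mu0 - mu1) ** 2
    crit = np.where((w0 > 0) & (w1 > 0), crit, -np.inf)
    return _lowest_argbest(crit, maximize=True)


def threshold_kapur(image: np.ndarray) -> int:
    """Kapur's maximum-entropy threshold.

    Maximizes the sum of the Shannon entropies of the two classes'
    normalized gray-level distributions.
    """
    hist = _histogram(image)
    p = hist / hist.sum()
    P0 = np.cumsum(p)[:-1]
    P1 = 1.0 - P0
    plogp = np.zeros_like(p)
    nz = p > 0
    plogp[nz] = p[nz] * np.log(p[nz])
    S0 = np.cumsum(plogp)[:-1]
    S1 = plogp.sum() - S0
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(P0) - S0 / P0
        h1 = np.log(P1) - S1 / P1
        crit = h0 + h1
    crit = np.where((P0 > 0) & (P1 > 0), crit, -np.inf)
    return _lowest_argbest(crit, maximize=True)


def threshold_kittler(image: np.ndarray) -> int:
    """Kittler-Illingworth minimum-error threshold.

    Models each class as Gaussian and minimizes
    ``J(t) = 1 + 2(w0 ln s0 + w1 ln s1) - 2(w0 ln w0 + w1 ln w1)``;
    candidate levels leaving a class empty or with zero variance are
    skipped.
    """
    hist = _histogram(image)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    m0c = np.cumsum(p * levels)[:-1]
    m1c = (p * levels).sum() - m0c
    v0c = np.cumsum(p * levels**2)[:-1]
    v1c = (p * levels**2).sum() - v0c
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0c / w0
        mu1 = m1c / w1
        # 1/12 floor: the quantization variance of a single gray level,
        # which keeps the criterion defined for delta-like classes
        var0 = np.maximum(v0c / w0 - mu0**2, 1.0 / 12.0)
        var1 = np.maximum(v1c / w1 - mu1**2, 1.0 / 12.0)
        crit = (
            1.0
            + w0 * np.log(var0)
            + w1 * np.log(var1)
            - 2.0 * (w0 * np.log(w0) + w1 * np.log(w1))
        )
    valid = (w0 > 0) & (w1 > 0)
    crit = np.where(valid, crit, np.inf)
    return _lowest_argbest(crit, maximize=False)


def compute_threshold(image: np.ndarray, config: PipelineConfig) -> int:
    if config.threshold_method == "otsu":
        return threshold_otsu(image)
    if config.threshold_method == "kapur":
        return threshold_kapur(image)
    if config.threshold_method == "kittler":
        return threshold_kittler(image)
    return int(config.fixed_level)


def binarize(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Threshold an image to a foreground mask, honouring polarity."""
    img = _check_gray(image)
    work = 255 - img.astype(np.uint8) if config.invert else img
    level = compute_threshold(work, config)
    return work > level


def extract_blobs(
    binary: np.ndarray,
    roi: Optional[tuple[int, int, int, int]] = None,
    scale: Optional[float] = None,
) -> list[Blob]:
    """8-connected components of a binary image, restricted to a ROI.

    ``roi`` is inclusive (x_min, y_min, x_max, y_max).  Labels are
    assigned in raster order of each component's first pixel; features
    are computed on full-frame masks so coordinates stay global.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 2:
        raise ValueError("expected a 2-D binary image")
    work = binary
    if roi is not None:
        x0, y0, x1, y1 = roi
        h, w = binary.shape
        if not (0 <= x0 <= x1 < w and 0 <= y0 <= y1 < h):
            raise ValueError(f"roi {roi} outside image bounds {(w, h)}")
        work = np.zeros_like(binary)
        work[y0 : y1 + 1, x0 : x1 + 1] = binary[y0 : y1 + 1, x0 : x1 + 1]
    labels, n = sklabel(work, connectivity=2, return_num=True)
    slices = ndi.find_objects(labels)
    blobs: list[Blob] = []
    for lab in range(1, n + 1):  # sklabel numbers components in raster order
        sl = slices[lab - 1]
        crop = labels[sl] == lab
        y0, x0 = sl[0].start, sl[1].start
        f = compute_shape(crop, scale=scale)
        s = 1.0 if scale is None else float(scale)
        feats = ShapeFeatures(
            area=f.area, perimeter=f.perimeter, length=f.length, angle=f.angle,
            centroid=(f.centroid[0] + x0 * s, f.centroid[1] + y0 * s),
            compactness=f.compactness, angle_degenerate=f.angle_degenerate,
            unit=f.unit,
        )
        bbox = (x0, y0, sl[1].stop - 1, sl[0].stop - 1)
        blobs.append(Blob(label=lab, mask=crop, features=feats, bbox=bbox))
    return blobs


def filter_blobs(blobs: Sequence[Blob], bounds: BlobFilters) -> list[Blob]:
    """Keep blobs satisfying every configured interval bound, in order."""

    def ok(b: Blob) -> bool:
        f = b.features
        for attr, val in (
            ("area", f.area),
            ("compactness", f.compactness),
            ("length", f.length),
            ("perimeter", f.perimeter),
        ):
            lo = getattr(bounds, f"min_{attr}")
            hi = getattr(bounds, f"max_{attr}")
            if lo is not None and val < lo:
                return False
            if hi is not None and val > hi:
                return False
        return True

    return [b for b in blobs if ok(b)]


def segment_frame(
    image: np.ndarray,
    config: PipelineConfig,
    roi: Optional[tuple[int, int, int, int]] = None,
    scale: Optional[float] = None,
) -> list[Blob]:
    """Run the full chain on one frame: preprocess, threshold, extract
    and filter blobs."""
    pre = apply_preprocessing(image, config)
    fg = binarize(pre, config)
    blobs = extract_blobs(fg, roi=roi, scale=scale)
    return filter_blobs(blobs, config.blob_filters)
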