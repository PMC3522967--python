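"""Segmentation chain: preprocessing, the three histogram thresholds
against brute-force criterion scans, blob extraction and filtering."""

import math

import numpy as np
import pytest
import skimage.filters
from hypothesis import given, settings
from hypothesis import strategies as st

from dielvision.segmentation import (BlobFilters, PipelineConfig,
                                     PreprocessingOp, apply_preprocessing,
                                     binarize, extract_blobs, filter_blobs,
                                     threshold_kapur, threshold_kittler,
                                     threshold_otsu)

# ---------------------------------------------------------------------------
# brute-force oracles: per-level recomputation straight from the definitions


def pick_level(crits, maximize):
    """Lowest level within relative tolerance of the optimum — the same
    deterministic tie rule the package defines for all three methods."""
    valid = [(t, c) for t, c in crits if c is not None and math.isfinite(c)]
    best = max(c for _, c in valid) if maximize else min(c for _, c in valid)
    tol = 1e-9 * max(1.0, abs(best))
    for t, c in valid:
        if (c >= best - tol) if maximize else (c <= best + tol):
            return t
    raise AssertionError("unreachable")


def otsu_scan(hist):
    total = hist.sum()
    crits = []
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            crits.append((t, None))
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        crits.append((t, w0 * w1 * (mu0 - mu1) ** 2))
    return pick_level(crits, maximize=True)


def kapur_scan(hist):
    p = hist / hist.sum()
    crits = []
    for t in range(255):
        p0, p1 = p[: t + 1].sum(), p[t + 1 :].sum()
        if p0 <= 0 or p1 <= 0:
            crits.append((t, None))
            continue
        h0 = -sum(q / p0 * math.log(q / p0) for q in p[: t + 1] if q > 0)
        h1 = -sum(q / p1 * math.log(q / p1) for q in p[t + 1 :] if q > 0)
        crits.append((t, h0 + h1))
    return pick_level(crits, maximize=True)


def kittler_scan(hist):
    p = hist / hist.sum()
    lv = np.arange(256.0)
    crits = []
    for t in range(255):
        w0, w1 = p[: t + 1].sum(), p[t + 1 :].sum()
        if w0 <= 0 or w1 <= 0:
            crits.append((t, None))
            continue
        mu0 = (p[: t + 1] * lv[: t + 1]).sum() / w0
        mu1 = (p[t + 1 :] * lv[t + 1 :]).sum() / w1
        # same 1/12 quantization-variance floor as the implementation:
        # a delta-distributed class has the variance of one gray bin
        v0 = max((p[: t + 1] * lv[: t + 1] ** 2).sum() / w0 - mu0**2, 1 / 12)
        v1 = max((p[t + 1 :] * lv[t + 1 :] ** 2).sum() / w1 - mu1**2, 1 / 12)
        crits.append((t, 1 + w0 * math.log(v0) + w1 * math.log(v1)
                      - 2 * (w0 * math.log(w0) + w1 * math.log(w1))))
    return pick_level(crits, maximize=False)


def image_from_hist(hist):
    vals = np.repeat(np.arange(256), hist).astype(np.uint8)
    return vals.reshape(1, -1)


def random_histograms(n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        hist = np.zeros(256, dtype=int)
        k = rng.integers(2, 20)
        bins = rng.choice(256, size=k, replace=False)
        hist[bins] = rng.integers(1, 50, size=k)
        out.append(hist)
    return out


# ---------------------------------------------------------------------------


class TestThresholds:
    def test_two_level_image_separated_by_all_methods(self):
        img = np.array([[50] * 20 + [200] * 12], dtype=np.uint8)
        for fn in (threshold_otsu, threshold_kapur, threshold_kittler):
            level = fn(img)
            assert 50 <= level <= 199
            assert np.array_equal(img > level, img == 200)

    @pytest.mark.parametrize(
        "fn,scan",
        [(threshold_otsu, otsu_scan), (threshold_kapur, kapur_scan),
         (threshold_kittler, kittler_scan)],
        ids=["otsu", "kapur", "kittler"],
    )
    def test_matches_exhaustive_criterion_scan(self, fn, scan):
        """Each method equals a per-level brute-force scan of its criterion
        on 100 random sparse histograms."""
        for hist in random_histograms(100, seed=42):
            img = image_from_hist(hist)
            assert fn(img) == scan(hist.astype(float)), hist.nonzero()

    def test_otsu_agrees_with_skimage(self, rng):
        img = np.clip(
            np.concatenate([rng.normal(70, 12, 4000), rng.normal(190, 9, 2000)]),
            0, 255).astype(np.uint8).reshape(60, 100)
        assert threshold_otsu(img) == int(skimage.filters.threshold_otsu(img))

    def test_kittler_recovers_gaussian_mixture_boundary(self, rng):
        # equal-weight, equal-variance mixture: minimum-error boundary is
        # the midpoint of the means
        mu0, mu1, sd = 80, 170, 15
        samples = np.concatenate([rng.normal(mu0, sd, 60000),
                                  rng.normal(mu1, sd, 60000)])
        img = np.clip(samples, 0, 255).astype(np.uint8).reshape(300, 400)
        assert abs(threshold_kittler(img) - (mu0 + mu1) / 2) <= 2

    def test_constant_image_rejected(self):
        img = np.full((10, 10), 77, np.uint8)
        for fn in (threshold_otsu, threshold_kapur, threshold_kittler):
            with pytest.raises(ValueError):
                fn(img)


class TestPreprocessing:
    def test_empty_chain_is_identity(self, rng):
        img = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        assert np.array_equal(apply_preprocessing(img, PipelineConfig()), img)

    def test_opening_removes_isolated_pixel(self):
        img = np.zeros((15, 15), np.uint8)
        img[7, 7] = 255
        cfg = PipelineConfig(preprocessing=[PreprocessingOp("erosion"),
                                            PreprocessingOp("dilation")])
        assert apply_preprocessing(img, cfg).max() == 0

    def test_median_replaces_salt_noise(self, rng):
        img = np.full((20, 20), 100, np.uint8)
        salt = [(3, 4), (10, 15), (17, 2)]
        for y, x in salt:
            img[y, x] = 255
        out = apply_preprocessing(
            img, PipelineConfig(preprocessing=[PreprocessingOp("median")]))
        # brute-force per-pixel 3x3 median with edge replication
        pad = np.pad(img, 1, mode="edge")
        for y, x in salt:
            expected = np.median(pad[y : y + 3, x : x + 3])
            assert out[y, x] == expected == 100

    def test_more_than_four_ops_rejected(self):
        ops = [PreprocessingOp("median")] * 5
        with pytest.raises(ValueError, match="4"):
            PipelineConfig(preprocessing=ops)

    def test_even_mask_rejected(self):
        with pytest.raises(ValueError):
            PreprocessingOp("average", kernel_size=4)
        with pytest.raises(ValueError):
            PreprocessingOp("custom_mask", mask=((1, 2), (3, 4)))


class TestExtractBlobs:
    def test_empty_image_gives_no_blobs(self):
        assert extract_blobs(np.zeros((10, 10), bool)) == []

    def test_two_disjoint_squares(self):
        img = np.zeros((20, 20), bool)
        img[2:5, 2:5] = True
        img[10:13, 10:13] = True
        blobs = extract_blobs(img)
        assert [b.area for b in blobs] == [9, 9]
        assert blobs[0].bbox == (2, 2, 4, 4)

    def test_diagonal_chain_is_one_blob_under_8_connectivity(self):
        img = np.eye(8, dtype=bool)
        assert len(extract_blobs(img)) == 1

    def test_blob_areas_partition_foreground(self, rng):
        img = rng.random((40, 40)) > 0.7
        blobs = extract_blobs(img)
        assert sum(b.area for b in blobs) == img.sum()

    def test_roi_restriction(self):
        img = np.zeros((20, 20), bool)
        img[2:5, 2:5] = True
        img[10:13, 10:13] = True
        blobs = extract_blobs(img, roi=(0, 0, 7, 7))
        assert len(blobs) == 1 and blobs[0].bbox == (2, 2, 4, 4)

    def test_roi_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            extract_blobs(np.zeros((10, 10), bool), roi=(0, 0, 10, 5))


class TestFilterBlobs:
    @staticmethod
    def _blobs():
        img = np.zeros((60, 120), bool)
        img[5:8, 5:8] = True            # 9 px square
        img[20:30, 20:30] = True        # 100 px square
        img[40:44, 10:110] = True       # elongated bar
        return extract_blobs(img)

    def test_no_bounds_is_identity(self):
        blobs = self._blobs()
        assert filter_blobs(blobs, BlobFilters()) == blobs

    def test_area_interval(self):
        blobs = self._blobs()
        kept = filter_blobs(blobs, BlobFilters(min_area=10, max_area=150))
        assert [b.area for b in kept] == [100]

    def test_compactness_separates_disc_from_bar(self):
        img = np.zeros((80, 160), bool)
        yy, xx = np.mgrid[0:80, 0:160]
        img[(xx - 30) ** 2 + (yy - 40) ** 2 <= 20**2] = True  # disc
        img[70:74, 60:156] = True  # bar
        blobs = extract_blobs(img)
        # verify by the formula which shapes satisfy the bound
        expected = [b for b in blobs
                    if b.features.perimeter**2 / (4 * math.pi * b.area) <= 1.3]
        kept = filter_blobs(blobs, BlobFilters(max_compactness=1.3))
        assert kept == expected
        assert len(kept) == 1 and kept[0].features.compactness < 1.1

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            BlobFilters(min_area=10, max_area=5)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_filter_blobs_idempotent_subset(seed):
    rng = np.random.default_rng(seed)
    img = rng.random((30, 30)) > 0.75
    blobs = extract_blobs(img)
    bounds = BlobFilters(min_area=2, max_compactness=2.0)
    once = filter_blobs(blobs, bounds)
    assert set(id(b) for b in once) <= set(id(b) for b in blobs)
    assert filter_blobs(once, bounds) == once


def test_polarity_inversion_segments_dark_objects():
    img = np.full((30, 30), 220, np.uint8)
    img[10:20, 10:20] = 30
    mask = binarize(img, PipelineConfig(invert=True))
    assert mask.sum() == 100 and mask[15, 15]
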