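"""Post-tracking analysis of diel time series.

Three stages turn a raw per-frame feature series into circadian-growth
read-outs:

1. **Illumination-transition correction.**  Dual day/night illumination
   produces an abrupt gray-level shift at every period transition, and
   every pixel-counting variable (area, length, centroid, perimeter)
   inherits a step discontinuity there.  At each transition, the series
   after the transition is offset so that the step equals the mean
   within-period step of the period just ended — i.e. the observed jump
   K1 (night-to-day; K3 day-to-night) is removed and the preceding
   period's mean step K2 (resp. K4) restored.  Offsets accumulate across
   successive transitions and within-period successive differences are
   preserved exactly.  Applied literally as printed, the source
   formulas (add K1 + K2) would enlarge the discontinuity they are
   meant to remove; this module implements the evident contract — a
   continuous corrected series — and flags the sign interpretation.

2. **Accumulated growth.**  The running sum of positive increments
   only, so dips caused by the organ turning toward the camera do not
   reduce accumulated totals.

3. **Binary growth patterns.**  Per fixed interval (default 8 h, three
   cells per day), a flag pair records whether accumulated area and
   accumulated length each grew by more than an epsilon of their total
   range — the representation in which length-growth-without-area-growth
   (axis decoupling) events are counted.

Organ ranking applies the selection criteria used when several organs
are candidates: visibility (fraction of frames with a valid
measurement), occlusion by other organs (bounding-box overlap), and
movement activity (variance of the motion vector) for nutation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import CaptureSchedule
from .tracking import OrganTrack

__all__ = [
    "correct_transitions",
    "accumulate_growth",
    "binarize_growth",
    "GrowthPattern",
    "rank_organs",
]


def _period_segments(periods: list[str]) -> list[tuple[int, int, str]]:
    """Contiguous (start, stop_exclusive, label) runs of the period list."""
    segs = []
    start = 0
    for i in range(1, len(periods) + 1):
        if i == len(periods) or periods[i] != periods[i - 1]:
            segs.append((start, i, periods[i - 1]))
            start = i
    return segs


def correct_transitions(
    values: np.ndarray, schedule: CaptureSchedule
) -> np.ndarray:
    """Remove day/night transition steps from a pixel-counting series.

    At each period transition the post-transition samples are offset by
    ``-(observed jump) + (mean successive difference of the preceding
    period)``, offsets accumulating in time order.  Within-period
    successive differences are untouched.

    Raises if the series is not aligned to the schedule or any period
    has fewer than 2 samples (its mean step is undefined).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) != len(schedule):
        raise ValueError(
            f"series length {v.shape} does not match schedule length {len(schedule)}"
        )
    segs = _period_segments(schedule.periods)
    for start, stop, label in segs:
        if stop - start < 2:
            raise ValueError(
                f"period {label!r} starting at index {start} has "
                f"{stop - start} sample(s); need >= 2 for its mean step"
            )
    # Quantize offsets to the ulp grid of the series' top binade so that
    # adding them is exact arithmetic for pixel-count (integer-valued)
    # series and for fractional series staying within one binade: the
    # within-period successive differences then survive bit-for-bit.
    grid = float(np.spacing(4.0 * max(np.abs(v).max(), 1.0)))
    corrected = v.copy()
    offset = 0.0
    for k in range(1, len(segs)):
        p_start, p_stop, _ = segs[k - 1]
        start, stop, _ = segs[k]
        jump = v[start] - v[start - 1]
        mean_step = np.diff(v[p_start:p_stop]).mean()
        offset = round((offset - jump + mean_step) / grid) * grid
        corrected[start:stop] = v[start:stop] + offset
    return corrected


def accumulate_growth(values: np.ndarray) -> np.ndarray:
    """Running sum of positive increments, anchored at 0.

    Monotone non-decreasing by construction; for a monotone input this
    equals ``values - values[0]``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v.copy()
    inc = np.maximum(np.diff(v), 0.0)
    return np.concatenate([[0.0], np.cumsum(inc)])


@dataclass
class GrowthPattern:
    """Binary per-interval growth flags for area and length."""

    area_flags: np.ndarray
    length_flags: np.ndarray
    samples_per_interval: int

    def decoupling_events(self) -> int:
        """Intervals with length growth but no area growth."""
        return int(np.sum((self.length_flags == 1) & (self.area_flags == 0)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"interval": np.arange(len(self.area_flags)),
             "area": self.area_flags, "length": self.length_flags}
        )


def binarize_growth(
    accumulated_area: np.ndarray,
    accumulated_length: np.ndarray,
    samples_per_interval: int,
    epsilon_fraction: float = 0.01,
) -> GrowthPattern:
    """Binary growth pattern of two accumulated series.

    The series are cut into consecutive intervals of
    ``samples_per_interval`` samples (e.g. 48 samples = 8 h at 6
    images/hour, three cells per day); an interval's flag is 1 iff the
    accumulated series increases over it by more than
    ``epsilon_fraction`` of that series' total range.  Adding a constant
    to a whole series changes nothing.
    """
    a = np.asarray(accumulated_area, dtype=float)
    l = np.asarray(accumulated_length, dtype=float)
    if len(a) != len(l):
        raise ValueError("area and length series must have equal length")
    if samples_per_interval < 1 or len(a) < samples_per_interval:
        raise ValueError("series shorter than one interval")
    if len(a) % samples_per_interval != 0:
        raise ValueError(
            f"series length {len(a)} is not an integer number of "
            f"{samples_per_interval}-sample intervals"
        )
    n_int = len(a) // samples_per_interval

    def flags(series: np.ndarray) -> np.ndarray:
        eps = epsilon_fraction * np.ptp(series)
        out = np.zeros(n_int, dtype=int)
        for i in range(n_int):
            start = i * samples_per_interval
            stop = min((i + 1) * samples_per_interval, len(series) - 1)
            out[i] = 1 if series[stop] - series[start] > eps else 0
        return out

    return GrowthPattern(
        area_flags=flags(a),
        length_flags=flags(l),
        samples_per_interval=samples_per_interval,
    )


def _bbox_overlap_fraction(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Per-frame fraction of box b1 covered by box b2 (inclusive coords)."""
    ix0 = np.maximum(b1[:, 0], b2[:, 0])
    iy0 = np.maximum(b1[:, 1], b2[:, 1])
    ix1 = np.minimum(b1[:, 2], b2[:, 2])
    iy1 = np.minimum(b1[:, 3], b2[:, 3])
    iw = np.maximum(ix1 - ix0 + 1, 0)
    ih = np.maximum(iy1 - iy0 + 1, 0)
    own = (b1[:, 2] - b1[:, 0] + 1) * (b1[:, 3] - b1[:, 1] + 1)
    with np.errstate(invalid="ignore"):
        return np.where(own > 0, iw * ih / own, 0.0)


def rank_organs(
    tracks: list[OrganTrack],
    min_visibility: float = 0.8,
    max_occlusion: float = 0.5,
) -> pd.DataFrame:
    """Score and rank candidate organs for nutation analysis.

    Each organ is scored on visibility (fraction of frames with a valid
    measurement), occlusion (maximum fractional bounding-box overlap
    with any other organ in any frame; lower is better) and activity
    (variance of the motion vector).  Organs below the visibility
    threshold or above the occlusion threshold are discarded; survivors
    are ranked by activity, most active first.
    """
    if not tracks:
        raise ValueError("no tracks to rank")
    n = len(tracks)
    boxes = [t.table[["rc_x0", "rc_y0", "rc_x1", "rc_y1"]].to_numpy(float)
             for t in tracks]
    rows = []
    for i, t in enumerate(tracks):
        valid = ~t.table["missing"].to_numpy()
        visibility = float(valid.mean())
        occlusion = 0.0
        for j in range(n):
            if j == i or len(boxes[j]) != len(boxes[i]):
                continue
            frac = _bbox_overlap_fraction(boxes[i], boxes[j])
            occlusion = max(occlusion, float(np.nanmax(frac)) if len(frac) else 0.0)
        mv = t.motion_vector()
        activity = float(np.nanvar(mv))
        retained = visibility >= min_visibility and occlusion <= max_occlusion
        rows.append(dict(organ=i, visibility=visibility, occlusion=occlusion,
                         activity=activity, retained=retained))
    df = pd.DataFrame(rows)
    df = df.sort_values(["retained", "activity"], ascending=[False, False])
    df["rank"] = np.where(df["retained"], np.arange(1, len(df) + 1), 0)
    # only retained organs get ranks 1..k
    ranks = np.zeros(len(df), dtype=int)
    ranks[: int(df["retained"].sum())] = np.arange(1, int(df["retained"].sum()) + 1)
    df["rank"] = ranks
    return df.reset_index(drop=True)
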