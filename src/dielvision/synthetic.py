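"""Synthetic growth chamber: ground-truthed time-lapse sequences.

A single plant organ (flower limb or cladode) is emulated as a bright
elliptical or superelliptical blob on a darker background.  The organ
grows linearly (independent rates per axis, so length and area growth
can decouple), nutates as a sinusoidal vertical displacement of its
centroid, and may receive a rectangular "dawn pulse" — a step change in
position and angle during the first frames of each day period, the
movement signature real flowers show shortly after lights-on.

Day and night frames draw their foreground/background gray levels from
separate statistics; with ``jump_emulation`` enabled the pooled means of
the two periods differ by the configured offset, reproducing the abrupt
gray-level discontinuity that dual day/night camera systems introduce at
every illumination transition.

The organ is rasterized by an analytic point-in-boundary test at pixel
centers, with no anti-aliasing, so the ground-truth pixel area is the
exact count of foreground pixels; the analytic (continuous) area is
recorded alongside it.  All randomness flows through the seed, and
identical inputs produce bitwise-identical frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gamma

from .io import Frame
from .schedule import CaptureSchedule, ExperimentPlan, build_schedule

__all__ = [
    "OrganModel",
    "IlluminationModel",
    "GroundTruthRecord",
    "render_frame",
    "simulate_sequence",
    "DEFAULT_FRAME_SIZE",
]

#: CCIR camera resolution (height, width).
DEFAULT_FRAME_SIZE = (576, 768)


@dataclass(frozen=True)
class OrganModel:
    """Geometric model of the emulated organ.

    Semiaxes grow linearly: ``a(t) = a0 + growth_rate_x * t`` (pixels,
    t in frames), likewise for b.  Nutation displaces the centroid
    vertically by ``amplitude * cos(2 pi t / period)`` — the organ starts
    at the top of its swing, so the peak displacement from the
    first-frame origin over a full cycle is twice the amplitude.
    ``dawn_pulse_px`` / ``dawn_pulse_deg`` add a step offset in position
    and angle during the first ``dawn_pulse_frames`` frames of each day
    period.
    """

    shape_kind: str = "ellipse"  # "ellipse" | "superellipse"
    initial_semiaxes: tuple[float, float] = (20.0, 12.0)
    growth_rate_x: float = 0.0  # px/frame, semiaxis a
    growth_rate_y: float = 0.0  # px/frame, semiaxis b
    nutation_amplitude: float = 0.0  # px
    nutation_period: float = 144.0  # frames (24 h at 6 frames/h)
    base_angle: float = 0.0  # degrees CCW from horizontal
    angle_drift: float = 0.0  # degrees/frame
    center: Optional[tuple[float, float]] = None  # (cx, cy); frame center if None
    superellipse_exponent: float = 4.0
    dawn_pulse_px: float = 0.0
    dawn_pulse_deg: float = 0.0
    dawn_pulse_frames: int = 3

    def __post_init__(self) -> None:
        if self.shape_kind not in ("ellipse", "superellipse"):
            raise ValueError("shape_kind must be 'ellipse' or 'superellipse'")
        if min(self.initial_semiaxes) <= 0:
            raise ValueError("initial semiaxes must be positive")
        if self.nutation_period <= 0:
            raise ValueError("nutation_period must be positive")

    def semiaxes_at(self, t: float) -> tuple[float, float]:
        a = self.initial_semiaxes[0] + self.growth_rate_x * t
        b = self.initial_semiaxes[1] + self.growth_rate_y * t
        if a <= 0 or b <= 0:
            raise ValueError(f"semiaxes nonpositive at frame {t}")
        return a, b

    def angle_at(self, t: float, pulse: bool = False) -> float:
        ang = self.base_angle + self.angle_drift * t
        if pulse:
            ang += self.dawn_pulse_deg
        return ang % 180.0

    def centroid_at(
        self, t: float, size: tuple[int, int], pulse: bool = False
    ) -> tuple[float, float]:
        h, w = size
        cx, cy = self.center if self.center is not None else ((w - 1) / 2, (h - 1) / 2)
        cy = cy - self.nutation_amplitude * math.cos(
            2.0 * math.pi * t / self.nutation_period
        )
        if pulse:
            cy = cy - self.dawn_pulse_px
        return cx, cy

    def analytic_area(self, t: float) -> float:
        a, b = self.semiaxes_at(t)
        if self.shape_kind == "ellipse":
            return math.pi * a * b
        n = self.superellipse_exponent
        return 4.0 * a * b * gamma(1 + 1 / n) ** 2 / gamma(1 + 2 / n)

    def analytic_perimeter(self, t: float) -> float:
        a, b = self.semiaxes_at(t)
        if self.shape_kind == "ellipse":
            # Ramanujan's second approximation
            h = ((a - b) / (a + b)) ** 2
            return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        th = np.linspace(0, 2 * math.pi, 4096, endpoint=False)
        n = self.superellipse_exponent
        x = a * np.sign(np.cos(th)) * np.abs(np.cos(th)) ** (2 / n)
        y = b * np.sign(np.sin(th)) * np.abs(np.sin(th)) ** (2 / n)
        return float(np.hypot(np.diff(x, append=x[0]), np.diff(y, append=y[0])).sum())


@dataclass(frozen=True)
class IlluminationModel:
    """Gray-level statistics of the two illumination regimes.

    With ``jump_emulation`` off, night frames reuse the day statistics
    (a single-camera chamber); with it on, day and night levels differ,
    producing the transition discontinuity.  Foreground/background
    contrast must be at least 20 gray levels in each period so that
    histogram segmentation stays well-posed.
    """

    day_bg: float = 40.0
    day_fg: float = 200.0
    night_bg: float = 15.0
    night_fg: float = 140.0
    noise_sd: float = 0.0
    jump_emulation: bool = True
    #: Apparent boundary shift (px) of the rendered organ in night
    #: frames: real dual-illumination systems measure a slightly
    #: different organ extent at night because the boundary response
    #: depends on contrast.  Ground truth is unaffected, so every
    #: pixel-counting series acquires the step discontinuity at each
    #: transition that the correction stage exists to remove.  0 keeps
    #: the render contract exact (foreground == analytic boundary).
    apparent_size_jump_px: float = 0.0

    def __post_init__(self) -> None:
        for name in ("day_bg", "day_fg", "night_bg", "night_fg"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name}={v} outside [0, 255]")
        if abs(self.day_fg - self.day_bg) < 20:
            raise ValueError("day foreground/background contrast < 20 gray levels")
        if abs(self.night_fg - self.night_bg) < 20:
            raise ValueError("night foreground/background contrast < 20 gray levels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def levels(self, period: str) -> tuple[float, float]:
        """(background, foreground) gray levels active in a period."""
        if period == "day" or not self.jump_emulation:
            return self.day_bg, self.day_fg
        return self.night_bg, self.night_fg


@dataclass(frozen=True)
class GroundTruthRecord:
    """Analytic truth for one rendered frame."""

    index: int
    period: str
    area_true: float  # analytic (continuous) area, px^2
    area_px: int  # exact count of rendered foreground pixels
    cx: float
    cy: float
    semi_a: float
    semi_b: float
    angle: float
    perimeter_true: float


@dataclass(frozen=True)
class Distractor:
    """A static bright disc sharing the foreground gray level."""

    cx: float
    cy: float
    radius: float


def _organ_mask(
    organ: OrganModel,
    t: float,
    size: tuple[int, int],
    pulse: bool,
    grow_px: float = 0.0,
) -> tuple[np.ndarray, tuple[float, float], float, tuple[float, float]]:
    h, w = size
    a, b = organ.semiaxes_at(t)
    a, b = a + grow_px, b + grow_px
    cx, cy = organ.centroid_at(t, size, pulse)
    ang = organ.angle_at(t, pulse)
    r = max(a, b)
    if not (r <= cx <= w - 1 - r and r <= cy <= h - 1 - r):
        raise ValueError(
            f"organ extends outside the {w}x{h} frame at frame {t} "
            f"(centroid=({cx:.1f},{cy:.1f}), max semiaxis={r:.1f})"
        )
    # evaluate the inside test only within the organ's bounding box
    x0, x1 = int(math.floor(cx - r)) - 1, int(math.ceil(cx + r)) + 1
    y0, y1 = int(math.floor(cy - r)) - 1, int(math.ceil(cy + r)) + 1
    xs = np.arange(max(x0, 0), min(x1, w - 1) + 1)
    ys = np.arange(max(y0, 0), min(y1, h - 1) + 1)
    xx, yy = np.meshgrid(xs, ys)
    dx = xx - cx
    dy_up = -(yy - cy)
    th = math.radians(ang)
    u = dx * math.cos(th) + dy_up * math.sin(th)
    v = -dx * math.sin(th) + dy_up * math.cos(th)
    if organ.shape_kind == "ellipse":
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    else:
        n = organ.superellipse_exponent
        inside = np.abs(u / a) ** n + np.abs(v / b) ** n <= 1.0
    mask = np.zeros((h, w), dtype=bool)
    mask[ys[0] : ys[-1] + 1, xs[0] : xs[-1] + 1] = inside
    return mask, (cx, cy), ang, (a, b)


def render_frame(
    organ: OrganModel,
    illum: IlluminationModel,
    t: int,
    period: str,
    size: tuple[int, int] = DEFAULT_FRAME_SIZE,
    seed: int = 0,
    pulse: bool = False,
    distractors: Sequence[Distractor] = (),
) -> tuple[Frame, GroundTruthRecord]:
    """Render one frame and its ground-truth record.

    Foreground pixels are exactly those whose centers fall inside the
    analytic organ boundary at frame ``t``; Gaussian noise of the
    configured standard deviation is added and clipped to [0, 255].
    """
    if period not in ("day", "night"):
        raise ValueError("period must be 'day' or 'night'")
    h, w = size
    grow = (
        illum.apparent_size_jump_px
        if (period == "night" and illum.jump_emulation)
        else 0.0
    )
    mask, (cx, cy), ang, _ = _organ_mask(organ, t, size, pulse, grow_px=grow)
    a, b = organ.semiaxes_at(t)
    if grow != 0.0:  # ground truth always describes the undilated organ
        true_mask, _, _, _ = _organ_mask(organ, t, size, pulse, grow_px=0.0)
    else:
        true_mask = mask
    bg, fg = illum.levels(period)
    img = np.full((h, w), bg, dtype=float)
    img[mask] = fg
    for d in distractors:
        yy, xx = np.mgrid[0:h, 0:w]
        img[(xx - d.cx) ** 2 + (yy - d.cy) ** 2 <= d.radius**2] = fg
    if illum.noise_sd > 0:
        rng = np.random.default_rng([seed, t])
        img = img + rng.normal(0.0, illum.noise_sd, size=img.shape)
    frame = Frame(
        image=np.clip(np.rint(img), 0, 255).astype(np.uint8),
        index=t,
        period=period,
    )
    gt = GroundTruthRecord(
        index=t,
        period=period,
        area_true=organ.analytic_area(t),
        area_px=int(true_mask.sum()),
        cx=cx,
        cy=cy,
        semi_a=a,
        semi_b=b,
        angle=ang,
        perimeter_true=organ.analytic_perimeter(t),
    )
    return frame, gt


def _pulse_flags(schedule: CaptureSchedule, organ: OrganModel) -> list[bool]:
    """True for the first dawn_pulse_frames frames of each day period."""
    flags = [False] * len(schedule)
    if organ.dawn_pulse_px == 0 and organ.dawn_pulse_deg == 0:
        return flags
    since_dawn = None
    for i, inst in enumerate(schedule):
        if inst.transition == "T_nd":
            since_dawn = 0
        if since_dawn is not None and inst.period == "day":
            if since_dawn < organ.dawn_pulse_frames:
                flags[i] = True
            since_dawn += 1
        else:
            since_dawn = None
    return flags


def simulate_sequence(
    organ: OrganModel,
    illum: IlluminationModel,
    plan: ExperimentPlan,
    seed: int = 0,
    size: tuple[int, int] = DEFAULT_FRAME_SIZE,
    distractors: Sequence[Distractor] = (),
) -> tuple[list[Frame], pd.DataFrame]:
    """Render one frame per scheduled capture instant.

    The whole sequence geometry is validated up front so an organ that
    would outgrow the frame is rejected before any rendering.  Returns
    the frame list and the ground-truth table (one row per frame).
    """
    schedule = build_schedule(plan)
    n = len(schedule)
    # pre-validate geometry across the whole sequence
    for t in (0, n - 1) if n else ():
        _organ_mask(organ, t, size, pulse=False)
    pulses = _pulse_flags(schedule, organ)
    frames: list[Frame] = []
    records: list[GroundTruthRecord] = []
    for inst in schedule:
        frame, gt = render_frame(
            organ,
            illum,
            inst.index,
            inst.period,
            size=size,
            seed=seed,
            pulse=pulses[inst.index],
            distractors=distractors,
        )
        frame.timestamp = inst.timestamp
        frames.append(frame)
        records.append(gt)
    truth = pd.DataFrame([r.__dict__ for r in records])
    return frames, truth
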