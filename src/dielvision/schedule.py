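"""Capture scheduling for day/night growth-chamber experiments.

An :class:`ExperimentPlan` describes the photoperiod program (e.g. 16 h
light / 8 h dark), the acquisition rate and the experiment span.  From it a
:class:`CaptureSchedule` is derived: the ordered capture instants, each
labelled ``day`` or ``night``, with the first instant of every period
carrying a transition marker (``T_nd`` for night-to-day, ``T_dn`` for
day-to-night).  The phase convention anchors lights-on (dawn) at the start
time, so the very first instant of the experiment opens a day period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import pandas as pd
import yaml

__all__ = [
    "ExperimentPlan",
    "CaptureInstant",
    "CaptureSchedule",
    "count_images",
    "build_schedule",
    "label_periods",
]

#: Transition markers: night-to-day, day-to-night, or none.
T_ND = "T_nd"
T_DN = "T_dn"
NO_TRANSITION = "none"

_FORMATS = {"BMP", "TIFF", "JPG", "PNG"}


@dataclass(frozen=True)
class ExperimentPlan:
    """The day/night timing program of one experiment.

    Parameters
    ----------
    t_i, t_f : datetime
        Start and end of the experiment.  ``t_i`` coincides with dawn
        (lights on).
    day_hours, night_hours : float
        Length of the light and dark periods; must sum to 24.
    images_per_hour : int
        Acquisition rate, at least 1.
    night_flash_seconds : float
        Duration of the IR flash used for night captures.  Carried for
        provenance; does not alter capture instants.
    pre_switch_seconds : float
        Lead time for switching illumination before a capture.  Carried
        for provenance only.
    image_format : str
        One of BMP, TIFF, JPG, PNG.
    sample_distance_mm : float
        Camera-to-sample distance used for metric calibration lookup.
    """

    t_i: datetime
    t_f: datetime
    day_hours: float = 16.0
    night_hours: float = 8.0
    images_per_hour: int = 6
    night_flash_seconds: float = 2.0
    pre_switch_seconds: float = 0.0
    image_format: str = "PNG"
    sample_distance_mm: float = 500.0

    def __post_init__(self) -> None:
        if self.day_hours + self.night_hours != 24:
            raise ValueError(
                f"day_hours + night_hours must equal 24, got "
                f"{self.day_hours} + {self.night_hours}"
            )
        if self.t_f <= self.t_i:
            raise ValueError("t_f must be after t_i")
        if self.images_per_hour < 1:
            raise ValueError("images_per_hour must be >= 1")
        if self.night_flash_seconds <= 0:
            raise ValueError("night_flash_seconds must be > 0")
        if self.image_format.upper() not in _FORMATS:
            raise ValueError(f"image_format must be one of {sorted(_FORMATS)}")

    @property
    def total_hours(self) -> float:
        return (self.t_f - self.t_i).total_seconds() / 3600.0

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentPlan":
        d = dict(d)
        for key in ("t_i", "t_f"):
            if isinstance(d.get(key), str):
                d[key] = datetime.fromisoformat(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentPlan":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class CaptureInstant:
    timestamp: datetime
    index: int
    period: str  # "day" | "night"
    transition: str  # T_ND | T_DN | NO_TRANSITION


@dataclass
class CaptureSchedule:
    """Ordered capture instants derived from an :class:`ExperimentPlan`.

    ``plan`` may be None for a schedule reloaded from its CSV export,
    which carries everything the downstream analysis needs."""

    plan: ExperimentPlan | None
    instants: list[CaptureInstant] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instants)

    def __iter__(self):
        return iter(self.instants)

    def __getitem__(self, i):
        return self.instants[i]

    @property
    def periods(self) -> list[str]:
        return [c.period for c in self.instants]

    @property
    def transitions(self) -> list[int]:
        """Indices of instants flagged as period transitions."""
        return [
            c.index for c in self.instants if c.transition != NO_TRANSITION
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [c.index for c in self.instants],
                "timestamp": [c.timestamp for c in self.instants],
                "period": [c.period for c in self.instants],
                "transition": [c.transition for c in self.instants],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CaptureSchedule":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        instants = [
            CaptureInstant(
                timestamp=row.timestamp.to_pydatetime(),
                index=int(row.index_),
                period=row.period,
                transition=row.transition,
            )
            for row in df.rename(columns={"index": "index_"}).itertuples()
        ]
        return cls(plan=None, instants=instants)


def count_images(plan: ExperimentPlan) -> int:
    """Total number of captures of a plan: days x images/hour x 24.

    A non-integral day span is computed on fractional hours (hours x
    images/hour), which reduces to the day formula for whole days.
    """
    return int(round(plan.total_hours * plan.images_per_hour))


def _phase_hours(ts: datetime, plan: ExperimentPlan) -> float:
    """Hours since the most recent dawn, in [0, 24)."""
    elapsed = (ts - plan.t_i).total_seconds() / 3600.0
    return elapsed % 24.0


def label_periods(
    timestamps: Sequence[datetime], plan: ExperimentPlan
) -> list[str]:
    """Label each timestamp ``day`` or ``night``.

    Dawn is anchored at ``t_i``; hours ``[0, day_hours)`` of each cycle are
    day, ``[day_hours, 24)`` night (half-open: an instant on the boundary
    belongs to the period that begins there).
    """
    labels = []
    for ts in timestamps:
        if not (plan.t_i <= ts <= plan.t_f):
            raise ValueError(f"timestamp {ts} outside plan [{plan.t_i}, {plan.t_f}]")
        labels.append("day" if _phase_hours(ts, plan) < plan.day_hours else "night")
    return labels


def build_schedule(plan: ExperimentPlan) -> CaptureSchedule:
    """Build the capture timeline: evenly spaced instants with period
    labels and transition flags.

    Instants are spaced ``60 / images_per_hour`` minutes apart starting at
    ``t_i``.  The first instant of each period carries the transition flag
    (``T_nd`` when a day period opens, ``T_dn`` when a night period opens);
    the flag at index 0 marks the nominal dawn that starts the experiment.
    """
    n = count_images(plan)
    step = timedelta(minutes=60.0 / plan.images_per_hour)
    instants: list[CaptureInstant] = []
    prev_period: str | None = None
    for i in range(n):
        ts = plan.t_i + i * step
        # phase from the capture index, not the timestamp: timedelta
        # rounds to microseconds, which would mislabel instants that
        # fall exactly on a period boundary
        phase = (i / plan.images_per_hour) % 24.0
        period = "day" if phase < plan.day_hours else "night"
        if period != prev_period:
            flag = T_ND if period == "day" else T_DN
        else:
            flag = NO_TRANSITION
        instants.append(CaptureInstant(ts, i, period, flag))
        prev_period = period
    return CaptureSchedule(plan=plan, instants=instants)
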