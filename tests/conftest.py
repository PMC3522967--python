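from datetime import datetime, timedelta

import numpy as np
import pytest

from dielvision.schedule import ExperimentPlan


@pytest.fixture
def day_plan():
    """1-day, 1 image/hour, 16 h light / 8 h dark."""
    t0 = datetime(2026, 3, 1, 8, 0)
    return ExperimentPlan(t_i=t0, t_f=t0 + timedelta(days=1), images_per_hour=1)


def make_plan(days: float, images_per_hour: int = 6, day_hours: float = 16.0):
    t0 = datetime(2026, 3, 1, 8, 0)
    return ExperimentPlan(
        t_i=t0,
        t_f=t0 + timedelta(days=days),
        day_hours=day_hours,
        night_hours=24 - day_hours,
        images_per_hour=images_per_hour,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
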