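"""Locomotor activity measures: total distance walked and average velocity.

Total distance is the sum of Euclidean step lengths over consecutive
observed frames; average velocity is path length divided by observed
duration.  Frame gaps contribute no distance and no time is interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .trajectory_io import TrajectoryTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FlyActivity:
    fly_id: int
    total_distance: float  # mm
    mean_velocity: float  # mm/s


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample SD (ddof=1), and SEM over one pooled collection."""

    mean: float
    sd: float
    sem: float
    n: int


def per_fly_activity(table: TrajectoryTable) -> list[FlyActivity]:
    """Total distance and mean velocity per fly.

    Flies observed for fewer than two frames are excluded with a warning.
    Distance over a frame gap is the straight segment between the two
    observed positions; elapsed time is (last_frame - first_frame) / fps.
    """
    fps = table.arena.fps
    out: list[FlyActivity] = []
    for fly_id, sub in table.data.groupby("fly_id"):
        if len(sub) < 2:
            logger.warning("fly %d has <2 frames; excluded from activity", fly_id)
            continue
        x = sub["x_mm"].to_numpy()
        y = sub["y_mm"].to_numpy()
        dist = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
        frames = sub["frame"].to_numpy()
        elapsed = (frames[-1] - frames[0]) / fps
        out.append(FlyActivity(int(fly_id), dist, dist / elapsed))
    return out


def group_activity_summary(values) -> SummaryStats:
    """Pooled summary (mean, SD with ddof=1, SEM) over flies of one group."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValidationError("group summary requires at least 2 flies")
    sd = float(np.std(arr, ddof=1))
    return SummaryStats(float(np.mean(arr)), sd, sd / np.sqrt(arr.size), arr.size)
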