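import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from flysin import ArenaSpec, TrajectoryTable

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("suite")


def build_table(tracks, fps=60.0, radius=65.0, body_length=2.5):
    """Build a TrajectoryTable from per-fly tracks.

    ``tracks`` maps fly_id -> (positions, headings) where positions is an
    (F, 2) array-like and headings an (F,) array-like (or None for zeros).
    """
    rows = []
    for fly_id, (positions, headings) in tracks.items():
        positions = np.asarray(positions, dtype=float)
        if headings is None:
            headings = np.zeros(len(positions))
        bl = body_length[fly_id] if isinstance(body_length, dict) else body_length
        for f, ((x, y), h) in enumerate(zip(positions, np.asarray(headings))):
            rows.append((fly_id, f, x, y, h, bl))
    df = pd.DataFrame(rows, columns=["fly_id", "frame", "x_mm", "y_mm",
                                     "heading_deg", "body_length_mm"])
    return TrajectoryTable.from_dataframe(df, ArenaSpec(radius=radius, fps=fps))


def random_pair_table(rng, n_frames, fps=60.0, step_sd=2.0, radius=65.0):
    """Two flies doing independent bounded random walks with random headings;
    scaled so that the pair repeatedly crosses the interaction distance."""
    tracks = {}
    for fly in (0, 1):
        pos = np.empty((n_frames, 2))
        pos[0] = rng.uniform(-5, 5, 2)
        steps = rng.normal(0, step_sd, (n_frames - 1, 2))
        pos[1:] = pos[0] + np.cumsum(steps, axis=0)
        r = np.hypot(pos[:, 0], pos[:, 1])
        too_far = r > radius - 3
        pos[too_far] *= ((radius - 3) / r[too_far])[:, None]
        headings = rng.uniform(0, 360, n_frames)
        tracks[fly] = (pos, headings)
    return build_table(tracks, fps=fps, radius=radius,
                       body_length={0: float(rng.uniform(2.0, 3.0)),
                                    1: float(rng.uniform(2.0, 3.0))})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
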