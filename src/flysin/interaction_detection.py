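"""Rule-based detection of pairwise social-interaction events.

An ordered pair (i, j) is *engaged* at a frame when

1. the centre-to-centre distance is within ``distance_bl`` body lengths of
   the focal fly i (per-fly mean tracked body length), and
2. the facing angle of i toward j — the angle between i's heading vector and
   the vector from i to j, in [0, 180] — is below ``max_angle_deg``.

Maximal engaged runs lasting at least ``min_duration_s`` (optionally
bridging short disengaged gaps) become :class:`InteractionEvent` records.
In symmetric mode (the default) the engagement predicate is symmetrised —
a pair is engaged when either direction satisfies both criteria — and every
event is registered in both directions with identical frames, so each fly's
in-event and out-event multisets coincide.  With ``symmetric=False`` the
two directions are detected independently.

Defaults follow the common criteria for grouped flies: 2.5 body lengths,
160 degrees, 0.6 s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .trajectory_io import TrajectoryTable

logger = logging.getLogger(__name__)

_CHUNK_FRAMES = 2048  # frames per block in the vectorised feature pass


@dataclass(frozen=True)
class InteractionCriteria:
    """Thresholds of the three-part interaction rule.

    ``min_duration_inclusive`` controls the exact boundary: with the default
    True a run of exactly ``ceil(min_duration_s * fps)`` frames qualifies
    (0.6 s at 60 fps = 36 frames); False requires strictly more.
    """

    distance_bl: float = 2.5
    max_angle_deg: float = 160.0
    min_duration_s: float = 0.6
    gap_bridge_frames: int = 0
    symmetric: bool = True
    min_duration_inclusive: bool = True

    def validate(self) -> None:
        if not self.distance_bl > 0:
            raise ConfigurationError("distance_bl must be > 0")
        if not 0 < self.max_angle_deg <= 180:
            raise ConfigurationError("max_angle_deg must be in (0, 180]")
        if not self.min_duration_s > 0:
            raise ConfigurationError("min_duration_s must be > 0")
        if self.gap_bridge_frames < 0:
            raise ConfigurationError("gap_bridge_frames must be >= 0")

    def min_frames(self, fps: float) -> int:
        return int(math.ceil(self.min_duration_s * fps))


@dataclass(frozen=True)
class InteractionEvent:
    """One directed, duration-qualified interaction episode."""

    source: int
    target: int
    start_frame: int
    end_frame: int  # inclusive
    duration_s: float
    onset_x_mm: float
    onset_y_mm: float


def _table_arrays(table: TrajectoryTable):
    """Dense (frame, fly) arrays of positions/headings; NaN where missing."""
    df = table.data
    ids = table.fly_ids
    n = len(ids)
    id_to_col = {int(f): k for k, f in enumerate(ids)}
    n_frames = table.n_frames
    P = np.full((n_frames, n, 2), np.nan)
    H = np.full((n_frames, n), np.nan)
    rows = df["frame"].to_numpy()
    cols = df["fly_id"].map(id_to_col).to_numpy()
    P[rows, cols, 0] = df["x_mm"].to_numpy()
    P[rows, cols, 1] = df["y_mm"].to_numpy()
    H[rows, cols] = df["heading_deg"].to_numpy()
    B = table.body_lengths().reindex(ids).to_numpy()
    return ids, P, H, B


def _engaged_mask(P, H, B, criteria) -> np.ndarray:
    """Boolean (n_frames, n, n) directed engagement mask, chunked over frames."""
    n_frames, n, _ = P.shape
    eng = np.zeros((n_frames, n, n), dtype=bool)
    thresh = criteria.distance_bl * B  # per source fly
    for s in range(0, n_frames, _CHUNK_FRAMES):
        e = min(s + _CHUNK_FRAMES, n_frames)
        p = P[s:e]
        h = np.radians(H[s:e])
        vec = p[:, None, :, :] - p[:, :, None, :]  # vec[f, i, j] = p_j - p_i
        dist = np.hypot(vec[..., 0], vec[..., 1])
        hx = np.cos(h)[:, :, None]
        hy = np.sin(h)[:, :, None]
        dot = hx * vec[..., 0] + hy * vec[..., 1]
        cross = hx * vec[..., 1] - hy * vec[..., 0]
        angle = np.degrees(np.arctan2(np.abs(cross), dot))
        ok = (dist <= thresh[None, :, None]) & (angle < criteria.max_angle_deg)
        ok &= np.isfinite(dist) & np.isfinite(angle)
        eng[s:e] = ok
    di = np.arange(n)
    eng[:, di, di] = False
    return eng


def pairwise_frame_features(table: TrajectoryTable) -> pd.DataFrame:
    """Per-frame distance and facing angle for every ordered fly pair.

    Columns: frame, source, target, distance_mm, facing_angle_deg.  Frames
    where either fly is missing are skipped (logged once).
    """
    ids, P, H, B = _table_arrays(table)
    n_frames, n, _ = P.shape
    parts = []
    skipped = 0
    for s in range(0, n_frames, _CHUNK_FRAMES):
        e = min(s + _CHUNK_FRAMES, n_frames)
        p = P[s:e]
        h = np.radians(H[s:e])
        vec = p[:, None, :, :] - p[:, :, None, :]
        dist = np.hypot(vec[..., 0], vec[..., 1])
        hx = np.cos(h)[:, :, None]
        hy = np.sin(h)[:, :, None]
        dot = hx * vec[..., 0] + hy * vec[..., 1]
        cross = hx * vec[..., 1] - hy * vec[..., 0]
        angle = np.degrees(np.arctan2(np.abs(cross), dot))
        fr, si, ti = np.meshgrid(np.arange(s, e), np.arange(n), np.arange(n),
                                 indexing="ij")
        keep = (si != ti)
        finite = np.isfinite(dist) & np.isfinite(angle)
        skipped += int(np.sum(keep & ~finite))
        keep &= finite
        parts.append(pd.DataFrame({
            "frame": fr[keep],
            "source": ids[si[keep]],
            "target": ids[ti[keep]],
            "distance_mm": dist[keep],
            "facing_angle_deg": angle[keep],
        }))
    if skipped:
        logger.info("skipped %d pair-frames with a missing fly", skipped)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["frame", "source", "target", "distance_mm", "facing_angle_deg"])
    return out.sort_values(["frame", "source", "target"]).reset_index(drop=True)


def _runs(mask: np.ndarray, min_frames: int, bridge: int,
          inclusive: bool) -> list[tuple[int, int]]:
    """Qualifying (start, end)-inclusive runs of True, bridging short gaps."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > bridge + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    out = []
    for s, e in zip(starts, ends):
        a, b = int(idx[s]), int(idx[e])
        length = b - a + 1
        if length >= min_frames if inclusive else length > min_frames:
            out.append((a, b))
    return out


def detect_events(table: TrajectoryTable,
                  criteria: InteractionCriteria = InteractionCriteria(),
                  features: pd.DataFrame | None = None) -> list[InteractionEvent]:
    """Detect all qualifying interaction events in one trajectory table.

    If ``features`` (output of :func:`pairwise_frame_features`) is supplied,
    the engagement mask is rebuilt from it; otherwise features are computed
    internally in a vectorised pass.
    """
    criteria.validate()
    fps = table.arena.fps
    min_frames = criteria.min_frames(fps)
    ids, P, H, B = _table_arrays(table)
    n = len(ids)
    col = {int(f): k for k, f in enumerate(ids)}

    if features is not None:
        eng = np.zeros((table.n_frames, n, n), dtype=bool)
        si = features["source"].map(col).to_numpy()
        ti = features["target"].map(col).to_numpy()
        ok = ((features["distance_mm"].to_numpy()
               <= criteria.distance_bl * B[si])
              & (features["facing_angle_deg"].to_numpy()
                 < criteria.max_angle_deg))
        eng[features["frame"].to_numpy()[ok], si[ok], ti[ok]] = True
        di = np.arange(n)
        eng[:, di, di] = False
    else:
        eng = _engaged_mask(P, H, B, criteria)

    events: list[InteractionEvent] = []

    def emit(i: int, j: int, a: int, b: int) -> None:
        mid = (P[a, i] + P[a, j]) / 2.0
        events.append(InteractionEvent(
            source=int(ids[i]), target=int(ids[j]),
            start_frame=a, end_frame=b,
            duration_s=(b - a + 1) / fps,
            onset_x_mm=float(mid[0]), onset_y_mm=float(mid[1]),
        ))

    if criteria.symmetric:
        sym = eng | eng.transpose(0, 2, 1)
        for i in range(n):
            for j in range(i + 1, n):
                for a, b in _runs(sym[:, i, j], min_frames,
                                  criteria.gap_bridge_frames,
                                  criteria.min_duration_inclusive):
                    emit(i, j, a, b)
                    emit(j, i, a, b)
    else:
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                for a, b in _runs(eng[:, i, j], min_frames,
                                  criteria.gap_bridge_frames,
                                  criteria.min_duration_inclusive):
                    emit(i, j, a, b)

    events.sort(key=lambda ev: (ev.start_frame, ev.source, ev.target))
    return events


def event_summary(events) -> pd.DataFrame:
    """Per ordered pair: event count and total duration in seconds."""
    if not events:
        return pd.DataFrame(columns=["source", "target", "count", "duration_s"])
    df = pd.DataFrame([(e.source, e.target, e.duration_s) for e in events],
                      columns=["source", "target", "duration_s"])
    out = (df.groupby(["source", "target"], as_index=False)
             .agg(count=("duration_s", "size"), duration_s=("duration_s", "sum")))
    return out


def events_to_dataframe(events) -> pd.DataFrame:
    """Events as a flat table (CSV-ready)."""
    return pd.DataFrame(
        [(e.source, e.target, e.start_frame, e.end_frame, e.duration_s,
          e.onset_x_mm, e.onset_y_mm) for e in events],
        columns=["source", "target", "start_frame", "end_frame",
                 "duration_s", "onset_x_mm", "onset_y_mm"],
    )


def validate_events(events, n_flies: int) -> None:
    """Raise if any event references a fly id outside ``range(n_flies)``."""
    for e in events:
        if not (0 <= e.source < n_flies and 0 <= e.target < n_flies):
            raise ValidationError(
                f"event references unknown fly: ({e.source}, {e.target})"
            )
        if e.source == e.target:
            raise ValidationError(f"self-interaction event for fly {e.source}")
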