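"""Reading, validating and writing multi-fly trajectory tables.

Trackers such as FlyTracker emit per-frame position/orientation records for
every identified fly in an arena.  This module normalises those records into
a single canonical in-memory container, :class:`TrajectoryTable`, holding one
row per fly per frame with arena-centred coordinates in millimetres and
headings in degrees counter-clockwise from the +x axis, in ``[0, 360)``.

Two input dialects are supported:

``long-csv``
    One row per fly per frame.  Either already canonical (columns
    ``fly_id, frame, x_mm, y_mm, heading_deg, body_length_mm``) or in pixel
    units (``x_px, y_px, body_length_px`` instead), converted through the
    arena's ``px_per_mm`` scale.

``tracker-matrix``
    One row per frame, per-fly column blocks ``x_<id>, y_<id>, theta_<id>,
    bl_<id>`` in pixels — a documented adapter for wide per-frame matrices.

The canonical on-disk form is the long CSV with the mm columns; writing and
re-reading a valid table is a bit-for-bit round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DialectError, ValidationError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["fly_id", "frame", "x_mm", "y_mm", "heading_deg", "body_length_mm"]

_PX_COLUMNS = ["fly_id", "frame", "x_px", "y_px", "heading_deg", "body_length_px"]


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and recording parameters of one circular arena.

    ``center_x``/``center_y`` locate the arena centre in the raw coordinate
    system (mm); canonical coordinates are arena-centred.  ``radius`` is in
    mm (default 65 mm: a 13 cm diameter chamber), ``px_per_mm`` the pixel
    scale of the recording, ``fps`` the frame rate (default 60).
    """

    center_x: float = 0.0
    center_y: float = 0.0
    radius: float = 65.0
    px_per_mm: float = 1.0
    fps: float = 60.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ConfigurationError("ArenaSpec.radius must be > 0")
        if not self.fps > 0:
            raise ConfigurationError("ArenaSpec.fps must be > 0")
        if not self.px_per_mm > 0:
            raise ConfigurationError("ArenaSpec.px_per_mm must be > 0")

    def to_dict(self) -> dict:
        return {
            "center_x": self.center_x,
            "center_y": self.center_y,
            "radius": self.radius,
            "px_per_mm": self.px_per_mm,
            "fps": self.fps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaSpec":
        return cls(**d)


def normalize_heading(deg):
    """Map any angle in degrees onto ``[0, 360)``."""
    h = np.asarray(deg, dtype=float) % 360.0
    # tiny negative inputs round to exactly 360.0 under fmod
    return np.where(h >= 360.0, 0.0, h)


@dataclass
class TrajectoryTable:
    """Per-frame kinematic state of every identified fly in one video.

    ``data`` holds the canonical columns; rows are sorted by (fly_id, frame).
    Structural invariants (unique (fly_id, frame), contiguous identity set)
    are enforced at construction; per-fly frame gaps and out-of-arena points
    are *reported* by :func:`validate_trajectories`, not rejected.
    """

    data: pd.DataFrame
    arena: ArenaSpec

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, arena: ArenaSpec) -> "TrajectoryTable":
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing trajectory columns: {missing}")
        df = df.loc[:, CANONICAL_COLUMNS].copy()
        df["fly_id"] = df["fly_id"].astype(np.int64)
        df["frame"] = df["frame"].astype(np.int64)
        for c in CANONICAL_COLUMNS[2:]:
            df[c] = df[c].astype(float)
        if (df["frame"] < 0).any():
            raise ValidationError("negative frame indices present")
        if (df["body_length_mm"] <= 0).any():
            raise ValidationError("non-positive body lengths present")
        dup = df.duplicated(subset=["fly_id", "frame"])
        if dup.any():
            pairs = df.loc[dup, ["fly_id", "frame"]].itertuples(index=False)
            listing = ", ".join(f"({p.fly_id}, {p.frame})" for p in list(pairs)[:10])
            raise ValidationError(f"duplicate (fly_id, frame) records: {listing}")
        ids = np.sort(df["fly_id"].unique())
        if len(ids) and not np.array_equal(ids, np.arange(ids[0], ids[0] + len(ids))):
            expected = set(range(ids[0], ids[0] + len(ids)))
            raise ValidationError(
                f"fly identities are not contiguous; missing {sorted(expected - set(ids))}"
            )
        df["heading_deg"] = normalize_heading(df["heading_deg"].to_numpy())
        df = df.sort_values(["fly_id", "frame"], kind="mergesort").reset_index(drop=True)
        return cls(data=df, arena=arena)

    @property
    def fly_ids(self) -> np.ndarray:
        return np.sort(self.data["fly_id"].unique())

    @property
    def n_flies(self) -> int:
        return int(self.data["fly_id"].nunique())

    @property
    def n_frames(self) -> int:
        if self.data.empty:
            return 0
        return int(self.data["frame"].max()) + 1

    def body_lengths(self) -> pd.Series:
        """Per-fly mean tracked body length (mm), indexed by fly_id."""
        return self.data.groupby("fly_id")["body_length_mm"].mean()


@dataclass
class GapRecord:
    fly_id: int
    start_frame: int
    length: int


@dataclass
class ValidationReport:
    """Pure report of structural anomalies; never mutates its input."""

    n_rows: int
    n_flies: int
    n_frames: int
    duplicate_records: int
    gaps: list = field(default_factory=list)
    out_of_arena: int = 0
    checks: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(self.checks.values())


def validate_trajectories(table: TrajectoryTable) -> ValidationReport:
    """Report per-fly frame gaps and out-of-arena points.

    A point is out of arena when its distance from the arena centre exceeds
    ``radius + 2 * body_length``.  Gaps are runs of missing frames strictly
    inside a fly's observed frame range.
    """
    df = table.data
    gaps: list[GapRecord] = []
    for fly_id, sub in df.groupby("fly_id"):
        frames = sub["frame"].to_numpy()
        diffs = np.diff(frames)
        for k in np.flatnonzero(diffs > 1):
            gaps.append(GapRecord(int(fly_id), int(frames[k]) + 1, int(diffs[k]) - 1))
    r = np.hypot(df["x_mm"].to_numpy(), df["y_mm"].to_numpy())
    out = int(np.sum(r > table.arena.radius + 2.0 * df["body_length_mm"].to_numpy()))
    report = ValidationReport(
        n_rows=len(df),
        n_flies=table.n_flies,
        n_frames=table.n_frames,
        duplicate_records=0,  # construction rejects duplicates
        gaps=gaps,
        out_of_arena=out,
        checks={"no_gaps": not gaps, "all_inside_arena": out == 0},
    )
    return report


def _read_sidecar_arena(path: Path) -> ArenaSpec | None:
    sidecar = path.with_suffix(path.suffix + ".arena.yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            return ArenaSpec.from_dict(yaml.safe_load(fh))
    return None


def write_arena_sidecar(arena: ArenaSpec, table_path) -> Path:
    table_path = Path(table_path)
    sidecar = table_path.with_suffix(table_path.suffix + ".arena.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(arena.to_dict(), fh)
    return sidecar


def read_trajectory_table(path, dialect: str = "long-csv",
                          arena: ArenaSpec | None = None) -> TrajectoryTable:
    """Read a trajectory table, converting pixels to arena-centred mm.

    Parameters
    ----------
    path : file path of the delimited table.
    dialect : ``"long-csv"`` or ``"tracker-matrix"``.
    arena : arena geometry; if omitted, a ``<path>.arena.yaml`` sidecar is
        required.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"trajectory file not found: {path}")
    if arena is None:
        arena = _read_sidecar_arena(path)
    if arena is None:
        raise ConfigurationError(
            f"no ArenaSpec supplied and no sidecar found for {path}"
        )
    if dialect == "long-csv":
        raw = pd.read_csv(path)
        if set(CANONICAL_COLUMNS).issubset(raw.columns):
            df = raw.loc[:, CANONICAL_COLUMNS].copy()
        elif set(_PX_COLUMNS).issubset(raw.columns):
            df = pd.DataFrame(
                {
                    "fly_id": raw["fly_id"],
                    "frame": raw["frame"],
                    "x_mm": raw["x_px"] / arena.px_per_mm - arena.center_x,
                    "y_mm": raw["y_px"] / arena.px_per_mm - arena.center_y,
                    "heading_deg": raw["heading_deg"],
                    "body_length_mm": raw["body_length_px"] / arena.px_per_mm,
                }
            )
        else:
            raise ValidationError(
                f"long-csv file {path} has neither mm nor px column sets; "
                f"found {list(raw.columns)}"
            )
    elif dialect == "tracker-matrix":
        df = _melt_tracker_matrix(pd.read_csv(path), arena)
    else:
        raise DialectError(
            f"unknown dialect {dialect!r}; expected 'long-csv' or 'tracker-matrix'"
        )
    return TrajectoryTable.from_dataframe(df, arena)


def _melt_tracker_matrix(raw: pd.DataFrame, arena: ArenaSpec) -> pd.DataFrame:
    """Adapt a wide per-frame matrix (x_<id>, y_<id>, theta_<id>, bl_<id>, px)."""
    if "frame" not in raw.columns:
        raise ValidationError("tracker-matrix file lacks a 'frame' column")
    ids = sorted(
        {int(c.split("_", 1)[1]) for c in raw.columns if c.startswith("x_")}
    )
    if not ids:
        raise ValidationError("tracker-matrix file has no per-fly x_<id> columns")
    parts = []
    for i in ids:
        for col in (f"x_{i}", f"y_{i}", f"theta_{i}", f"bl_{i}"):
            if col not in raw.columns:
                raise ValidationError(f"tracker-matrix file missing column {col}")
        parts.append(
            pd.DataFrame(
                {
                    "fly_id": i,
                    "frame": raw["frame"],
                    "x_mm": raw[f"x_{i}"] / arena.px_per_mm - arena.center_x,
                    "y_mm": raw[f"y_{i}"] / arena.px_per_mm - arena.center_y,
                    "heading_deg": raw[f"theta_{i}"],
                    "body_length_mm": raw[f"bl_{i}"] / arena.px_per_mm,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_trajectory_table(table: TrajectoryTable, path,
                           sidecar: bool = True) -> Path:
    """Write the canonical long CSV (and, by default, the arena sidecar).

    Floats are serialised with shortest round-trip repr, so
    ``read(write(table))`` reproduces the table bit-for-bit.
    """
    path = Path(path)
    try:
        table.data.loc[:, CANONICAL_COLUMNS].to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"cannot write trajectory table to {path}: {exc}") from exc
    if sidecar:
        write_arena_sidecar(table.arena, path)
    return path
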