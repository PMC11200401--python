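"""Three-level aggregation, two-group statistics, and interaction localization.

Aggregation follows the replication structure of a grouped-fly experiment:
(i) each one-minute snapshot yields a measure vector; (ii) snapshot vectors
are averaged into one value per video; (iii) per-video values are averaged
into the group mean, with sample SD (ddof=1) and SEM over the ``n_videos``
replicates.  Undefined entries (flagged assortativity on degenerate
snapshots) are excluded from means with the exclusion count recorded.

Two-group comparisons are unpaired t-tests on the per-video values (the
video is the unit of replication), Student's pooled-variance variant by
default, Welch as an alternative.  A summary-statistic t-test is also
provided for recomputing t from published group means and dispersions
alone.  Both SD and SEM are always reported: published dispersions for this
kind of experiment are sometimes labelled SD while behaving as SEMs, and
reporting both keeps either reading checkable.

Interaction localization bins event onset midpoints onto a square grid over
the arena; ``boundary_fraction`` quantifies thigmotaxis as the share of
events in the outer annulus, next to the uniform-baseline area share
(1 - (1 - f)^2, i.e. 0.36 for the outer 20% of the radius).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .activity_metrics import per_fly_activity
from .errors import ConfigurationError, ValidationError
from .interaction_detection import InteractionCriteria, detect_events
from .sin_networks import (MeasureConfig, MeasureVector, build_snapshots,
                           measure_suite)
from .trajectory_io import ArenaSpec, TrajectoryTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# aggregation

@dataclass(frozen=True)
class GroupSummary:
    """Per-measure group-level summary over per-video means."""

    measure: str
    video_means: tuple
    mean: float
    sd: float
    sem: float
    n_videos: int


def aggregate_video(measure_vectors) -> tuple[dict, dict]:
    """Mean per measure across the snapshots of one video.

    Returns (means, n_excluded): NaN entries are excluded from the mean and
    counted per measure; a measure undefined on every snapshot stays NaN.
    """
    vectors = list(measure_vectors)
    if not vectors:
        raise ValidationError("aggregate_video requires at least one snapshot")
    names = MeasureVector.field_names()
    arr = np.array([[getattr(v, nm) for nm in names] for v in vectors])
    means, excluded = {}, {}
    for k, nm in enumerate(names):
        col = arr[:, k]
        bad = np.isnan(col)
        excluded[nm] = int(bad.sum())
        if bad.sum():
            logger.info("measure %s undefined on %d/%d snapshots",
                        nm, int(bad.sum()), len(col))
        means[nm] = float(np.nanmean(col)) if (~bad).any() else math.nan
    return means, excluded


def aggregate_group(measure: str, per_video_means) -> GroupSummary:
    """Group mean, SD (ddof=1) and SEM over the per-video means."""
    raw = list(per_video_means)
    if len(raw) < 2:
        raise ValidationError(
            f"group summary for {measure!r} needs >= 2 videos"
        )
    vals = np.asarray([v for v in raw if not math.isnan(v)], dtype=float)
    if vals.size < 2:
        # measure undefined on (nearly) every video: flag, don't fail
        logger.info("measure %s defined on %d/%d videos; summary flagged "
                    "undefined", measure, vals.size, len(raw))
        return GroupSummary(measure, tuple(vals.tolist()), math.nan,
                            math.nan, math.nan, int(vals.size))
    sd = float(np.std(vals, ddof=1))
    return GroupSummary(measure, tuple(vals.tolist()), float(vals.mean()),
                        sd, sd / math.sqrt(vals.size), int(vals.size))


# ---------------------------------------------------------------------------
# t-tests

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def unpaired_ttest(values_a, values_b, variant: str = "student") -> TTestResult:
    """Two-sided unpaired t-test; t's sign follows (a - b)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return TTestResult(math.nan, math.nan, math.nan, variant)
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    df = a.size + b.size - 2 if variant == "student" else float(res.df)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue),
                       variant)


def summary_ttest(mean_a: float, disp_a: float, n_a: int,
                  mean_b: float, disp_b: float, n_b: int,
                  disp_kind: str = "sem") -> TTestResult:
    """t-test from summary statistics only.

    ``disp_kind`` says whether the dispersions are SDs or SEMs; the t uses
    the standard errors, t = (mean_a - mean_b) / sqrt(se_a^2 + se_b^2), with
    Welch–Satterthwaite degrees of freedom.
    """
    if disp_kind not in ("sd", "sem"):
        raise ConfigurationError(f"disp_kind must be 'sd' or 'sem', got {disp_kind!r}")
    if n_a < 2 or n_b < 2:
        raise ValidationError("summary t-test needs n >= 2 per group")
    se_a = disp_a if disp_kind == "sem" else disp_a / math.sqrt(n_a)
    se_b = disp_b if disp_kind == "sem" else disp_b / math.sqrt(n_b)
    if se_a <= 0 and se_b <= 0:
        return TTestResult(math.nan, math.nan, math.nan, "welch-summary")
    se2 = se_a ** 2 + se_b ** 2
    t = (mean_a - mean_b) / math.sqrt(se2)
    df = se2 ** 2 / (se_a ** 4 / (n_a - 1) + se_b ** 4 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t, df, p, "welch-summary")


# ---------------------------------------------------------------------------
# localization

@dataclass
class HeatmapGrid:
    """2-D histogram of interaction positions over the arena square."""

    counts: np.ndarray  # (nx, ny), first axis = x bins
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_mm: float
    arena_mask: np.ndarray  # True where the bin centre lies inside the arena

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _event_positions(events) -> np.ndarray:
    return np.array([(e.onset_x_mm, e.onset_y_mm) for e in events],
                    dtype=float).reshape(-1, 2)


def interaction_heatmap(events, arena: ArenaSpec,
                        bin_mm: float | None = None) -> HeatmapGrid:
    """Bin event onset midpoints onto a square grid covering the arena.

    Default grid is 50x50 over the arena bounding square.  Points outside
    the square (tracking artefacts) are clipped into the nearest edge bin
    with a warning; total counts are conserved.
    """
    r = arena.radius
    if bin_mm is None:
        bin_mm = 2.0 * r / 50.0
    if not bin_mm > 0:
        raise ConfigurationError("bin_mm must be > 0")
    nbins = max(1, int(math.ceil(2.0 * r / bin_mm)))
    edges = -r + bin_mm * np.arange(nbins + 1)
    pos = _event_positions(events)
    if pos.size:
        outside = (np.abs(pos) > r).any(axis=1)
        if outside.any():
            logger.warning("%d event positions outside the arena square; "
                           "clipped to edge bins", int(outside.sum()))
        eps = 1e-9
        pos = np.clip(pos, -r + eps, edges[-1] - eps)
    counts, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=(edges, edges))
    centers = (edges[:-1] + edges[1:]) / 2.0
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    mask = np.hypot(cx, cy) <= r
    return HeatmapGrid(counts, edges.copy(), edges.copy(), bin_mm, mask)


def boundary_fraction(events, arena: ArenaSpec,
                      annulus_fraction: float = 0.2) -> tuple[float, float]:
    """Share of event positions in the outer annulus, with uniform baseline.

    Returns (fraction, baseline) where baseline = 1 - (1 - annulus_fraction)^2
    is the annulus' share of the arena area; fraction is NaN for empty input.
    """
    if not 0 < annulus_fraction < 1:
        raise ConfigurationError("annulus_fraction must be in (0, 1)")
    baseline = 1.0 - (1.0 - annulus_fraction) ** 2
    pos = _event_positions(events)
    if pos.shape[0] == 0:
        logger.warning("boundary_fraction of empty event list is undefined")
        return math.nan, baseline
    rad = np.hypot(pos[:, 0], pos[:, 1])
    frac = float(np.mean(rad > (1.0 - annulus_fraction) * arena.radius))
    return frac, baseline


# ---------------------------------------------------------------------------
# end-to-end comparison

@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the end-to-end two-group comparison needs."""

    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    measure_seed: int = 0
    ttest_variant: str = "student"
    significance: float = 0.05
    heatmap_bin_mm: float | None = None
    annulus_fraction: float = 0.2


@dataclass
class VideoResult:
    """Pipeline output for a single video."""

    events: list
    snapshots: list
    vectors: list
    means: dict
    n_excluded: dict


@dataclass
class GroupComparison:
    """Full two-group report: per-measure summaries, t-tests, localization."""

    results: pd.DataFrame
    summaries_a: dict
    summaries_b: dict
    heatmap_a: HeatmapGrid
    heatmap_b: HeatmapGrid
    boundary_a: tuple[float, float]
    boundary_b: tuple[float, float]
    videos_a: list
    videos_b: list
    n_tests: int


def analyze_video(table: TrajectoryTable, config: AnalysisConfig) -> VideoResult:
    """Run detection, snapshot construction and the measure battery on one
    video, then aggregate to the per-video mean vector."""
    fps = table.arena.fps
    events = detect_events(table, config.criteria)
    n_minutes = max(1, int(math.ceil(table.n_frames / (60.0 * fps))))
    snapshots = build_snapshots(events, table.n_flies, fps, n_minutes)
    mcfg = MeasureConfig(seed=config.measure_seed)
    vectors = [measure_suite(s, mcfg) for s in snapshots]
    means, excluded = aggregate_video(vectors)
    acts = per_fly_activity(table)
    means["total_distance"] = float(np.mean([a.total_distance for a in acts]))
    means["mean_velocity"] = float(np.mean([a.mean_velocity for a in acts]))
    return VideoResult(events, snapshots, vectors, means, excluded)


def compare_groups(group_a_tables, group_b_tables,
                   config: AnalysisConfig = AnalysisConfig()) -> GroupComparison:
    """Run the full pipeline on two groups of videos and compare them.

    Raises if either group has fewer than two videos (no dispersion).
    Significance is flagged at ``config.significance`` (default 0.05); no
    multiple-testing correction is applied, but the number of tests
    performed is reported.
    """
    tables_a = list(group_a_tables)
    tables_b = list(group_b_tables)
    for name, tabs in (("group_a", tables_a), ("group_b", tables_b)):
        if len(tabs) < 2:
            raise ValidationError(
                f"{name} has {len(tabs)} video(s); at least 2 are required"
            )

    def run(tabs, label):
        out = []
        for k, t in enumerate(tabs):
            try:
                out.append(analyze_video(t, config))
            except Exception as exc:
                raise type(exc)(f"[{label} video {k}] {exc}") from exc
        return out

    videos_a = run(tables_a, "group_a")
    videos_b = run(tables_b, "group_b")

    measures = MeasureVector.field_names() + ["total_distance", "mean_velocity"]
    rows = []
    summaries_a, summaries_b = {}, {}
    for m in measures:
        va = [v.means[m] for v in videos_a]
        vb = [v.means[m] for v in videos_b]
        sa = aggregate_group(m, va)
        sb = aggregate_group(m, vb)
        summaries_a[m], summaries_b[m] = sa, sb
        if sa.n_videos >= 2 and sb.n_videos >= 2:
            tt = unpaired_ttest(sa.video_means, sb.video_means,
                                config.ttest_variant)
            ts = summary_ttest(sa.mean, sa.sem, sa.n_videos,
                               sb.mean, sb.sem, sb.n_videos, disp_kind="sem")
        else:
            tt = TTestResult(math.nan, math.nan, math.nan,
                             config.ttest_variant)
            ts = tt
        rows.append({
            "measure": m,
            "mean_a": sa.mean, "sd_a": sa.sd, "sem_a": sa.sem,
            "mean_b": sb.mean, "sd_b": sb.sd, "sem_b": sb.sem,
            "n_a": sa.n_videos, "n_b": sb.n_videos,
            "t": tt.t, "df": tt.df, "p": tt.p,
            "t_summary": ts.t,
            "significant": bool(tt.p < config.significance)
            if math.isfinite(tt.p) else False,
        })
    results = pd.DataFrame(rows)

    events_a = [e for v in videos_a for e in v.events]
    events_b = [e for v in videos_b for e in v.events]
    arena = tables_a[0].arena
    comparison = GroupComparison(
        results=results,
        summaries_a=summaries_a,
        summaries_b=summaries_b,
        heatmap_a=interaction_heatmap(events_a, arena, config.heatmap_bin_mm),
        heatmap_b=interaction_heatmap(events_b, arena, config.heatmap_bin_mm),
        boundary_a=boundary_fraction(events_a, arena, config.annulus_fraction),
        boundary_b=boundary_fraction(events_b, arena, config.annulus_fraction),
        videos_a=videos_a,
        videos_b=videos_b,
        n_tests=len(measures),
    )
    logger.info("compared %d measures across %d vs %d videos",
                len(measures), len(tables_a), len(tables_b))
    return comparison
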