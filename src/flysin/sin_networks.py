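"""Per-minute Social Interaction Network snapshots and the SNA measure battery.

A Social Interaction Network (SIN) is a weighted graph G = (V, E) whose
nodes are the flies of one arena (isolates included) and whose edges carry
two weights per ordered pair: the number of interaction events (count) and
their total duration in seconds.  Analysis is temporal: each minute of a
recording yields one snapshot, and every event is assigned wholly to the
snapshot containing its onset frame.

Topological measures (edges, degree, density, efficiency, heterogeneity,
assortativity, transitivity, clustering, betweenness, closeness,
modularity) are computed on the *undirected merged view*, in which a
reciprocal interaction is a single link whose weights are the sums of the
two directed weights; in- and out-strengths use the directed view.
Weighted shortest-path measures use edge length 1/weight (stronger tie =
shorter distance).  Conventions:

* heterogeneity — coefficient of variation (population SD / mean) of the
  undirected degree distribution; 0 when the mean degree is 0.
* assortativity — Pearson correlation of degrees across edge endpoints;
  NaN (flagged, excluded from aggregation) when degenerate, e.g. on
  degree-regular snapshots.
* weighted clustering — geometric-mean (Onnela) local clustering with
  weights normalised by the maximum edge weight.
* closeness — Wasserman–Faust per-component normalisation, isolates 0.
* modularity — Q of the partition found by seeded Louvain; 0 on edgeless
  snapshots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dataclass_fields

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .interaction_detection import validate_events

logger = logging.getLogger(__name__)

WEIGHT_MODES = ("unweighted", "count", "duration")


@dataclass
class SINSnapshot:
    """One minute of interactions as a dual-weighted directed graph."""

    minute: int
    n_flies: int
    edges: pd.DataFrame  # columns: source, target, count, duration_s (directed)

    def _edge_rows(self):
        cols = ["source", "target", "count", "duration_s"]
        return self.edges[cols].to_numpy(dtype=float)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_flies))
        for s, t, c, d in self._edge_rows():
            g.add_edge(int(s), int(t), count=c, duration=d)
        return g

    def to_undirected(self) -> nx.Graph:
        """Merged view: reciprocal edges collapse to one link, weights summed."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_flies))
        for s, t, c, d in self._edge_rows():
            u, v = int(s), int(t)
            if g.has_edge(u, v):
                g[u][v]["count"] += c
                g[u][v]["duration"] += d
            else:
                g.add_edge(u, v, count=c, duration=d)
        return g


def build_snapshots(events, n_flies: int, fps: float,
                    n_minutes: int) -> list[SINSnapshot]:
    """Bin events into per-minute snapshots by onset frame.

    Every event contributes +1 count and +duration_s to its (source,
    target) edge in the snapshot of its onset minute; events are atomic and
    never split across minutes.
    """
    validate_events(events, n_flies)
    frames_per_minute = 60.0 * fps
    buckets: dict[int, dict] = {m: {} for m in range(n_minutes)}
    for e in events:
        m = int(e.start_frame // frames_per_minute)
        if m >= n_minutes:
            raise ConfigurationError(
                f"event onset frame {e.start_frame} beyond {n_minutes} minutes"
            )
        key = (e.source, e.target)
        cnt, dur = buckets[m].get(key, (0, 0.0))
        buckets[m][key] = (cnt + 1, dur + e.duration_s)
    out = []
    for m in range(n_minutes):
        rows = [(s, t, c, d) for (s, t), (c, d) in sorted(buckets[m].items())]
        out.append(SINSnapshot(
            minute=m, n_flies=n_flies,
            edges=pd.DataFrame(rows, columns=["source", "target", "count",
                                              "duration_s"]),
        ))
    return out


@dataclass
class MeasureVector:
    """The full SNA battery for one snapshot; NaN marks undefined entries."""

    total_edges: float = 0.0
    average_degree: float = 0.0
    avg_in_strength_count: float = 0.0
    avg_out_strength_count: float = 0.0
    avg_in_strength_duration: float = 0.0
    avg_out_strength_duration: float = 0.0
    density: float = 0.0
    global_efficiency: float = 0.0
    global_efficiency_count: float = 0.0
    global_efficiency_duration: float = 0.0
    heterogeneity: float = 0.0
    assortativity: float = math.nan
    transitivity: float = 0.0
    avg_clustering: float = 0.0
    avg_clustering_duration: float = 0.0
    avg_betweenness: float = 0.0
    avg_betweenness_count: float = 0.0
    avg_betweenness_duration: float = 0.0
    avg_closeness: float = 0.0
    avg_closeness_count: float = 0.0
    avg_closeness_duration: float = 0.0
    modularity: float = 0.0
    modularity_count: float = 0.0
    modularity_duration: float = 0.0

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclass_fields(cls)]


def _dist_attr(g: nx.Graph, weight: str) -> None:
    for _, _, d in g.edges(data=True):
        d["dist_" + weight] = 1.0 / d[weight]


def _weight_arg(weight_mode: str) -> str | None:
    if weight_mode not in WEIGHT_MODES:
        raise ConfigurationError(
            f"unknown weight_mode {weight_mode!r}; expected one of {WEIGHT_MODES}"
        )
    return None if weight_mode == "unweighted" else weight_mode


def degree_strength_measures(snapshot: SINSnapshot) -> dict:
    """Edge count, mean degree (undirected view) and mean in/out strengths."""
    und = snapshot.to_undirected()
    dg = snapshot.to_digraph()
    n = snapshot.n_flies
    degs = np.array([d for _, d in und.degree()], dtype=float)
    out = {
        "total_edges": float(und.number_of_edges()),
        "average_degree": float(degs.mean()) if n else 0.0,
    }
    for w in ("count", "duration"):
        out[f"avg_in_strength_{w}"] = float(
            np.mean([s for _, s in dg.in_degree(weight=w)])) if n else 0.0
        out[f"avg_out_strength_{w}"] = float(
            np.mean([s for _, s in dg.out_degree(weight=w)])) if n else 0.0
    return out


def _global_efficiency(g: nx.Graph, weight_mode: str) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    if weight_mode == "unweighted":
        lengths = dict(nx.all_pairs_shortest_path_length(g))
    else:
        _dist_attr(g, weight_mode)
        lengths = dict(nx.all_pairs_dijkstra_path_length(
            g, weight="dist_" + weight_mode))
    total = 0.0
    for u, du in lengths.items():
        for v, d in du.items():
            if u != v and d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def connectivity_measures(snapshot: SINSnapshot) -> dict:
    """Density, global efficiency (all weight modes), heterogeneity,
    assortativity."""
    n = snapshot.n_flies
    if n < 2:
        raise ConfigurationError("connectivity measures require >= 2 nodes")
    und = snapshot.to_undirected()
    m = und.number_of_edges()
    degs = np.array([d for _, d in und.degree()], dtype=float)
    mean_deg = degs.mean()
    het = float(np.std(degs) / mean_deg) if mean_deg > 0 else 0.0
    if m >= 2 and np.std(degs) > 0:
        try:
            with np.errstate(invalid="ignore", divide="ignore"):
                assort = float(nx.degree_assortativity_coefficient(und))
        except (ZeroDivisionError, ValueError):
            assort = math.nan
        if not math.isfinite(assort):
            assort = math.nan
    else:
        assort = math.nan
    out = {
        "density": m / (n * (n - 1) / 2.0),
        "heterogeneity": het,
        "assortativity": assort,
        "global_efficiency": _global_efficiency(und, "unweighted"),
        "global_efficiency_count": _global_efficiency(und, "count"),
        "global_efficiency_duration": _global_efficiency(und, "duration"),
    }
    return out


def cohesion_measures(snapshot: SINSnapshot) -> dict:
    """Transitivity and average (unweighted and duration-weighted) clustering."""
    und = snapshot.to_undirected()
    avg_clust = nx.average_clustering(und) if und.number_of_nodes() else 0.0
    avg_clust_dur = (nx.average_clustering(und, weight="duration")
                     if und.number_of_edges() else 0.0)
    return {
        "transitivity": float(nx.transitivity(und)),
        "avg_clustering": float(avg_clust),
        "avg_clustering_duration": float(avg_clust_dur),
    }


def centrality_measures(snapshot: SINSnapshot, weight_mode: str) -> dict:
    """Mean normalised betweenness and mean WF-corrected closeness."""
    warg = _weight_arg(weight_mode)
    und = snapshot.to_undirected()
    if warg is None:
        btw = nx.betweenness_centrality(und, normalized=True)
        cls = nx.closeness_centrality(und, wf_improved=True)
    else:
        _dist_attr(und, warg)
        btw = nx.betweenness_centrality(und, normalized=True,
                                        weight="dist_" + warg)
        cls = nx.closeness_centrality(und, distance="dist_" + warg,
                                      wf_improved=True)
    return {
        "avg_betweenness": float(np.mean(list(btw.values()))),
        "avg_closeness": float(np.mean(list(cls.values()))),
    }


def community_modularity(snapshot: SINSnapshot, weight_mode: str,
                         seed: int = 0) -> float:
    """Modularity Q of the seeded-Louvain partition of the undirected view."""
    warg = _weight_arg(weight_mode)
    und = snapshot.to_undirected()
    if und.number_of_edges() == 0:
        logger.info("snapshot %d has no edges; modularity set to 0",
                    snapshot.minute)
        return 0.0
    parts = nx.community.louvain_communities(und, weight=warg, seed=seed)
    return float(nx.community.modularity(und, parts, weight=warg))


@dataclass(frozen=True)
class MeasureConfig:
    """Options for the measure battery (currently the Louvain seed)."""

    seed: int = 0


def measure_suite(snapshot: SINSnapshot,
                  config: MeasureConfig = MeasureConfig()) -> MeasureVector:
    """Evaluate every measure of the battery on one snapshot."""
    vec = MeasureVector()
    values = degree_strength_measures(snapshot)
    values.update(connectivity_measures(snapshot))
    values.update(cohesion_measures(snapshot))
    for mode in WEIGHT_MODES:
        cent = centrality_measures(snapshot, mode)
        suffix = "" if mode == "unweighted" else "_" + mode
        values["avg_betweenness" + suffix] = cent["avg_betweenness"]
        values["avg_closeness" + suffix] = cent["avg_closeness"]
        values["modularity" + suffix] = community_modularity(
            snapshot, mode, seed=config.seed)
    for k, v in values.items():
        setattr(vec, k, v)
    return vec


def snapshots_to_edgelist(snapshots) -> pd.DataFrame:
    """All snapshots as one flat edge list (minute, source, target, count,
    duration_s) — the CSV export format."""
    parts = []
    for s in snapshots:
        df = s.edges.copy()
        df.insert(0, "minute", s.minute)
        parts.append(df)
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["minute", "source", "target", "count", "duration_s"])


def snapshot_to_graphml(snapshot: SINSnapshot, path) -> None:
    """Export one snapshot (undirected merged view) as GraphML."""
    nx.write_graphml(snapshot.to_undirected(), path)
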