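"""Independent brute-force oracles for graph measures and event detection.

Everything here is deliberately naive: Bellman-style relaxation for
shortest paths, explicit shortest-path counting over the distance matrix,
triple/triangle enumeration, direct evaluation of the modularity formula,
and a per-frame Python scan for interaction events.  These implementations
share no code with the package and exist only to cross-check it.
"""

from __future__ import annotations

import math
from itertools import combinations


# ---------------------------------------------------------------------------
# graphs: represented as (n, edges) with edges = {(u, v): length} undirected,
# u < v, length > 0

def shortest_path_matrix(n, edges):
    inf = math.inf
    d = [[0.0 if i == j else inf for j in range(n)] for i in range(n)]
    for (u, v), w in edges.items():
        d[u][v] = min(d[u][v], w)
        d[v][u] = min(d[v][u], w)
    for _ in range(n):
        changed = False
        for (u, v), w in edges.items():
            for a, b in ((u, v), (v, u)):
                for s in range(n):
                    if d[s][a] + w < d[s][b]:
                        d[s][b] = d[s][a] + w
                        changed = True
        if not changed:
            break
    return d


def global_efficiency(n, edges):
    if n < 2:
        return 0.0
    d = shortest_path_matrix(n, edges)
    total = sum(1.0 / d[i][j] for i in range(n) for j in range(n)
                if i != j and math.isfinite(d[i][j]) and d[i][j] > 0)
    return total / (n * (n - 1))


def _num_shortest_paths(n, edges, d, s):
    """sigma[v] = number of shortest s->v paths (exact edge lengths)."""
    adj = {v: [] for v in range(n)}
    for (u, v), w in edges.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    order = sorted((v for v in range(n) if math.isfinite(d[s][v])),
                   key=lambda v: d[s][v])
    sigma = [0.0] * n
    sigma[s] = 1.0
    for v in order:
        if v == s:
            continue
        sigma[v] = sum(sigma[u] for u, w in adj[v] if d[s][u] + w == d[s][v])
    return sigma


def betweenness(n, edges):
    """Normalized shortest-path betweenness, endpoints excluded."""
    if n < 3:
        return [0.0] * n
    d = shortest_path_matrix(n, edges)
    sigma = {s: _num_shortest_paths(n, edges, d, s) for s in range(n)}
    bc = [0.0] * n
    for s, t in combinations(range(n), 2):
        st = sigma[s][t]
        if st == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if math.isfinite(d[s][v]) and math.isfinite(d[v][t]) \
                    and d[s][v] + d[v][t] == d[s][t]:
                bc[v] += sigma[s][v] * sigma[t][v] / st
    norm = (n - 1) * (n - 2) / 2.0
    return [b / norm for b in bc]


def closeness(n, edges):
    """Wasserman–Faust per-component-normalized closeness; isolates 0."""
    d = shortest_path_matrix(n, edges)
    out = []
    for v in range(n):
        reach = [d[v][u] for u in range(n) if u != v and math.isfinite(d[v][u])]
        nr = len(reach)
        if nr == 0 or sum(reach) == 0:
            out.append(0.0)
            continue
        out.append((nr / sum(reach)) * (nr / (n - 1)))
    return out


def transitivity(n, edges):
    adj = [set() for _ in range(n)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    triangles = 0
    triples = 0
    for v in range(n):
        k = len(adj[v])
        triples += k * (k - 1) // 2
        triangles += sum(1 for a, b in combinations(sorted(adj[v]), 2)
                         if b in adj[a])
    return 3 * (triangles // 3) / triples if triples else 0.0


def clustering(n, edges, weights=None):
    """Per-node local clustering; weighted variant is geometric-mean
    (Onnela) with weights normalized by the graph maximum."""
    adj = [set() for _ in range(n)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    if weights is None:
        out = []
        for v in range(n):
            k = len(adj[v])
            if k < 2:
                out.append(0.0)
                continue
            links = sum(1 for a, b in combinations(sorted(adj[v]), 2)
                        if b in adj[a])
            out.append(2.0 * links / (k * (k - 1)))
        return out
    wmax = max(weights.values())
    wh = {}
    for (u, v), w in weights.items():
        wh[(u, v)] = wh[(v, u)] = w / wmax
    out = []
    for v in range(n):
        k = len(adj[v])
        if k < 2:
            out.append(0.0)
            continue
        s = 0.0
        for a, b in combinations(sorted(adj[v]), 2):
            if b in adj[a]:
                s += (wh[(v, a)] * wh[(v, b)] * wh[(a, b)]) ** (1.0 / 3.0)
        out.append(2.0 * s / (k * (k - 1)))
    return out


def degree_assortativity(n, edges):
    deg = [0] * n
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    xs, ys = [], []
    for u, v in edges:
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    if len(xs) < 2:
        return math.nan
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    if sxx == 0 or syy == 0:
        return math.nan
    return sxy / math.sqrt(sxx * syy)


def modularity(n, edges, partition, weights=None):
    """Direct Q = sum_c [ W_c/W - (S_c/2W)^2 ] over communities."""
    if weights is None:
        weights = {e: 1.0 for e in edges}
    two_w = 2.0 * sum(weights.values())
    if two_w == 0:
        return 0.0
    comm = {}
    for c, nodes in enumerate(partition):
        for v in nodes:
            comm[v] = c
    strength = [0.0] * n
    for (u, v), w in weights.items():
        strength[u] += w
        strength[v] += w
    q = 0.0
    for c, nodes in enumerate(partition):
        w_in = sum(w for (u, v), w in weights.items()
                   if comm[u] == c and comm[v] == c)
        s_c = sum(strength[v] for v in nodes)
        q += 2.0 * w_in / two_w - (s_c / two_w) ** 2
    return q


# ---------------------------------------------------------------------------
# interaction events: exhaustive frame scan on a two-or-more-fly table

def detect_events_bruteforce(table, criteria):
    """Frame-by-frame scan enumerating all engaged runs.

    Returns a sorted list of (source, target, start_frame, end_frame)
    tuples, mirroring the package's event semantics (symmetric or directed,
    gap bridging, inclusive/exclusive minimum duration).
    """
    df = table.data
    fps = table.arena.fps
    ids = sorted(df["fly_id"].unique())
    bl = df.groupby("fly_id")["body_length_mm"].mean().to_dict()
    state = {}
    for row in df.itertuples(index=False):
        state[(int(row.fly_id), int(row.frame))] = (
            row.x_mm, row.y_mm, row.heading_deg)
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0

    def engaged_directed(i, j, f):
        if (i, f) not in state or (j, f) not in state:
            return False
        xi, yi, hi = state[(i, f)]
        xj, yj, _ = state[(j, f)]
        dx, dy = xj - xi, yj - yi
        dist = math.hypot(dx, dy)
        if dist > criteria.distance_bl * bl[i]:
            return False
        hx, hy = math.cos(math.radians(hi)), math.sin(math.radians(hi))
        ang = math.degrees(math.atan2(abs(hx * dy - hy * dx),
                                      hx * dx + hy * dy))
        return ang < criteria.max_angle_deg

    min_frames = math.ceil(criteria.min_duration_s * fps)

    def scan(engaged_at):
        frames = [f for f in range(n_frames) if engaged_at(f)]
        runs = []
        for f in frames:
            if runs and f - runs[-1][1] <= criteria.gap_bridge_frames + 1:
                runs[-1][1] = f
            else:
                runs.append([f, f])
        keep = []
        for a, b in runs:
            length = b - a + 1
            ok = (length >= min_frames if criteria.min_duration_inclusive
                  else length > min_frames)
            if ok:
                keep.append((a, b))
        return keep

    events = []
    if criteria.symmetric:
        for i, j in combinations(ids, 2):
            for a, b in scan(lambda f: engaged_directed(i, j, f)
                             or engaged_directed(j, i, f)):
                events.append((i, j, a, b))
                events.append((j, i, a, b))
    else:
        for i in ids:
            for j in ids:
                if i == j:
                    continue
                for a, b in scan(lambda f: engaged_directed(i, j, f)):
                    events.append((i, j, a, b))
    return sorted(events)
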