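"""Node and global statistics of the health network.

Conventions match the published node-metric table of the study design this
package targets:

* path-based metrics (closeness, harmonic closeness, betweenness,
  diameter, average path length) use **unweighted** topology — the
  retained edges count as unit distances regardless of the magnitude of
  the partial correlation;
* closeness is the Gephi form ``(n - 1) / sum(d)`` over reachable
  targets, 0 for isolated nodes;
* harmonic closeness averages reciprocal distances with ``1/inf = 0`` for
  unreachable pairs;
* betweenness is the raw (unnormalised) Brandes count over unordered
  pairs, with fractional credit when shortest paths tie;
* eigenvector centrality is the leading eigenvector of the
  absolute-weight adjacency, rescaled so the maximum score is 1;
* HITS hub/authority scores are the same leading eigenvector under L2
  normalisation — on an undirected graph hub equals authority entrywise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from collections import deque
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .network import HealthNetwork, potential_edge_count

_UNREACHABLE = -1

#: Column order of the node-metrics report.
NODE_METRIC_COLUMNS = [
    "ID", "ClosenessCentrality", "HarmonicClosenessCentrality",
    "BetweennessCentrality", "Authority", "HUB", "Modularity",
    "Clustering.Coefficient", "NumberTriangles", "EigenvectorCentrality",
]


@dataclass
class GlobalMetrics:
    """Whole-network summary statistics."""

    edge_count: int
    density: float
    diameter: int
    avg_path_length: float
    avg_clustering: float
    modularity_q: float
    connected: bool

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


# ---------------------------------------------------------------------------
# distances

def _bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, _UNREACHABLE, dtype=int)
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in np.flatnonzero(adj[u]):
            if dist[v] == _UNREACHABLE:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def distance_matrix(graph: HealthNetwork) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (-1 = unreachable)."""
    adj = graph.adjacency
    return np.vstack([_bfs_distances(adj, s) for s in range(graph.n_nodes)])


def path_stats(graph: HealthNetwork) -> tuple[int, float, bool]:
    """(diameter, average path length, connected flag).

    The average runs over ordered connected pairs; the diameter is the
    maximum eccentricity within the largest connected component, so both
    are well defined on disconnected graphs (the flag records whether any
    pair was excluded).
    """
    if graph.n_nodes < 2:
        raise ValueError("path statistics need at least two nodes")
    dist = distance_matrix(graph)
    off = ~np.eye(graph.n_nodes, dtype=bool)
    reachable = (dist > 0) & off
    connected = bool(reachable.sum() == off.sum())
    if not reachable.any():
        return 0, 0.0, connected
    avg = float(dist[reachable].mean())
    diameter = int(dist[reachable].max())
    return diameter, avg, connected


def density(graph: HealthNetwork) -> float:
    """Edges divided by potential edges (1.0 for a complete graph)."""
    n = graph.n_nodes
    if n < 2:
        return 0.0
    return graph.n_edges / potential_edge_count(n)


# ---------------------------------------------------------------------------
# centrality

def closeness(graph: HealthNetwork, node: int) -> float:
    """Gephi-style closeness: (n - 1) / sum of distances to reachable nodes."""
    dist = _bfs_distances(graph.adjacency, node)
    reach = dist > 0
    if not reach.any():
        return 0.0
    return (graph.n_nodes - 1) / float(dist[reach].sum())


def harmonic_closeness(graph: HealthNetwork, node: int) -> float:
    """Mean reciprocal distance, unreachable nodes contributing zero."""
    dist = _bfs_distances(graph.adjacency, node)
    reach = dist > 0
    if graph.n_nodes < 2:
        return 0.0
    return float(np.sum(1.0 / dist[reach])) / (graph.n_nodes - 1)


def betweenness(graph: HealthNetwork) -> np.ndarray:
    """Raw Brandes betweenness for every node (unordered pairs).

    Shortest-path ties share credit fractionally. Endpoints are excluded.
    """
    adj = graph.adjacency
    n = graph.n_nodes
    bc = np.zeros(n)
    for s in range(n):
        # single-source shortest-path DAG
        stack: list[int] = []
        pred: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, _UNREACHABLE)
        dist[s] = 0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for v in np.flatnonzero(adj[u]):
                if dist[v] == _UNREACHABLE:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    pred[v].append(u)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for u in pred[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair was counted from both endpoints


def _power_iteration(mat: np.ndarray, tol: float = 1e-10,
                     max_iter: int = 100_000) -> np.ndarray:
    """Leading eigenvector of a symmetric non-negative matrix.

    A unit diagonal shift removes the period-2 oscillation that plain
    power iteration exhibits on bipartite graphs without changing the
    eigenvectors.
    """
    n = mat.shape[0]
    shifted = mat + np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return x
        y /= norm
        if np.linalg.norm(y - x) < tol:
            return y
        x = y
    raise RuntimeError(f"power iteration failed to converge in {max_iter} steps")


def eigenvector_centrality(graph: HealthNetwork,
                           weighted: bool = True) -> np.ndarray:
    """Leading-eigenvector scores, max-normalised to 1.

    Uses the absolute edge weights by default (non-negativity is required
    for the Perron–Frobenius leading eigenvector to be meaningful);
    ``weighted=False`` switches to unit weights.
    """
    if graph.n_edges == 0:
        raise ValueError("eigenvector centrality needs at least one edge")
    mat = np.abs(graph.weights) if weighted else graph.adjacency.astype(float)
    v = _power_iteration(mat)
    v = np.abs(v)
    return v / v.max()


def hits(graph: HealthNetwork, weighted: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """HITS hub and authority scores (equal on undirected graphs).

    On a symmetric adjacency the HITS fixed point is the Perron
    eigenvector of the matrix itself, L2-normalised, so hub and authority
    coincide entrywise; computing it directly avoids the degenerate
    dominant eigenspace that A^T A = A^2 has on bipartite components.
    """
    if graph.n_edges == 0:
        raise ValueError("HITS needs at least one edge")
    mat = np.abs(graph.weights) if weighted else graph.adjacency.astype(float)
    v = np.abs(_power_iteration(mat))
    v /= np.linalg.norm(v)
    return v, v.copy()


def hits_matrix(adjacency: np.ndarray, tol: float = 1e-12,
                max_iter: int = 100_000) -> tuple[np.ndarray, np.ndarray]:
    """HITS on an arbitrary (possibly directed) non-negative adjacency.

    Authority scores are the leading eigenvector of A^T A, hubs of A A^T,
    both L2-normalised.
    """
    a = np.asarray(adjacency, dtype=float)
    auth = _power_iteration(a.T @ a, tol=tol, max_iter=max_iter)
    auth = np.abs(auth)
    auth /= np.linalg.norm(auth)
    hub = a @ auth
    norm = np.linalg.norm(hub)
    if norm > 0:
        hub /= norm
    else:
        hub = _power_iteration(a @ a.T, tol=tol, max_iter=max_iter)
        hub = np.abs(hub) / np.linalg.norm(hub)
    return hub, auth


# ---------------------------------------------------------------------------
# clustering

def local_clustering(graph: HealthNetwork, node: int) -> tuple[float, int]:
    """(local clustering coefficient, triangle count) of one node.

    ``T`` is the number of edges among the node's neighbours; the
    coefficient is ``2T / (k(k-1))`` for degree k >= 2 and 0 otherwise.
    """
    nbrs = graph.neighbors(node)
    k = len(nbrs)
    if k < 2:
        return 0.0, 0
    sub = graph.adjacency[np.ix_(nbrs, nbrs)]
    t = int(np.count_nonzero(np.triu(sub, k=1)))
    return 2.0 * t / (k * (k - 1)), t


def avg_clustering(graph: HealthNetwork) -> float:
    """Mean local clustering coefficient over all nodes."""
    return float(np.mean([
        local_clustering(graph, v)[0] for v in range(graph.n_nodes)
    ]))


# ---------------------------------------------------------------------------
# assembly

def node_metrics(graph: HealthNetwork,
                 partition: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-node metrics table, one row per node in label order.

    ``partition`` maps node label to community id and fills the
    "Modularity" column (0 for every node when omitted). On an edgeless
    graph the eigenvector/HITS columns are 0 by convention.
    """
    n = graph.n_nodes
    if partition is None:
        partition = {lab: 0 for lab in graph.labels}
    missing = [lab for lab in graph.labels if lab not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes {missing}")
    if graph.n_edges > 0:
        eig = eigenvector_centrality(graph)
        hub, auth = hits(graph)
        btw = betweenness(graph)
    else:
        eig = np.zeros(n)
        hub = auth = np.zeros(n)
        btw = np.zeros(n)
    rows = []
    for v, lab in enumerate(graph.labels):
        coef, tri = local_clustering(graph, v)
        rows.append({
            "ID": lab,
            "ClosenessCentrality": closeness(graph, v),
            "HarmonicClosenessCentrality": harmonic_closeness(graph, v),
            "BetweennessCentrality": btw[v],
            "Authority": auth[v],
            "HUB": hub[v],
            "Modularity": int(partition[lab]),
            "Clustering.Coefficient": coef,
            "NumberTriangles": tri,
            "EigenvectorCentrality": eig[v],
        })
    return pd.DataFrame(rows, columns=NODE_METRIC_COLUMNS)


def global_metrics(graph: HealthNetwork, modularity_q: float) -> GlobalMetrics:
    """Assemble the whole-network summary (modularity supplied by caller)."""
    diameter, avg_path, connected = path_stats(graph)
    return GlobalMetrics(
        edge_count=graph.n_edges,
        density=density(graph),
        diameter=diameter,
        avg_path_length=avg_path,
        avg_clustering=avg_clustering(graph),
        modularity_q=modularity_q,
        connected=connected,
    )
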