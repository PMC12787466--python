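"""Shared fixtures: random graph factories and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pcornet.network import HealthNetwork

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

# --------------------------------------------------------------------------
# graph factories


def random_network(rng: np.random.Generator, n: int,
                   p_edge: float = 0.4, signed: bool = True) -> HealthNetwork:
    """Erdos–Renyi style random weighted network for oracle comparisons."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                weight = rng.uniform(0.1, 1.0)
                if signed and rng.random() < 0.5:
                    weight = -weight
                w[i, j] = w[j, i] = weight
    labels = [f"v{i}" for i in range(n)]
    return HealthNetwork(labels=labels, weights=w,
                         pvalues=np.full((n, n), np.nan))


def star_network(n: int) -> HealthNetwork:
    """Star graph: node 0 is the hub, 1..n-1 are leaves (unit weights)."""
    labels = [f"v{i}" for i in range(n)]
    return HealthNetwork.from_edges(
        labels, [(labels[0], labels[i]) for i in range(1, n)]
    )


def complete_network(n: int) -> HealthNetwork:
    labels = [f"v{i}" for i in range(n)]
    edges = [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)]
    return HealthNetwork.from_edges(labels, edges)


def table1_style_network() -> HealthNetwork:
    """17-node graph whose node "v0" has 9 direct neighbours with 12 edges
    among them and all 7 remaining nodes at distance exactly 2.

    This configuration reproduces the published stress-node row of the
    node-metrics table: closeness 16/23, harmonic closeness 12.5/16,
    clustering coefficient 24/72.
    """
    labels = [f"v{i}" for i in range(17)]
    edges = [("v0", f"v{i}") for i in range(1, 10)]
    edges += [(f"v{i}", "v1") for i in range(10, 17)]  # distance 2 from v0
    # 12 edges among the 9 neighbours of v0
    nbr_pairs = [(1, 2), (1, 3), (2, 3), (4, 5), (4, 6), (5, 6),
                 (7, 8), (7, 9), (8, 9), (2, 4), (5, 7), (3, 9)]
    edges += [(f"v{a}", f"v{b}") for a, b in nbr_pairs]
    return HealthNetwork.from_edges(labels, edges)


# --------------------------------------------------------------------------
# independent oracles


def residual_pcor_oracle(x: np.ndarray) -> np.ndarray:
    """Partial correlations by explicit regress-out-and-correlate."""
    n, p = x.shape
    rp = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [c for c in range(p) if c not in (i, j)]
            design = np.column_stack([np.ones(n), x[:, others]])
            ri = x[:, i] - design @ np.linalg.lstsq(design, x[:, i], rcond=None)[0]
            rj = x[:, j] - design @ np.linalg.lstsq(design, x[:, j], rcond=None)[0]
            rp[i, j] = rp[j, i] = np.corrcoef(ri, rj)[0, 1]
    return rp


def pvalue_quadrature_oracle(r: float, n: int, k: int) -> float:
    """Two-sided p by numerically integrating the t density."""
    from scipy.integrate import quad

    df = n - k - 2
    t_obs = abs(r) * math.sqrt(df / (1.0 - r * r))

    def t_pdf(t: float) -> float:
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + t * t / df) ** (-(df + 1) / 2)

    tail, _err = quad(t_pdf, t_obs, np.inf)
    return 2.0 * tail


def distance_oracle(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by boolean matrix powers."""
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=int)
    np.fill_diagonal(dist, 0)
    reach = np.eye(n, dtype=bool)
    frontier = adj.astype(bool)
    for d in range(1, n):
        newly = frontier & ~reach
        dist[newly & (dist == -1)] = d
        reach |= frontier
        frontier = (frontier @ adj.astype(bool)) | frontier
        if reach.all():
            break
    return dist


def betweenness_enumeration_oracle(net: HealthNetwork) -> np.ndarray:
    """Raw betweenness by exhaustively enumerating all shortest paths."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    for i, j, _w, _p in net.edges():
        g.add_edge(i, j)
    scores = np.zeros(net.n_nodes)
    for s in range(net.n_nodes):
        for t in range(s + 1, net.n_nodes):
            if s == t or not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for path in paths:
                for v in path[1:-1]:
                    scores[v] += 1.0 / len(paths)
    return scores


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for idx in range(len(partition)):
            yield partition[:idx] + [[first] + partition[idx]] + partition[idx + 1:]
        yield [[first]] + partition


def modularity_direct_oracle(net: HealthNetwork,
                             groups: list[list[int]]) -> float:
    """Q by the per-community direct formula on absolute weights."""
    w = np.abs(net.weights)
    m = np.triu(w, k=1).sum()
    degrees = w.sum(axis=1)
    q = 0.0
    for group in groups:
        idx = np.array(group)
        within = np.triu(w[np.ix_(idx, idx)], k=1).sum()
        q += within / m - (degrees[idx].sum() / (2 * m)) ** 2
    return q


@pytest.fixture
def table1_metrics() -> pd.DataFrame:
    """The published node-metrics table, entered verbatim as a fixture."""
    rows = [
        ("Sex", 0.5926, 0.6979, 6.6262, 0.2829, 0.2829, 3, 0.3810, 8, 0.7852),
        ("Age", 0.5000, 0.5833, 1.5056, 0.1632, 0.1632, 3, 0.5000, 3, 0.4526),
        ("Marital", 0.5333, 0.6458, 4.4500, 0.2141, 0.2141, 3, 0.4000, 6, 0.5945),
        ("Social", 0.5517, 0.6354, 2.7444, 0.2161, 0.2161, 3, 0.3000, 3, 0.6008),
        ("BMI", 0.5926, 0.6771, 8.1968, 0.2434, 0.2434, 3, 0.2667, 4, 0.6811),
        ("HTN", 0.6667, 0.7500, 12.8881, 0.3399, 0.3399, 3, 0.3929, 11, 0.9491),
        ("Glucose", 0.5926, 0.6771, 7.3889, 0.2336, 0.2336, 2, 0.4667, 7, 0.6604),
        ("Insulin", 0.4571, 0.5521, 0.3333, 0.1237, 0.1237, 2, 0.8333, 5, 0.3578),
        ("CholesT", 0.6154, 0.7083, 8.8746, 0.2521, 0.2521, 1, 0.4762, 10, 0.7153),
        ("TAG", 0.4848, 0.5729, 1.3111, 0.1382, 0.1382, 1, 0.6667, 4, 0.3961),
        ("HOMA", 0.5333, 0.6250, 5.2429, 0.1606, 0.1606, 2, 0.5000, 5, 0.4608),
        ("Depre", 0.5000, 0.5833, 1.6500, 0.1587, 0.1587, 3, 0.3333, 2, 0.4406),
        ("Anxiety", 0.5926, 0.6771, 4.2667, 0.2658, 0.2658, 3, 0.4667, 7, 0.7377),
        ("Stress", 0.6957, 0.7813, 17.3468, 0.3589, 0.3589, 3, 0.3333, 12, 1.0000),
        ("NP1", 0.6667, 0.7500, 7.9389, 0.3429, 0.3429, 3, 0.4286, 12, 0.9536),
        ("NP2", 0.6400, 0.7188, 12.8690, 0.2710, 0.2710, 3, 0.2857, 6, 0.7552),
        ("NP3", 0.5161, 0.5938, 1.3667, 0.1792, 0.1792, 3, 0.5000, 3, 0.4965),
    ]
    columns = ["ID", "ClosenessCentrality", "HarmonicClosenessCentrality",
               "BetweennessCentrality", "Authority", "HUB", "Modularity",
               "Clustering.Coefficient", "NumberTriangles",
               "EigenvectorCentrality"]
    return pd.DataFrame(rows, columns=columns)
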