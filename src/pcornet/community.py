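"""Modularity scoring and Louvain community detection.

Communities are scored with Newman–Girvan modularity on the absolute
edge weights (signed-modularity variants are out of scope; a negative
partial correlation still marks a conditional dependence, and it is the
magnitude that binds nodes into modules here):

    Q = sum_c [ W_c / m  -  (S_c / 2m)^2 ]

with W_c the total within-community weight, S_c the community's total
(weighted) degree, and m the total edge weight. Louvain greedily
maximises Q by local node moves followed by graph aggregation, repeated
until no move improves Q; node visiting order is shuffled from a seed so
runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import HealthNetwork

_MIN_GAIN = 1e-10


@dataclass
class CommunityPartition:
    """A node-to-community assignment with its modularity score."""

    assignment: dict[str, int]
    q: float
    resolution: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lab, cid in self.assignment.items():
            out.setdefault(cid, []).append(lab)
        return out

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            {"node": list(self.assignment), "community": list(self.assignment.values())}
        )
        frame.to_csv(path, index=False)


def _abs_weight_matrix(graph: HealthNetwork) -> np.ndarray:
    return np.abs(np.asarray(graph.weights, dtype=float))


def modularity_q(graph: HealthNetwork, assignment: dict[str, int],
                 resolution: float = 1.0) -> float:
    """Modularity Q of a total assignment, on absolute edge weights."""
    missing = [lab for lab in graph.labels if lab not in assignment]
    if missing:
        raise ValueError(f"assignment does not cover nodes {missing}")
    w = _abs_weight_matrix(graph)
    two_m = w.sum()
    if two_m == 0:
        raise ValueError("modularity is undefined for a graph with no edges")
    comm = np.array([assignment[lab] for lab in graph.labels])
    same = comm[:, None] == comm[None, :]
    degrees = w.sum(axis=1)
    q_edges = w[same].sum() / two_m
    q_degrees = sum(
        (degrees[comm == c].sum() / two_m) ** 2 for c in np.unique(comm)
    )
    return float(q_edges - resolution * q_degrees)


def _one_level(w: np.ndarray, resolution: float,
               rng: np.random.Generator) -> np.ndarray | None:
    """One Louvain local-moving phase; returns community array or None if
    no node moved. ``w`` is symmetric with doubled self-loop diagonal."""
    n = w.shape[0]
    comm = np.arange(n)
    k = w.sum(axis=1)
    two_m = k.sum()
    sigma_tot = k.copy()
    improved_any = False
    moved = True
    while moved:
        moved = False
        order = rng.permutation(n)
        for i in order:
            ci = comm[i]
            # weights from i to each community (excluding the self term)
            links = np.zeros(n)
            for j in np.flatnonzero(w[i]):
                if j != i:
                    links[comm[j]] += w[i, j]
            sigma_tot[ci] -= k[i]
            comm[i] = -1
            # gain of joining community c: links[c] - gamma * k_i * sigma_c / 2m
            candidates = np.flatnonzero(links)
            best_c, best_gain = ci, links[ci] - resolution * k[i] * sigma_tot[ci] / two_m
            for c in candidates:
                if c == ci:
                    continue
                gain = links[c] - resolution * k[i] * sigma_tot[c] / two_m
                if gain > best_gain + _MIN_GAIN:
                    best_gain, best_c = gain, c
            comm[i] = best_c
            sigma_tot[best_c] += k[i]
            if best_c != ci:
                moved = True
                improved_any = True
    return comm if improved_any else None


def _aggregate(w: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse communities into super-nodes; returns (new weights, relabel)."""
    ids, relabel = np.unique(comm, return_inverse=True)
    nc = len(ids)
    new_w = np.zeros((nc, nc))
    for a in range(w.shape[0]):
        for b in range(w.shape[0]):
            new_w[relabel[a], relabel[b]] += w[a, b]
    return new_w, relabel


def louvain(graph: HealthNetwork, resolution: float = 1.0,
            seed: int = 0) -> CommunityPartition:
    """Two-phase Louvain modularity maximisation, deterministic per seed.

    Community ids in the result are renumbered by descending size (ties
    broken by the smallest member index in label order).
    """
    if graph.n_edges == 0:
        raise ValueError("community detection needs at least one edge")
    w = _abs_weight_matrix(graph)
    n = graph.n_nodes
    rng = np.random.default_rng(seed)
    membership = np.arange(n)  # original node -> current super-node
    while True:
        comm = _one_level(w, resolution, rng)
        if comm is None:
            break
        w, relabel = _aggregate(w, comm)
        membership = relabel[membership]

    # renumber by descending community size, stable in label order
    sizes: dict[int, int] = {}
    first_member: dict[int, int] = {}
    for idx, c in enumerate(membership):
        sizes[c] = sizes.get(c, 0) + 1
        first_member.setdefault(c, idx)
    ordered = sorted(sizes, key=lambda c: (-sizes[c], first_member[c]))
    renumber = {c: new for new, c in enumerate(ordered)}
    assignment = {
        lab: renumber[membership[i]] for i, lab in enumerate(graph.labels)
    }
    q = modularity_q(graph, assignment, resolution=resolution)
    return CommunityPartition(assignment=assignment, q=q,
                              resolution=resolution, seed=seed)
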