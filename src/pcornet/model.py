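"""Model/Results interface for the health-variable network analysis.

:class:`HealthNetworkModel` wraps a cohort table; :meth:`fit` estimates
the partial-correlation matrix, prunes it with the p-value screen,
detects communities and assembles node and global metrics into a
:class:`NetworkResults` object with a printable :meth:`~NetworkResults.summary`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .cohort import CohortTable, GeneratorConfig, generate_cohort
from .community import CommunityPartition, louvain
from .network import HealthNetwork, select_edges
from .pcor import PcorResult, partial_correlations

#: Default liberal significance screen for retaining edges.
DEFAULT_ALPHA = 0.25


class HealthNetworkModel:
    """Partial-correlation network model of a mixed-type cohort.

    Parameters
    ----------
    data : CohortTable, DataFrame or (n, p) array
        The cohort; categorical variables enter as numeric codes.
    alpha : float
        Edge-retention threshold: pairs with partial-correlation p-value
        strictly below ``alpha`` become edges.

    Examples
    --------
    >>> from pcornet import GeneratorConfig, generate_cohort
    >>> model = HealthNetworkModel.simulate(GeneratorConfig(n=188, seed=7))
    >>> res = model.fit(seed=7)
    >>> res.global_metrics.edge_count  # doctest: +SKIP
    """

    def __init__(self, data, alpha: float = DEFAULT_ALPHA):
        if not 0 < alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {alpha}")
        self.data = data
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       alpha: float = DEFAULT_ALPHA) -> "HealthNetworkModel":
        return cls(frame, alpha=alpha)

    @classmethod
    def from_csv(cls, path: str | Path,
                 alpha: float = DEFAULT_ALPHA) -> "HealthNetworkModel":
        return cls(CohortTable.from_csv(path), alpha=alpha)

    @classmethod
    def simulate(cls, config: GeneratorConfig,
                 alpha: float = DEFAULT_ALPHA) -> "HealthNetworkModel":
        """Build the model on a synthetic cohort drawn from ``config``."""
        return cls(generate_cohort(config), alpha=alpha)

    def fit(self, seed: int = 0, resolution: float = 1.0) -> "NetworkResults":
        """Estimate the network and all derived statistics.

        ``seed`` controls the Louvain node-visiting order (the only
        stochastic step of the fit); identical data, alpha and seed give
        identical results.
        """
        pcor = partial_correlations(self.data)
        network = select_edges(pcor, alpha=self.alpha)
        if network.n_edges > 0:
            partition = louvain(network, resolution=resolution, seed=seed)
            q = partition.q
        else:
            partition = CommunityPartition(
                assignment={lab: 0 for lab in network.labels},
                q=float("nan"), resolution=resolution, seed=seed)
            q = float("nan")
        node_table = _metrics.node_metrics(network, partition.assignment)
        global_stats = _metrics.global_metrics(network, q)
        return NetworkResults(
            model=self, pcor=pcor, network=network, partition=partition,
            node_metrics=node_table, global_metrics=global_stats,
        )


@dataclass
class NetworkResults:
    """Fitted network with node metrics, communities and global summary."""

    model: HealthNetworkModel
    pcor: PcorResult
    network: HealthNetwork
    partition: CommunityPartition
    node_metrics: pd.DataFrame
    global_metrics: _metrics.GlobalMetrics

    def rank_nodes(self, metric: str) -> pd.DataFrame:
        """Nodes sorted by one metric column, descending (ties keep label order)."""
        if metric not in self.node_metrics.columns:
            raise KeyError(f"unknown metric column {metric!r}")
        return self.node_metrics.sort_values(
            metric, ascending=False, kind="stable"
        )[["ID", metric]].reset_index(drop=True)

    def summary(self, decimals: int = 4) -> str:
        """Human-readable fit report (global stats plus the node table)."""
        g = self.global_metrics
        lines = [
            "Partial-correlation health network",
            "=" * 64,
            f"Observations:        {self.pcor.n}",
            f"Variables (nodes):   {self.pcor.p}",
            f"Conditioning size k: {self.pcor.k}"
            f"   (t-test df = {self.pcor.n - self.pcor.k - 2})",
            f"Edge screen:         p < {self.model.alpha} (no correction)",
            f"Edges retained:      {g.edge_count}",
            f"Density:             {g.density:.{decimals}f}",
            f"Diameter:            {g.diameter}",
            f"Avg path length:     {g.avg_path_length:.{decimals}f}",
            f"Avg clustering:      {g.avg_clustering:.{decimals}f}",
            f"Modularity Q:        {g.modularity_q:.{decimals}f}"
            f"   ({self.partition.n_communities} communities)",
            f"Connected:           {g.connected}",
            "-" * 64,
            self.node_metrics.round(decimals).to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path, decimals: int = 4) -> dict[str, Path]:
        """Write all standard artifacts into ``outdir``; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "rp": outdir / "rp.csv",
            "pvals": outdir / "pvals.csv",
            "edges": outdir / "edges.csv",
            "gexf": outdir / "network.gexf",
            "graphml": outdir / "network.graphml",
            "node_metrics": outdir / "node_metrics.csv",
            "global_metrics": outdir / "global_metrics.json",
            "partition": outdir / "partition.csv",
        }
        self.pcor.to_csv(paths["rp"], paths["pvals"])
        self.network.to_edge_csv(paths["edges"])
        self.network.to_gexf(paths["gexf"])
        self.network.to_graphml(paths["graphml"])
        rounded = self.node_metrics.copy()
        float_cols = rounded.select_dtypes(float).columns
        rounded[float_cols] = rounded[float_cols].round(decimals)
        rounded.to_csv(paths["node_metrics"], index=False,
                       float_format=f"%.{decimals}f")
        self.global_metrics.to_json(paths["global_metrics"])
        self.partition.to_csv(paths["partition"])
        return paths

    def plot_network(self, ax=None):
        """Basic spring-layout drawing (matplotlib); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(7, 7))
        pos = _spring_layout(self.network)
        for i, j, w, _p in self.network.edges():
            xs = [pos[i][0], pos[j][0]]
            ys = [pos[i][1], pos[j][1]]
            ax.plot(xs, ys, color="tab:blue" if w > 0 else "peru",
                    linewidth=0.5 + 4 * abs(w), alpha=0.7, zorder=1)
        colors = {"sociodemographic": "orange", "nutritional": "pink",
                  "physical": "green", "psychological": "yellowgreen",
                  "other": "grey"}
        for i, lab in enumerate(self.network.labels):
            dim = self.network.dimensions.get(lab, "other")
            ax.scatter(*pos[i], s=300, color=colors[dim], zorder=2,
                       edgecolors="black")
            ax.annotate(lab, pos[i], ha="center", va="center", fontsize=7,
                        zorder=3)
        ax.set_axis_off()
        return ax


def _spring_layout(network: HealthNetwork, iterations: int = 200,
                   seed: int = 0) -> np.ndarray:
    """Small deterministic Fruchterman–Reingold layout for plotting."""
    n = network.n_nodes
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1, 1, size=(n, 2))
    k = 1.0 / np.sqrt(n)
    adj = network.adjacency.astype(float)
    t = 0.1
    for _ in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        repulse = k**2 / dist**2
        attract = adj * dist / k
        force = ((repulse - attract)[:, :, None] * delta / dist[:, :, None]).sum(axis=1)
        length = np.linalg.norm(force, axis=1, keepdims=True)
        length[length == 0] = 1.0
        pos += force / length * min(t, 1.0)
        t *= 0.98
    return pos
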