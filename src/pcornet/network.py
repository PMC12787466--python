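"""Edge selection and the signed, weighted health network.

The full 17-variable partial-correlation matrix defines a complete graph
of 136 candidate edges; the analyzed network keeps only pairs whose
partial correlation is significant at a deliberately liberal screen
(p < 0.25, strict), without multiple-testing correction. Isolated nodes
stay in the graph so that every variable receives node-level metrics.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pcor import PcorResult
from .schema import DIMENSIONS


def potential_edge_count(n_nodes: int) -> int:
    """Number of unordered pairs among ``n_nodes`` (complete simple graph)."""
    if n_nodes < 1:
        raise ValueError(f"need at least one node, got {n_nodes}")
    return n_nodes * (n_nodes - 1) // 2


@dataclass
class HealthNetwork:
    """Undirected simple graph; nodes = variables, weights = selected Rp.

    ``weights[i, j]`` holds the signed partial correlation of a retained
    edge and 0 where no edge was retained; ``pvalues`` holds the matching
    p-value (NaN off-edges). ``dimensions`` tags each node with its
    measurement dimension for export.
    """

    labels: list[str]
    weights: np.ndarray
    pvalues: np.ndarray
    dimensions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.labels), len(self.labels)):
            raise ValueError("weight matrix shape does not match labels")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed")
        if not self.dimensions:
            self.dimensions = {
                lab: DIMENSIONS.get(lab, "other") for lab in self.labels
            }

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean adjacency (unweighted topology)."""
        return self.weights != 0

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def degree(self, i: int | None = None):
        deg = self.adjacency.sum(axis=1)
        return int(deg[i]) if i is not None else deg.astype(int)

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def edges(self) -> list[tuple[int, int, float, float]]:
        """Sorted list of (i, j, weight, p) with i < j."""
        out = []
        for i, j in zip(*np.where(np.triu(self.adjacency, k=1))):
            out.append((int(i), int(j), float(self.weights[i, j]),
                        float(self.pvalues[i, j])))
        return out

    @classmethod
    def from_edges(cls, labels: list[str],
                   edges: list[tuple], **kwargs) -> "HealthNetwork":
        """Build from (label_i, label_j[, weight[, p]]) tuples; unit weights
        by default (convenient for tests and toy graphs)."""
        p = len(labels)
        w = np.zeros((p, p))
        pv = np.full((p, p), np.nan)
        idx = {lab: i for i, lab in enumerate(labels)}
        for e in edges:
            i, j = idx[e[0]], idx[e[1]]
            weight = float(e[2]) if len(e) > 2 else 1.0
            pval = float(e[3]) if len(e) > 3 else np.nan
            w[i, j] = w[j, i] = weight
            pv[i, j] = pv[j, i] = pval
        return cls(labels=list(labels), weights=w, pvalues=pv, **kwargs)

    # -- export ------------------------------------------------------------
    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": self.labels[i],
                "target": self.labels[j],
                "weight": w,
                "p": p,
                "sign": "positive" if w > 0 else "negative",
            }
            for i, j, w, p in self.edges()
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "weight", "p", "sign"]
        )

    def to_edge_csv(self, path: str | Path) -> None:
        self.edge_frame().to_csv(path, index=False, float_format="%.10g")

    def to_gexf(self, path: str | Path) -> None:
        """Write GEXF 1.2 with node dimension and edge sign attributes."""
        root = ET.Element("gexf", {
            "xmlns": "http://www.gexf.net/1.2draft", "version": "1.2"})
        graph = ET.SubElement(root, "graph", {
            "mode": "static", "defaultedgetype": "undirected"})
        attrs = ET.SubElement(graph, "attributes", {"class": "node"})
        ET.SubElement(attrs, "attribute", {
            "id": "0", "title": "dimension", "type": "string"})
        eattrs = ET.SubElement(graph, "attributes", {"class": "edge"})
        ET.SubElement(eattrs, "attribute", {
            "id": "0", "title": "sign", "type": "string"})
        nodes = ET.SubElement(graph, "nodes")
        for lab in self.labels:
            node = ET.SubElement(nodes, "node", {"id": lab, "label": lab})
            av = ET.SubElement(node, "attvalues")
            ET.SubElement(av, "attvalue", {
                "for": "0", "value": self.dimensions.get(lab, "other")})
        edges = ET.SubElement(graph, "edges")
        for eid, (i, j, w, _p) in enumerate(self.edges()):
            # GEXF weight must be positive; keep the signed Rp in "sign"
            # plus the magnitude as weight.
            edge = ET.SubElement(edges, "edge", {
                "id": str(eid), "source": self.labels[i],
                "target": self.labels[j], "weight": f"{abs(w):.10g}"})
            av = ET.SubElement(edge, "attvalues")
            ET.SubElement(av, "attvalue", {
                "for": "0", "value": "positive" if w > 0 else "negative"})
        ET.indent(root)
        ET.ElementTree(root).write(path, encoding="utf-8",
                                   xml_declaration=True)

    def to_graphml(self, path: str | Path) -> None:
        """Write GraphML with dimension, signed weight and p attributes."""
        ns = "http://graphml.graphdrawing.org/xmlns"
        root = ET.Element("graphml", {"xmlns": ns})
        ET.SubElement(root, "key", {"id": "d0", "for": "node",
                                    "attr.name": "dimension",
                                    "attr.type": "string"})
        ET.SubElement(root, "key", {"id": "d1", "for": "edge",
                                    "attr.name": "weight",
                                    "attr.type": "double"})
        ET.SubElement(root, "key", {"id": "d2", "for": "edge",
                                    "attr.name": "p",
                                    "attr.type": "double"})
        ET.SubElement(root, "key", {"id": "d3", "for": "edge",
                                    "attr.name": "sign",
                                    "attr.type": "string"})
        graph = ET.SubElement(root, "graph", {"id": "G",
                                              "edgedefault": "undirected"})
        for lab in self.labels:
            node = ET.SubElement(graph, "node", {"id": lab})
            data = ET.SubElement(node, "data", {"key": "d0"})
            data.text = self.dimensions.get(lab, "other")
        for i, j, w, p in self.edges():
            edge = ET.SubElement(graph, "edge", {"source": self.labels[i],
                                                 "target": self.labels[j]})
            ET.SubElement(edge, "data", {"key": "d1"}).text = f"{w:.10g}"
            ET.SubElement(edge, "data", {"key": "d2"}).text = f"{p:.10g}"
            ET.SubElement(edge, "data", {"key": "d3"}).text = (
                "positive" if w > 0 else "negative")
        ET.indent(root)
        ET.ElementTree(root).write(path, encoding="utf-8",
                                   xml_declaration=True)


def select_edges(pcor: PcorResult, alpha: float = 0.25) -> HealthNetwork:
    """Prune the complete pairwise matrix to edges with p strictly < alpha.

    All nodes are kept even when isolated; edge weights are the signed
    partial correlations of the retained pairs.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    keep = pcor.pvals < alpha
    np.fill_diagonal(keep, False)
    weights = np.where(keep, pcor.rp, 0.0)
    pvalues = np.where(keep, pcor.pvals, np.nan)
    return HealthNetwork(labels=list(pcor.labels), weights=weights,
                         pvalues=pvalues)
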