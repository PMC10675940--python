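"""Cell-subpopulation correlation networks and their topology panel.

Within one (survival group, region) stratum, each of the ten cell
populations is a node and an undirected edge joins two populations whose
abundance profiles across patients have Pearson correlation strictly
above a threshold (default 0.5, signed).  The topology panel follows the
Cytoscape NetworkAnalyzer conventions: only connected nodes (degree >= 1)
count as nodes, path metrics are taken on the largest connected
component, and centralization/heterogeneity use the Freeman-style degree
formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
import pandas as pd


def build_network(
    abundance: pd.DataFrame,
    r_threshold: float = 0.5,
    *,
    group: str | None = None,
    region: str | None = None,
) -> nx.Graph:
    """Correlation network of cell populations within one stratum.

    Parameters
    ----------
    abundance
        Patients x cell-types abundance table restricted to one
        (group, region) stratum.
    r_threshold
        Edge (u, v) exists iff Pearson r(u, v) > r_threshold (strict,
        signed -- strong negative correlations do not form edges).
    """
    if len(abundance) < 3:
        raise ValueError(f"need at least 3 patients, got {len(abundance)}")
    constant = abundance.columns[abundance.nunique() <= 1]
    if len(constant):
        warnings.warn(
            f"constant-abundance cell types form no edges: {list(constant)}",
            stacklevel=2,
        )
    corr = abundance.corr(method="pearson")  # NaN for constant columns
    g = nx.Graph(group=group, region=region, r_threshold=r_threshold)
    g.add_nodes_from(abundance.columns)
    cols = list(abundance.columns)
    for i, u in enumerate(cols):
        for v in cols[i + 1 :]:
            r = corr.loc[u, v]
            if np.isfinite(r) and r > r_threshold:
                g.add_edge(u, v, weight=float(r))
    return g


@dataclass
class TopologySummary:
    """The nine-parameter topology panel of one network."""

    node_number: int
    edge_number: int
    network_density: float
    network_diameter: float
    characteristic_path_length: float
    clustering_coefficient: float
    network_centralization: float
    network_heterogeneity: float
    mean_degree: float

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


def topology(g: nx.Graph) -> TopologySummary:
    """Compute the topology panel; isolated nodes are not counted as nodes.

    Degenerate cases (no edges, n <= 2) return 0 for the undefined
    metrics.  Diameter and characteristic path length are taken over the
    largest connected component; the clustering coefficient is the mean
    local clustering over nodes of degree >= 2.
    """
    connected = [v for v, d in g.degree() if d >= 1]
    sub = g.subgraph(connected)
    n = sub.number_of_nodes()
    e = sub.number_of_edges()
    if n == 0:
        return TopologySummary(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    degrees = np.array([d for _, d in sub.degree()], dtype=float)
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    mean_degree = 2.0 * e / n

    components = sorted(nx.connected_components(sub), key=len, reverse=True)
    giant = sub.subgraph(components[0])
    if giant.number_of_nodes() > 1:
        diameter = float(nx.diameter(giant))
        cpl = float(nx.average_shortest_path_length(giant))
    else:  # pragma: no cover - cannot happen when all nodes have degree >= 1
        diameter = cpl = 0.0

    local = nx.clustering(sub)
    deg2 = [v for v, d in sub.degree() if d >= 2]
    clustering = float(np.mean([local[v] for v in deg2])) if deg2 else 0.0

    if n > 2:
        centralization = (n / (n - 2.0)) * (degrees.max() / (n - 1.0) - density)
    else:
        centralization = 0.0
    mean_d = degrees.mean()
    heterogeneity = float(np.sqrt(degrees.var()) / mean_d) if mean_d > 0 else 0.0

    return TopologySummary(
        node_number=n,
        edge_number=e,
        network_density=float(density),
        network_diameter=diameter,
        characteristic_path_length=cpl,
        clustering_coefficient=clustering,
        network_centralization=float(centralization),
        network_heterogeneity=heterogeneity,
        mean_degree=float(mean_degree),
    )


def topology_panel(
    abundances: dict[tuple[str, str], pd.DataFrame], r_threshold: float = 0.5
) -> pd.DataFrame:
    """Topology panel per (group, region) stratum; one row each."""
    rows = {}
    for (group, region), table in abundances.items():
        g = build_network(table, r_threshold, group=group, region=region)
        rows[(group, region)] = topology(g).as_series()
    out = pd.DataFrame(rows).T
    out.index.names = ["group", "region"]
    return out


def write_edge_list(g: nx.Graph, path) -> None:
    """Write a graph-viewer-importable TSV edge list: source, target, weight."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in g.edges(data="weight"):
            fh.write(f"{u}\t{v}\t{w:.6f}\n")
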