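"""Topology metrics of a directed gene network.

Reports the hub genes (maximum total degree), mean total degree, directed
edge density, mean closeness and mean betweenness (both on the undirected
view of the graph, normalized to [0, 1]), and the Shannon entropy of the
empirical total-degree distribution.  For disconnected graphs the path-based
centralities are computed within each node's connected component with
per-component normalization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import networkx as nx


@dataclass
class NetworkMetrics:
    hubs: list[str]
    mean_degree: float
    edge_density: float
    mean_closeness: float
    mean_betweenness: float
    degree_entropy: float
    n_nodes: int
    n_edges: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def degree_entropy(degrees: list[int], base: float = np.e) -> float:
    """Shannon entropy of the empirical degree distribution.

    Zero for degree-regular graphs; bounded by log(#distinct degrees).
    """
    counts = np.bincount(np.asarray(degrees, dtype=int))
    p = counts[counts > 0] / len(degrees)
    return float(-(p * (np.log(p) / np.log(base))).sum())


def compute_metrics(
    g: nx.DiGraph,
    betweenness_normalized: bool = True,
    entropy_base: float = np.e,
) -> NetworkMetrics:
    """Summary topology metrics of a directed network.

    mean_degree is the mean total (in + out) degree, 2E/N; edge_density is
    E / (N(N-1)) for a directed graph.  Closeness and betweenness are
    averaged node centralities of the undirected view (closeness normalized
    within each node's component; betweenness divided by (N-1)(N-2)/2 when
    ``betweenness_normalized``).  Hubs are all nodes attaining the maximum
    total degree.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    e = g.number_of_edges()
    degs = dict(g.degree())
    max_deg = max(degs.values())
    hubs = sorted([v for v, d in degs.items() if d == max_deg])

    und = g.to_undirected()
    closeness = nx.closeness_centrality(und, wf_improved=False)
    betweenness = nx.betweenness_centrality(und, normalized=betweenness_normalized)

    return NetworkMetrics(
        hubs=hubs,
        mean_degree=2.0 * e / n,
        edge_density=e / (n * (n - 1)),
        mean_closeness=float(np.mean(list(closeness.values()))),
        mean_betweenness=float(np.mean(list(betweenness.values()))),
        degree_entropy=degree_entropy(list(degs.values()), base=entropy_base),
        n_nodes=n,
        n_edges=e,
    )
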