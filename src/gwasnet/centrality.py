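"""Six component centralities and the composite Integrated Value of Influence.

The IVI of node *i* combines six topological features, each min-max
range-normalized to [1, 100] over the analyzed network (primed symbols):

    IVI_i = (DC'_i + LH'_i) * ((NC'_i + CR'_i) * (BC'_i + CI'_i))

The first factor (degree centrality + local H index) measures the node's
*hubness*; the second (neighborhood connectivity + ClusterRank, times
betweenness + collective influence) its *spreading* capacity.  The raw
product spans [8, 80000], so a final min-max rescale to [1, 100] is applied
by default to present IVI on the conventional 1-100 scale.

Component definitions (undirected simple graphs):

* DC — number of distinct neighbors.
* LH — node's local h-index plus the sum of its neighbors' h-indices,
  where h(i) is the largest h such that i has >= h neighbors of degree >= h.
* NC — mean degree of the node's neighbors (0 for isolated nodes).
* CR — ClusterRank, 10^(−c(i)) * Σ_{j∈N(i)} (deg(j)+1) with c(i) the local
  clustering coefficient (0 for degree < 2).
* BC — unnormalized shortest-path betweenness, endpoints excluded, each
  unordered pair counted once.
* CI — collective influence, (deg(i)−1) * Σ (deg(j)−1) over the BFS
  frontier at exactly ``radius`` (default 3).
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import pandas as pd

from .exceptions import ValidationError
from .scoring import minmax_normalize, significance_threshold

RAW_COLUMNS = ("dc", "lh", "nc", "cr", "bc", "ci")


def degree_centrality(network: nx.Graph) -> dict:
    """Number of distinct neighbors per node (self-loops excluded)."""
    return {n: len(set(network[n]) - {n}) for n in network.nodes}


def _h_index(values) -> int:
    vals = sorted(values, reverse=True)
    h = 0
    for i, v in enumerate(vals, start=1):
        if v >= i:
            h = i
        else:
            break
    return h


def local_h_index(network: nx.Graph) -> dict:
    """LH(i) = h(i) + Σ_{j∈N(i)} h(j); isolated nodes score 0."""
    deg = degree_centrality(network)
    h = {n: _h_index(deg[j] for j in network[n]) for n in network.nodes}
    return {n: h[n] + sum(h[j] for j in network[n]) if deg[n] else 0
            for n in network.nodes}


def neighborhood_connectivity(network: nx.Graph) -> dict:
    """Mean neighbor degree; 0 for isolated nodes."""
    deg = degree_centrality(network)
    return {
        n: (sum(deg[j] for j in network[n]) / deg[n]) if deg[n] else 0.0
        for n in network.nodes
    }


def clusterrank(network: nx.Graph) -> dict:
    """CR(i) = 10^(−c(i)) · Σ_{j∈N(i)} (deg(j)+1), c from local clustering."""
    deg = degree_centrality(network)
    clust = nx.clustering(network)  # 0 for degree < 2
    return {
        n: 10.0 ** (-clust[n]) * sum(deg[j] + 1 for j in network[n])
        for n in network.nodes
    }


def betweenness_centrality(network: nx.Graph) -> dict:
    """Unnormalized betweenness; undirected pairs counted once."""
    return nx.betweenness_centrality(network, normalized=False)


def collective_influence(network: nx.Graph, radius: int = 3) -> dict:
    """CI(i) = (deg(i)−1) · Σ_{j: dist(i,j)=radius} (deg(j)−1)."""
    if radius < 1:
        raise ValidationError("radius must be >= 1")
    deg = degree_centrality(network)
    ci = {}
    for n in network.nodes:
        if deg[n] == 0:
            ci[n] = 0.0
            continue
        # BFS out to the exact-radius frontier
        dist = {n: 0}
        queue = deque([n])
        frontier_sum = 0
        while queue:
            u = queue.popleft()
            if dist[u] == radius:
                frontier_sum += deg[u] - 1
                continue
            for v in network[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        ci[n] = float((deg[n] - 1) * frontier_sum)
    return ci


def compute_ivi(network: nx.Graph, radius: int = 3,
                final_rescale: bool = True) -> pd.DataFrame:
    """Full centrality profile and IVI for every node of ``network``.

    Disconnected graphs are accepted; path-based terms only see pairs within
    the same component.  Raises for graphs with fewer than 2 nodes, where
    range normalization is meaningless.
    """
    if network.number_of_nodes() < 2:
        raise ValidationError("IVI needs a network with at least 2 nodes")
    nodes = list(network.nodes)
    raw = {
        "dc": degree_centrality(network),
        "lh": local_h_index(network),
        "nc": neighborhood_connectivity(network),
        "cr": clusterrank(network),
        "bc": betweenness_centrality(network),
        "ci": collective_influence(network, radius=radius),
    }
    table = pd.DataFrame({k: [float(v[n]) for n in nodes]
                          for k, v in raw.items()},
                         index=pd.Index(nodes, name="node"))
    for col in RAW_COLUMNS:
        table[col + "_n"] = minmax_normalize(table[col])
    table["hubness"] = table["dc_n"] + table["lh_n"]
    table["spreading1"] = table["nc_n"] + table["cr_n"]
    table["spreading2"] = table["bc_n"] + table["ci_n"]
    table["ivi_raw"] = table["hubness"] * (table["spreading1"]
                                           * table["spreading2"])
    table["ivi"] = (minmax_normalize(table["ivi_raw"])
                    if final_rescale else table["ivi_raw"])
    table.attrs["radius"] = radius
    table.attrs["final_rescale"] = final_rescale
    return table


def prioritize_by_ivi(profiles: pd.DataFrame, k: float = 1.5) -> set:
    """Nodes whose IVI reaches mean + k * SD over the analyzed network."""
    cut = significance_threshold(profiles["ivi"], k)
    return set(profiles.index[profiles["ivi"] >= cut])
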