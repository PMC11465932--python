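"""GWAS-deduced PPI subnetwork and its shortest-path (RbSP) extension.

The GWAS proteins present in the reference interactome are split into the
largest connected component of their induced subgraph ("blue" nodes, BN) and
the remainder ("green" nodes, GN).  The network is then extended by the
interior nodes of all shortest paths connecting each GN to its nearest BN
("yellow" nodes, YN); the extended network is the reference subgraph induced
on BN ∪ GN ∪ YN.  Under the guilt-by-association rationale the YNs are
candidate disease proteins deduced purely from network topology.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .exceptions import ValidationError

LABELS = ("BN", "GN", "YN", "OTHER")


@dataclass
class LoadReport:
    n_nodes: int = 0
    n_edges: int = 0
    n_self_loops_removed: int = 0
    n_duplicates_removed: int = 0


@dataclass
class NodeClassification:
    """Per-node label (BN/GN/YN/OTHER) and connected-component id."""

    labels: dict = field(default_factory=dict)
    component_id: dict = field(default_factory=dict)
    dropped: set = field(default_factory=set)  # GWAS ids absent from network

    def nodes_with(self, label: str) -> set:
        return {n for n, lab in self.labels.items() if lab == label}


@dataclass
class RbSPResult:
    """Extended network plus bookkeeping from the shortest-path extension."""

    graph: nx.Graph
    yn_set: set
    gn_distance: dict           # GN -> BFS distance to the nearest BN
    unreachable_gns: set
    classification: NodeClassification

    @property
    def fraction_gn_within_two(self) -> float:
        """Diagnostic: fraction of reachable GNs at distance <= 2 of a BN."""
        if not self.gn_distance:
            return float("nan")
        d = list(self.gn_distance.values())
        return sum(x <= 2 for x in d) / len(d)


def load_network(path) -> tuple[nx.Graph, LoadReport]:
    """Read an undirected simple graph from a 2-column TSV or a SIF file.

    Self-loops and duplicate edges are removed and counted in the report.
    SIF lines are ``source<TAB>interaction<TAB>target[<TAB>target...]``;
    files ending in ``.sif`` are parsed as SIF, everything else as TSV.
    """
    path = str(path)
    is_sif = path.endswith(".sif")
    graph = nx.Graph()
    report = LoadReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if is_sif:
                if len(fields) < 3:
                    # single-column SIF lines declare isolated nodes
                    if len(fields) == 1:
                        graph.add_node(fields[0])
                        continue
                    raise ValidationError(
                        f"{path}:{lineno}: SIF line needs source, "
                        f"interaction and at least one target")
                pairs = [(fields[0], t) for t in fields[2:]]
            else:
                if len(fields) != 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
                pairs = [(fields[0], fields[1])]
            for u, v in pairs:
                if u == v:
                    report.n_self_loops_removed += 1
                    graph.add_node(u)
                elif graph.has_edge(u, v):
                    report.n_duplicates_removed += 1
                else:
                    graph.add_edge(u, v)
    report.n_nodes = graph.number_of_nodes()
    report.n_edges = graph.number_of_edges()
    return graph, report


def classify_bn_gn(network: nx.Graph, gwas_proteins: set) -> NodeClassification:
    """Split GWAS proteins into BN (largest induced component) and GN.

    GWAS ids absent from the network are recorded in ``dropped``.  Ties for
    the largest component are broken by the lexicographically smallest
    member, making the classification deterministic.
    """
    present = set(gwas_proteins) & set(network.nodes)
    cls = NodeClassification(dropped=set(gwas_proteins) - present)
    if not present:
        return cls
    induced = network.subgraph(present)
    components = sorted(nx.connected_components(induced),
                        key=lambda c: (-len(c), min(str(n) for n in c)))
    for cid, comp in enumerate(components):
        label = "BN" if cid == 0 else "GN"
        for node in comp:
            cls.labels[node] = label
            cls.component_id[node] = cid
    return cls


def _bfs_distances(graph: nx.Graph, sources, limit=None) -> dict:
    """Plain multi-source BFS; ``limit`` caps the explored depth."""
    dist = {s: 0 for s in sources}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        if limit is not None and dist[u] >= limit:
            continue
        for v in graph[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _single_shortest_path(graph: nx.Graph, source, dist_bn: dict, d: int):
    """One deterministic shortest source→BN path (lexicographic choice).

    Greedily walks from ``source`` towards the BN set, always picking the
    lexicographically smallest neighbor that still lies on a shortest path
    (i.e. whose distance to the BN set decreases by one each step).
    """
    path = [source]
    node, remaining = source, d
    while remaining > 0:
        nxt = min((v for v in graph[node] if dist_bn.get(v) == remaining - 1),
                  key=str)
        path.append(nxt)
        node, remaining = nxt, remaining - 1
    return path


def rbsp_extend(reference: nx.Graph, classification: NodeClassification,
                path_policy: str = "all_shortest") -> RbSPResult:
    """Extend the GWAS-deduced network by shortest-path intermediates.

    For each GN ``g`` with distance ``d(g)`` to the nearest BN, the interior
    nodes of shortest g→BN paths become YNs (non-GWAS nodes only; BNs/GNs
    encountered as interiors keep their labels).  Under ``all_shortest``
    (default) every interior node of every length-d(g) path to any BN at
    that distance is included; ``single`` keeps one deterministic path per
    GN.  The extended network is the reference subgraph induced on
    BN ∪ GN ∪ YN; unreachable GNs are retained as isolated/GN-only parts.
    """
    if path_policy not in ("all_shortest", "single"):
        raise ValidationError(f"unknown path_policy {path_policy!r}")
    bns = classification.nodes_with("BN")
    gns = classification.nodes_with("GN")
    if not bns:
        raise ValidationError("no BN nodes: cannot extend the network")

    dist_bn = _bfs_distances(reference, bns)
    gwas = bns | gns
    yn_set: set = set()
    gn_distance: dict = {}
    unreachable: set = set()

    for g in gns:
        d = dist_bn.get(g)
        if d is None:
            unreachable.add(g)
            continue
        gn_distance[g] = d
        if d <= 1:
            continue  # adjacent GNs contribute no interior nodes
        if path_policy == "all_shortest":
            dist_g = _bfs_distances(reference, [g], limit=d - 1)
            for v, dg in dist_g.items():
                if 0 < dg < d and dist_bn.get(v, np.inf) + dg == d:
                    if v not in gwas:
                        yn_set.add(v)
        else:
            path = _single_shortest_path(reference, g, dist_bn, d)
            yn_set.update(v for v in path[1:-1] if v not in gwas)

    extended = reference.subgraph(bns | gns | yn_set).copy()

    labels = dict(classification.labels)
    labels.update({v: "YN" for v in yn_set})
    out_cls = NodeClassification(labels=labels,
                                 dropped=set(classification.dropped))
    comps = sorted(nx.connected_components(extended),
                   key=lambda c: (-len(c), min(str(n) for n in c)))
    for cid, comp in enumerate(comps):
        for node in comp:
            out_cls.component_id[node] = cid
    return RbSPResult(graph=extended, yn_set=yn_set, gn_distance=gn_distance,
                      unreachable_gns=unreachable, classification=out_cls)


def fit_power_law(degree_counts: dict) -> dict | None:
    """Least-squares fit of log10 P(k) against log10 k.

    Only degrees k >= 1 with nonzero frequency enter the regression.
    Returns ``{"slope", "intercept", "r2"}`` or ``None`` (with a warning)
    when fewer than 3 distinct degrees are available.
    """
    ks = sorted(k for k, c in degree_counts.items() if k >= 1 and c > 0)
    if len(ks) < 3:
        warnings.warn("fewer than 3 distinct degrees: power-law fit skipped")
        return None
    total = sum(degree_counts[k] for k in ks)
    x = np.log10(ks)
    y = np.log10([degree_counts[k] / total for k in ks])
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r2": float(fit.rvalue ** 2)}


def network_summary(network: nx.Graph, reference: nx.Graph | None = None,
                    hub_threshold: int = 300) -> dict:
    """Node/edge counts, degree histogram, hub count and scale-free fit.

    Hubs are counted by degree in the *reference* network (the full
    interactome) when one is given, since hub status is a property of the
    protein in the complete interactome rather than in the analyzed subset.
    """
    degrees = dict(network.degree())
    hist: dict[int, int] = {}
    for d in degrees.values():
        hist[d] = hist.get(d, 0) + 1
    ref = reference if reference is not None else network
    n_hubs = sum(1 for n in network.nodes
                 if n in ref and ref.degree(n) > hub_threshold)
    return {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "degree_histogram": hist,
        "n_reference_hubs": n_hubs,
        "hub_threshold": hub_threshold,
        "power_law": fit_power_law(hist),
    }
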