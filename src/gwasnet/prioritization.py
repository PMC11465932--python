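"""Criterion 3 (common-neighbor subnetwork) and the multi-criteria ranking.

Criterion 3 promotes network-deduced intermediates (YNs) that are common
interactors of at least two GWAS-prioritized proteins, together with the
GWAS-prioritized proteins they connect; all nodes of that subnetwork count
as prioritized.  The final ranking orders the union of the three criteria
sets by the number and kind of satisfied criteria, then by the relevant
score within each group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .centrality import compute_ivi
from .exceptions import ValidationError
from .scoring import significance_threshold

#: group labels in ranking order; GWAS-backed pairs outrank purely
#: network-backed pairs
GROUP_ORDER = ("G1_all3", "G2a_c1c3", "G2c_c1c2", "G2b_c2c3",
               "G3a_c1_only", "G3b_c3_only", "G3c_c2_only")


@dataclass
class Criterion3Result:
    subgraph: nx.Graph
    selected_yns: set = field(default_factory=set)
    anchor_proteins: set = field(default_factory=set)  # prioritized neighbors

    @property
    def nodes(self) -> set:
        return set(self.subgraph.nodes)


def criterion3_subnetwork(rbsp, gwas_prioritized: set,
                          star_only: bool = False) -> Criterion3Result:
    """Common-neighbor subnetwork of the GWAS-prioritized proteins.

    YNs adjacent (in the extended network) to >= 2 distinct GWAS-prioritized
    proteins are selected; the node set adds every GWAS-prioritized protein
    adjacent to >= 1 selected YN, and the subnetwork is the induced subgraph
    on that node set (``star_only`` instead keeps only YN-prioritized edges,
    for sensitivity analysis).
    """
    graph = rbsp.graph
    labels = rbsp.classification.labels
    prioritized = set(gwas_prioritized) & set(graph.nodes)
    if len(prioritized) < 2:
        warnings.warn("fewer than 2 GWAS-prioritized proteins in the "
                      "network: Criterion 3 is empty")
        return Criterion3Result(subgraph=nx.Graph())
    yns = {
        n for n in graph.nodes
        if labels.get(n) == "YN"
        and len(set(graph[n]) & prioritized) >= 2
    }
    anchors = {p for p in prioritized if set(graph[p]) & yns}
    node_set = yns | anchors
    sub = graph.subgraph(node_set).copy()
    if star_only:
        drop = [(u, v) for u, v in sub.edges
                if not ((u in yns) ^ (v in yns))]
        sub.remove_edges_from(drop)
    return Criterion3Result(subgraph=sub, selected_yns=yns,
                            anchor_proteins=anchors)


def criterion3_rank(subnetwork: nx.Graph, radius: int = 3,
                    k: float = 1.5) -> pd.DataFrame:
    """IVI ranking of the Criterion-3 subnetwork, recomputed on it alone.

    The ``passes_threshold`` column (mean + k*SD within the subnetwork) is a
    diagnostic; all subnetwork nodes remain Criterion-3 prioritized.
    """
    profiles = compute_ivi(subnetwork, radius=radius)
    profiles = profiles.loc[
        sorted(profiles.index, key=lambda n: (-profiles.at[n, "ivi"], str(n)))]
    cut = significance_threshold(profiles["ivi"], k)
    profiles["passes_threshold"] = profiles["ivi"] >= cut
    profiles["rank"] = range(1, len(profiles) + 1)
    return profiles


def combine_and_rank(c1: set, c2: set, c3: set,
                     scores: pd.Series | None = None,
                     ivi_rbsp: pd.Series | None = None,
                     ivi_c3: pd.Series | None = None,
                     node_types: dict | None = None) -> pd.DataFrame:
    """Rank the union of the three criteria sets.

    Group order: all three; C1∧C3; C1∧C2; C2∧C3; C1 only; C3 only; C2 only.
    Within-group sort keys: Criterion-3 IVI for groups containing C3,
    integrated GWAS score for C1-only, RbSP IVI for groups containing C2 but
    not C3; remaining ties break lexicographically by id.  The rank is a
    strict 1-based total order.
    """
    proteins = sorted(c1 | c2 | c3, key=str)
    if not proteins:
        return pd.DataFrame(columns=["c1", "c2", "c3", "n_criteria", "group",
                                     "sort_key", "overall_rank"])

    def _lookup(series, p, what):
        if series is None or p not in series.index:
            raise ValidationError(f"protein {p!r} lacks {what}")
        return float(series.loc[p])

    rows = []
    for p in proteins:
        f1, f2, f3 = p in c1, p in c2, p in c3
        if f1 and f2 and f3:
            group = "G1_all3"
        elif f1 and f3:
            group = "G2a_c1c3"
        elif f1 and f2:
            group = "G2c_c1c2"
        elif f2 and f3:
            group = "G2b_c2c3"
        elif f1:
            group = "G3a_c1_only"
        elif f3:
            group = "G3b_c3_only"
        else:
            group = "G3c_c2_only"
        if f3:
            key = _lookup(ivi_c3, p, "a Criterion-3 IVI value")
        elif f2:
            key = _lookup(ivi_rbsp, p, "an RbSP IVI value")
        else:
            key = _lookup(scores, p, "an integrated GWAS score") \
                if scores is not None else 0.0
        rows.append({
            "protein": p,
            "node_type": (node_types or {}).get(p, ""),
            "c1": f1, "c2": f2, "c3": f3,
            "n_criteria": int(f1) + int(f2) + int(f3),
            "group": group,
            "sort_key": key,
        })
    table = pd.DataFrame(rows).set_index("protein")
    order = {g: i for i, g in enumerate(GROUP_ORDER)}
    table = table.loc[sorted(
        table.index,
        key=lambda p: (order[table.at[p, "group"]],
                       -table.at[p, "sort_key"], str(p)))]
    table["overall_rank"] = range(1, len(table) + 1)
    return table
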