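"""Independent brute-force oracles used to cross-check the implementation.

Everything here favors transparency over speed: exhaustive enumeration,
closed forms and exact rational arithmetic, kept deliberately separate from
the code paths they verify.
"""

from __future__ import annotations

import math
from fractions import Fraction

import networkx as nx


# ---- centralities -------------------------------------------------------

def bf_degree(G, v):
    return len(set(G[v]) - {v})


def bf_h(G, v):
    degs = sorted((bf_degree(G, u) for u in G[v]), reverse=True)
    h = 0
    while h < len(degs) and degs[h] >= h + 1:
        h += 1
    return h


def bf_lh(G, v):
    if bf_degree(G, v) == 0:
        return 0
    return bf_h(G, v) + sum(bf_h(G, u) for u in G[v])


def bf_nc(G, v):
    d = bf_degree(G, v)
    return sum(bf_degree(G, u) for u in G[v]) / d if d else 0.0


def bf_cr(G, v):
    neigh = list(G[v])
    d = len(neigh)
    if d < 2:
        c = 0.0
    else:
        links = sum(1 for i in range(d) for j in range(i + 1, d)
                    if G.has_edge(neigh[i], neigh[j]))
        c = 2 * links / (d * (d - 1))
    return 10.0 ** (-c) * sum(bf_degree(G, u) + 1 for u in neigh)


def _enumerate_shortest_paths(G, s, t):
    """All shortest s-t paths by walking BFS levels backwards from t."""
    dist = nx.single_source_shortest_path_length(G, s)
    if t not in dist:
        return []
    paths = []

    def back(u, tail):
        if u == s:
            paths.append([s] + tail)
            return
        for w in G[u]:
            if dist.get(w) == dist[u] - 1:
                back(w, [u] + tail)

    back(t, [])
    return paths


def bf_bc(G, v):
    """Betweenness by explicit enumeration of every shortest path per pair."""
    total = 0.0
    nodes = sorted(G.nodes, key=str)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if s == v or t == v:
                continue
            shortest = _enumerate_shortest_paths(G, s, t)
            if not shortest:
                continue
            through = sum(1 for p in shortest if v in p[1:-1])
            total += through / len(shortest)
    return total


def bf_ci(G, v, radius):
    deg = bf_degree(G, v)
    if deg == 0:
        return 0.0
    dist = nx.single_source_shortest_path_length(G, v)
    frontier = [u for u, d in dist.items() if d == radius]
    return float((deg - 1) * sum(bf_degree(G, u) - 1 for u in frontier))


def bf_all_centralities(G, radius=3):
    return {
        "dc": {v: float(bf_degree(G, v)) for v in G},
        "lh": {v: float(bf_lh(G, v)) for v in G},
        "nc": {v: bf_nc(G, v) for v in G},
        "cr": {v: bf_cr(G, v) for v in G},
        "bc": {v: bf_bc(G, v) for v in G},
        "ci": {v: bf_ci(G, v, radius) for v in G},
    }


# ---- RbSP ----------------------------------------------------------------

def bf_rbsp_ynset(G, bns, gns):
    """Interior nodes of all shortest GN->nearest-BN paths, non-GWAS only."""
    gwas = set(bns) | set(gns)
    yns = set()
    for g in gns:
        dists = {}
        for b in bns:
            try:
                dists[b] = nx.shortest_path_length(G, g, b)
            except nx.NetworkXNoPath:
                continue
        if not dists:
            continue
        d = min(dists.values())
        for b, db in dists.items():
            if db != d:
                continue
            for path in nx.all_shortest_paths(G, g, b):
                yns.update(v for v in path[1:-1] if v not in gwas)
    return yns


# ---- enrichment ----------------------------------------------------------

def hypergeom_exact(N, K, n, k):
    """Exact upper-tail P(X >= k) by rational summation."""
    if k <= 0:
        return 1.0
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


# ---- scoring -------------------------------------------------------------

def minmax_oracle(xs, lo=1.0, hi=100.0):
    mn, mx = min(xs), max(xs)
    if mx == mn:
        return [lo] * len(xs)
    return [lo + (hi - lo) * (x - mn) / (mx - mn) for x in xs]


def score_oracle(triples, weights=(0.45, 0.35, 0.20), final_rescale=True):
    """Integrated score from (neglog10p, n_snps, n_pubs) triples."""
    np_ = minmax_oracle([t[0] for t in triples])
    ns = minmax_oracle([t[1] for t in triples])
    nb = minmax_oracle([t[2] for t in triples])
    raw = [weights[0] * a + weights[1] * b + weights[2] * c
           for a, b, c in zip(np_, ns, nb)]
    return minmax_oracle(raw) if final_rescale else raw
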