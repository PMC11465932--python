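"""Gene-set over-representation analysis with BH FDR.

Standard hypergeometric (one-sided, upper tail) over-representation of a
query protein set against a GMT collection, with Benjamini-Hochberg q-values
across the tested sets.  An EASE mode (the conservative modified Fisher
statistic, computed with one success removed from the overlap) is offered
as an alternative.  Pathways whose overlapping members are mostly
network-deduced intermediates (YN fraction above a threshold, default 65%)
can be flagged: such pathways would not have surfaced from the GWAS
proteins alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError


@dataclass
class GeneSetCollection:
    """GMT-style collection: set_id -> (name, member frozenset)."""

    sets: dict = field(default_factory=dict)
    universe: frozenset = frozenset()

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets = {}
        members_union: set = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValidationError(
                        f"{path}:{lineno}: GMT line needs id, description "
                        "and at least one member")
                set_id, name = fields[0], fields[1]
                members = frozenset(m for m in fields[2:] if m)
                if set_id in sets:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate set id {set_id!r}")
                sets[set_id] = (name, members)
                members_union |= members
        return cls(sets=sets, universe=frozenset(members_union))

    def restricted(self, universe) -> "GeneSetCollection":
        """Intersect members with ``universe``; drop sets that become empty."""
        uni = frozenset(universe)
        sets = {}
        for set_id, (name, members) in self.sets.items():
            kept = members & uni
            if kept:
                sets[set_id] = (name, kept)
        return GeneSetCollection(sets=sets, universe=uni)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k | N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query: set, collection: GeneSetCollection,
           mode: str = "hypergeometric",
           universe: set | None = None) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of ``collection``.

    ``universe`` defaults to all ids appearing in the collection.  Sets with
    zero overlap are reported with p = 1.  ``mode='ease'`` computes the
    tail with k-1 successes (floored at 0).  Raises when the query is
    disjoint from the universe.
    """
    if mode not in ("hypergeometric", "ease"):
        raise ValidationError(f"unknown enrichment mode {mode!r}")
    coll = collection.restricted(universe if universe is not None
                                 else collection.universe)
    N = len(coll.universe)
    q = set(query) & coll.universe
    if not q:
        raise ValidationError("query is disjoint from the universe")
    n = len(q)

    rows = []
    for set_id, (name, members) in sorted(coll.sets.items()):
        K = len(members)
        overlap = q & members
        k = len(overlap)
        successes = max(k - 1, 0) if mode == "ease" else k
        p = hypergeom_tail(N, K, n, successes)
        fold = (k / n) / (K / N) if K else 0.0
        rows.append({
            "set_id": set_id, "name": name,
            "k": k, "n": n, "K": K, "N": N,
            "fold_enrichment": fold, "p": p,
            "overlap": frozenset(overlap),
        })
    table = pd.DataFrame(rows).set_index("set_id")
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["q"] = []
    table.attrs["mode"] = mode
    return table


def yn_pathway_flag(result: pd.DataFrame, labels: dict,
                    threshold: float = 0.65) -> pd.DataFrame:
    """Add the YN fraction of each set's overlap and flag fractions > threshold."""
    out = result.copy()
    fracs = []
    for overlap in out["overlap"]:
        if overlap:
            fracs.append(sum(labels.get(m) == "YN" for m in overlap)
                         / len(overlap))
        else:
            fracs.append(0.0)
    out["yn_fraction"] = fracs
    out["yn_flag"] = out["yn_fraction"] > threshold
    return out
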