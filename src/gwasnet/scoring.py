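"""Integrated GWAS-based gene scoring (Criterion 1) and gene-table utilities.

A gene's evidence from genome-wide association studies is summarized by three
attributes: the minimum association p-value over its significant SNPs, the
number of significant SNPs mapped to the gene, and the number of independent
publications supporting the association.  The integrated score is a weighted
sum of the three attributes after each has been min-max range-normalized to
[1, 100]; the log-scale attribute |log10 p| is normalized rather than the raw
p-value, which would collapse nearly all genes onto the lower bound.  By
default the weighted sums are themselves rescaled to [1, 100] so that the
best-supported gene scores exactly 100.

Genes are prioritized (Criterion 1) when their score reaches the lenient
normal-distribution threshold mean + 1*SD; the stricter mean + 1.5*SD variant
used for network metrics is the same function with k = 1.5.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: default genome-wide significance threshold on the SNP association p-value
GENOME_WIDE_P = 5e-8

#: default attribute weights (p-value, #SNPs, #Pubs)
DEFAULT_WEIGHTS = (0.45, 0.35, 0.20)


@dataclass(frozen=True)
class GeneRecord:
    """One gene's aggregated GWAS attributes.

    Parameters
    ----------
    gene_id:
        Unique gene identifier (symbol or stable id).
    min_p:
        Minimum association p-value over the gene's significant SNPs;
        must lie in (0, genome-wide threshold].
    n_snps:
        Number of significant SNPs mapped to the gene (>= 1).
    n_pubs:
        Number of independent supporting publications (>= 1).
    traits:
        Trait labels the gene is associated with (e.g. SBP, DBP, PP).
    eqtl_q:
        Optional tissue -> cis-eQTL q-value map; q in [0, 1].
    """

    gene_id: str
    min_p: float
    n_snps: int
    n_pubs: int
    traits: frozenset = field(default_factory=frozenset)
    eqtl_q: Mapping[str, float] | None = None

    @property
    def neglog10p(self) -> float:
        return -math.log10(self.min_p)


def validate_table(records: Sequence[GeneRecord],
                   genome_wide_p: float = GENOME_WIDE_P) -> None:
    """Check GeneRecord invariants; raise :class:`ValidationError` on failure."""
    if not records:
        raise ValidationError("gene table is empty")
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        if not (0.0 < rec.min_p <= genome_wide_p):
            raise ValidationError(
                f"{rec.gene_id}: min_p {rec.min_p!r} outside (0, {genome_wide_p}]")
        if rec.n_snps < 1:
            raise ValidationError(f"{rec.gene_id}: n_snps must be >= 1")
        if rec.n_pubs < 1:
            raise ValidationError(f"{rec.gene_id}: n_pubs must be >= 1")
        if rec.eqtl_q is not None:
            for tissue, q in rec.eqtl_q.items():
                if not (0.0 <= q <= 1.0):
                    raise ValidationError(
                        f"{rec.gene_id}: q-value {q!r} for tissue {tissue!r} "
                        "outside [0, 1]")


def minmax_normalize(values: Iterable[float], lo: float = 1.0,
                     hi: float = 100.0) -> np.ndarray:
    """Min-max range-normalize ``values`` to ``[lo, hi]``.

    A degenerate input (all values equal, including a single value) maps
    every element to ``lo``.  The transform is affine, hence order-preserving.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot normalize an empty sequence")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValidationError(f"non-finite value at index {int(bad[0])}")
    vmin, vmax = arr.min(), arr.max()
    if vmax == vmin:
        return np.full_like(arr, lo)
    return lo + (hi - lo) * (arr - vmin) / (vmax - vmin)


def significance_threshold(scores: Iterable[float], k: float,
                           ddof: int = 1) -> float:
    """Normal-distribution significance cut-off: mean + k * SD.

    Uses the sample standard deviation (``ddof=1``) by default.  Downstream
    selection keeps items with score **>=** the returned threshold.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 2:
        raise ValidationError("threshold needs at least 2 values")
    return float(arr.mean() + k * arr.std(ddof=ddof))


def compute_integrated_scores(records: Sequence[GeneRecord],
                              weights: Sequence[float] = DEFAULT_WEIGHTS,
                              final_rescale: bool = True,
                              criterion1_k: float = 1.0) -> pd.DataFrame:
    """Compute the integrated GWAS score for every gene in ``records``.

    Returns a DataFrame indexed by ``gene_id`` with the raw attributes, their
    [1, 100]-normalized versions, the weighted ``raw_score``, the final
    ``score`` (rescaled to [1, 100] when ``final_rescale``), and the
    Criterion-1 flag ``prioritized_c1`` (score >= mean + criterion1_k * SD).
    """
    validate_table(records)
    w = np.asarray(weights, dtype=float)
    if w.size != 3 or (w < 0).any():
        raise ValidationError("weights must be three non-negative numbers")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError(f"weights must sum to 1 (got {w.sum()!r})")

    neglog = np.array([r.neglog10p for r in records])
    snps = np.array([r.n_snps for r in records], dtype=float)
    pubs = np.array([r.n_pubs for r in records], dtype=float)

    norm_p = minmax_normalize(neglog)
    norm_snps = minmax_normalize(snps)
    norm_pubs = minmax_normalize(pubs)
    raw = w[0] * norm_p + w[1] * norm_snps + w[2] * norm_pubs
    score = minmax_normalize(raw) if final_rescale else raw

    table = pd.DataFrame(
        {
            "min_p": [r.min_p for r in records],
            "n_snps": [r.n_snps for r in records],
            "n_pubs": [r.n_pubs for r in records],
            "neglog10p": neglog,
            "norm_p": norm_p,
            "norm_snps": norm_snps,
            "norm_pubs": norm_pubs,
            "raw_score": raw,
            "score": score,
        },
        index=pd.Index([r.gene_id for r in records], name="gene_id"),
    )
    if len(table) >= 2:
        cut = significance_threshold(score, criterion1_k)
    else:  # a single gene is trivially at its own threshold
        cut = float(score[0])
    table["prioritized_c1"] = table["score"] >= cut
    table.attrs["criterion1_threshold"] = cut
    table.attrs["criterion1_k"] = criterion1_k
    table.attrs["weights"] = tuple(w)
    table.attrs["final_rescale"] = final_rescale
    return table


def prioritize_criterion1(score_table: pd.DataFrame, k: float = 1.0) -> set:
    """Genes whose score reaches mean + k * SD of all scores."""
    cut = significance_threshold(score_table["score"], k)
    return set(score_table.index[score_table["score"] >= cut])


def top_attribute_set(records: Sequence[GeneRecord], min_snps: int = 5,
                      max_p: float = 1e-30, min_pubs: int = 2) -> set:
    """Genes in the joint upper tail of all three attributes.

    The default filter (>= 5 SNPs, min p < 1e-30, >= 2 publications) selects
    the genes most strongly supported by the GWAS evidence alone.
    """
    return {
        r.gene_id for r in records
        if r.n_snps >= min_snps and r.min_p < max_p and r.n_pubs >= min_pubs
    }


def trait_overlap_counts(records: Sequence[GeneRecord],
                         trait_names: Sequence[str]) -> dict:
    """Venn-region counts over the named traits.

    Keys are sorted tuples of trait labels; each gene with at least one of
    the named traits is counted in exactly one region (its exact overlap),
    so region counts sum to the number of genes carrying any named trait.
    """
    named = set(trait_names)
    counts: dict[tuple, int] = {}
    for r in records:
        combo = tuple(sorted(r.traits & named))
        if combo:
            counts[combo] = counts.get(combo, 0) + 1
    return counts


class EGeneFlags(NamedTuple):
    egene: bool        # q <= 0.05 in this tissue
    significant: bool  # eGene and q equals the gene's minimum over tissues


def flag_significant_egenes(records: Sequence[GeneRecord],
                            q_cut: float = 0.05) -> dict:
    """Per-gene, per-tissue eGene flags.

    A gene is an eGene in tissue ``t`` when its cis-eQTL q-value there is
    <= ``q_cut``; it is flagged *significant* only in the tissue(s) where
    its q-value equals its minimum over all tissues (ties flagged in all
    tied tissues).  Genes without eQTL data are omitted from the result.
    """
    if not any(r.eqtl_q for r in records):
        raise ValidationError("no gene carries eQTL q-values")
    out: dict[str, dict[str, EGeneFlags]] = {}
    for r in records:
        if not r.eqtl_q:
            continue
        for tissue, q in r.eqtl_q.items():
            if not (0.0 <= q <= 1.0):
                raise ValidationError(
                    f"{r.gene_id}: q-value {q!r} for {tissue!r} outside [0, 1]")
        qmin = min(r.eqtl_q.values())
        out[r.gene_id] = {
            tissue: EGeneFlags(egene=q <= q_cut,
                               significant=q <= q_cut and q == qmin)
            for tissue, q in r.eqtl_q.items()
        }
    return out


def count_egenes(flags: Mapping[str, Mapping[str, EGeneFlags]]) -> int:
    """Number of genes that are an eGene in at least one tissue."""
    return sum(any(f.egene for f in per_tissue.values())
               for per_tissue in flags.values())


def score_summary(records: Sequence[GeneRecord],
                  table: pd.DataFrame) -> dict:
    """Descriptive summary used in the JSON report."""
    return {
        "n_genes": len(records),
        "criterion1_threshold": table.attrs.get("criterion1_threshold"),
        "n_prioritized_c1": int(table["prioritized_c1"].sum()),
        "median_min_p": float(np.median([r.min_p for r in records])),
        "n_top_attribute": len(top_attribute_set(records)),
    }
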