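"""Integrated GWAS scoring: normalization, thresholds, filters, eGene flags."""

import math

import numpy as np
import pytest

from gwasnet.exceptions import ValidationError
from gwasnet.scoring import (
    GeneRecord, compute_integrated_scores, count_egenes,
    flag_significant_egenes, minmax_normalize, prioritize_criterion1,
    significance_threshold, top_attribute_set, trait_overlap_counts,
    validate_table,
)

from oracles import score_oracle


@pytest.mark.parametrize("values,expected", [
    ([0, 5, 10], [1.0, 50.5, 100.0]),
    ([3, 3, 3], [1.0, 1.0, 1.0]),
    ([7], [1.0]),
])
def test_minmax_normalize_examples(values, expected):
    assert minmax_normalize(values) == pytest.approx(expected)


def test_minmax_normalize_rejects_non_finite():
    with pytest.raises(ValidationError, match="index 1"):
        minmax_normalize([1.0, float("nan"), 2.0])
    with pytest.raises(ValidationError):
        minmax_normalize([])


@pytest.mark.parametrize("scores,k,expected", [
    ([1, 2, 3, 4, 5], 1.0, 3 + math.sqrt(2.5)),        # sample SD
    ([0, 10], 1.5, 5 + 1.5 * math.sqrt(50)),
    ([4, 4, 4], 2.0, 4.0),                              # zero variance
])
def test_significance_threshold(scores, k, expected):
    assert significance_threshold(scores, k) == pytest.approx(expected)


def test_significance_threshold_needs_two_values():
    with pytest.raises(ValidationError):
        significance_threshold([1.0], 1.0)


def _records(triples):
    return [GeneRecord(f"g{i}", 10.0 ** -t[0], t[1], t[2])
            for i, t in enumerate(triples)]


def test_integrated_scores_match_arithmetic_oracle():
    triples = [(10, 1, 1), (20, 5, 2), (30, 10, 3)]
    table = compute_integrated_scores(_records(triples))
    assert list(table["score"]) == pytest.approx(score_oracle(triples))
    # middle gene by hand: each normalized component then the weighted sum
    assert table["norm_p"].iloc[1] == pytest.approx(50.5)
    assert table["norm_snps"].iloc[1] == pytest.approx(1 + 99 * 4 / 9)
    assert table["norm_pubs"].iloc[1] == pytest.approx(50.5)
    assert table["raw_score"].iloc[1] == pytest.approx(
        0.45 * 50.5 + 0.35 * (1 + 99 * 4 / 9) + 0.20 * 50.5)


def test_extreme_genes_score_1_and_100():
    table = compute_integrated_scores(
        _records([(10, 1, 1), (20, 5, 2), (30, 10, 3)]))
    assert table["score"].iloc[0] == pytest.approx(1.0)   # all minima
    assert table["score"].iloc[2] == pytest.approx(100.0)  # all maxima


def test_weight_validation():
    recs = _records([(10, 1, 1), (20, 5, 2)])
    with pytest.raises(ValidationError):
        compute_integrated_scores(recs, weights=(0.5, 0.5, 0.5))
    with pytest.raises(ValidationError):
        compute_integrated_scores([])


def test_criterion1_dominant_gene_included():
    triples = [(10, 1, 1)] * 9 + [(100, 50, 10)]
    table = compute_integrated_scores(_records(triples))
    assert "g9" in prioritize_criterion1(table, k=1.0)


def test_criterion1_equals_brute_force_scan():
    rng = np.random.default_rng(7)
    triples = [(float(rng.uniform(8, 60)), int(rng.integers(1, 30)),
                int(rng.integers(1, 8))) for _ in range(50)]
    table = compute_integrated_scores(_records(triples))
    cut = significance_threshold(table["score"], 1.0)
    brute = {g for g, s in table["score"].items() if s >= cut}
    assert prioritize_criterion1(table, k=1.0) == brute


def test_top_attribute_set_filters_and_brute_force():
    recs = [
        GeneRecord("pass", 1e-40, 5, 2),
        GeneRecord("few_snps", 1e-40, 4, 5),
        GeneRecord("weak_p", 1e-30, 9, 3),   # p not strictly below 1e-30
        GeneRecord("one_pub", 1e-50, 9, 1),
    ]
    assert top_attribute_set(recs) == {"pass"}
    rng = np.random.default_rng(11)
    recs = [GeneRecord(f"g{i}", 10.0 ** -float(rng.uniform(8, 60)),
                       int(rng.integers(1, 12)), int(rng.integers(1, 5)))
            for i in range(80)]
    brute = {r.gene_id for r in recs
             if r.n_snps >= 5 and r.min_p < 1e-30 and r.n_pubs >= 2}
    assert top_attribute_set(recs) == brute


def test_trait_overlap_counts(toy_records):
    counts = trait_overlap_counts(toy_records, ["SBP", "DBP", "PP"])
    assert counts == {("SBP",): 1, ("DBP", "SBP"): 1,
                      ("DBP", "PP", "SBP"): 1, ("DBP",): 1}
    assert sum(counts.values()) == 4  # every gene carries a named trait
    single = [GeneRecord("g", 1e-9, 1, 1, frozenset({"SBP", "DBP", "PP"}))]
    assert trait_overlap_counts(single, ["SBP", "DBP", "PP"]) == {
        ("DBP", "PP", "SBP"): 1}


def test_trait_overlap_equals_brute_force():
    rng = np.random.default_rng(3)
    names = ["SBP", "DBP", "PP"]
    recs = [GeneRecord(f"g{i}", 1e-9, 1, 1,
                       frozenset(t for t in names if rng.random() < 0.5))
            for i in range(60)]
    counts = trait_overlap_counts(recs, names)
    brute: dict = {}
    for r in recs:
        key = tuple(sorted(r.traits & set(names)))
        if key:
            brute[key] = brute.get(key, 0) + 1
    assert counts == brute


def test_egene_flags(toy_records):
    flags = flag_significant_egenes(toy_records)
    # g1: eGene in both tissues, significant only at its minimum (A)
    assert flags["g1"]["A"] == (True, True)
    assert flags["g1"]["B"] == (True, False)
    # g2: all q above 0.05 -> no eGene anywhere
    assert not any(f.egene for f in flags["g2"].values())
    # g3: tied minimum q -> significant in both tissues
    assert flags["g3"]["A"].significant and flags["g3"]["B"].significant
    # g4 has no eQTL data at all
    assert "g4" not in flags
    assert count_egenes(flags) == 2


def test_egene_validation():
    with pytest.raises(ValidationError):
        flag_significant_egenes([GeneRecord("g", 1e-9, 1, 1)])
    with pytest.raises(ValidationError):
        flag_significant_egenes(
            [GeneRecord("g", 1e-9, 1, 1, eqtl_q={"A": 1.2})])


def test_validate_table_rejects_bad_rows():
    with pytest.raises(ValidationError, match="duplicate"):
        validate_table([GeneRecord("g", 1e-9, 1, 1),
                        GeneRecord("g", 1e-9, 1, 1)])
    with pytest.raises(ValidationError, match="min_p"):
        validate_table([GeneRecord("g", 0.5, 1, 1)])  # above threshold
    with pytest.raises(ValidationError, match="n_snps"):
        validate_table([GeneRecord("g", 1e-9, 0, 1)])
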