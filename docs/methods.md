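# Methods

## Model and procedure

`gwasnet` treats disease-gene prioritization as the combination of one
evidence-based and two topology-based criteria over a reference
protein–protein interaction network.

**Integrated GWAS score.** The per-gene evidence is reduced to three
attributes: the minimum association p-value over the gene's significant
SNPs (capped at the genome-wide threshold, default 5×10⁻⁸), the number of
significant SNPs, and the number of independent supporting publications.
The score is a weighted sum of the three attributes after min–max range
normalization to [1, 100] over the analyzed table.  The p-value enters on
the log scale: normalizing raw p-values would collapse essentially every
gene onto the lower bound because the attribute spans 170 orders of
magnitude, so |log10 p| is the normalized quantity.  The weighted sums are
themselves rescaled to [1, 100] (`final_rescale`, default on) so that the
best-supported gene scores exactly 100 and the scale is comparable across
tables.  Default weights 0.45/0.35/0.20 reflect the relative reliability
of the three attributes in current GWAS reporting: p-values are the primary
signal; SNP counts are biased by the historical habit of reporting one
characteristic SNP per locus; publication counts are suppressed because
follow-up studies often omit known loci.

**Significance thresholds.** All prioritization cut-offs have the form
mean + k·SD over the analyzed values, with selection by ≥.  Criterion 1
uses the lenient k = 1; all network metrics use k = 1.5.  The SD is the
sample standard deviation (ddof = 1); the population variant is one
parameter away.

**BN/GN classification and RbSP extension.** GWAS proteins present in the
reference network are classified by the connected components of their
induced subgraph: the largest component is the BN ("blue node") core, the
rest are GNs.  A tie for the largest component is broken by the
lexicographically smallest member so the classification is deterministic.
For each GN *g* with BFS distance d(*g*) to the nearest BN, every interior
node of every length-d(*g*) path from *g* to any BN at that distance is
collected; interior nodes that are not themselves GWAS proteins become YNs
("yellow nodes").  Membership is decided by the distance criterion
dist_g(v) + dist_BN(v) = d(g), which exactly characterizes the nodes on
shortest paths; a `single` path policy (one deterministic path per GN,
lexicographic tie-breaks) is available for sensitivity analysis and always
yields a subset of the default.  GNs with no path to any BN are retained
and flagged.  The extended (RbSP) network is the reference subgraph induced
on BN ∪ GN ∪ YN; the fraction of GNs within two steps of the core is
reported as a diagnostic, not enforced.

**IVI.** The Integrated Value of Influence combines six centralities, each
min–max normalized to [1, 100] over the analyzed network:
(DC′+LH′)·((NC′+CR′)·(BC′+CI′)).  Definitions follow the metrics'
source literature: the local H-index is the node's own h-index over
neighbor degrees plus the sum of its neighbors' h-indices; ClusterRank is
10^(−c)·Σ(deg+1) over neighbors with c the local clustering coefficient
(0 below degree 2); betweenness is unnormalized with endpoints excluded
and each unordered pair counted once; collective influence is
(deg−1)·Σ(deg−1) over the BFS frontier at exactly radius 3 (the metric's
common default; configurable and recorded in output metadata).  The raw
product spans [8, 8×10⁴], so a final min–max rescale to [1, 100] presents
IVI on the conventional 1–100 scale.  Disconnected inputs are accepted;
unreachable pairs simply contribute nothing to the path-based terms.

**Criterion 3 and ranking.** YNs adjacent in the extended network to at
least two GWAS-prioritized proteins are selected together with the
prioritized proteins adjacent to at least one selected YN; the induced
subgraph on that node set (optionally restricted to YN–prioritized edges,
`star_only`) is IVI-ranked in isolation, and all its nodes count as
Criterion-3 prioritized.  The final ranking orders the union of the three
criteria sets by group: all three criteria; C1∧C3; C1∧C2; C2∧C3; C1 only;
C3 only; C2 only.  GWAS-backed pairs outrank purely network-backed pairs;
the C1∧C2 group sits between them as an extrapolation, since its occupancy
is empirically rare.  Within groups the ordering uses Criterion-3 IVI where
C3 membership is involved, the integrated score for C1-only, and RbSP IVI
otherwise — the only within-group signal each combination carries.  Any
remaining tie breaks lexicographically by protein id, so the ranking is a
strict total order.

**Enrichment.** Over-representation uses the upper-tail hypergeometric
probability P(X ≥ k) with universe N (default: all ids in the collection,
overridable), set size K and query size n, with Benjamini–Hochberg q-values
across all tested sets and zero-overlap sets reported at p = 1.  The EASE
mode subtracts one success (floored at 0) to reproduce the conservative
modified-Fisher statistic of the DAVID service; since that service's exact
universe is not reproducible, both modes are exposed and verification is
oracle-based (exact rational tail summation).  Pathways whose overlap is
more than 65% YNs are flagged: these are functional associations the GWAS
proteins alone would not have revealed.

## Numerical choices and degenerate inputs

* Degenerate min–max normalization (max = min, including single-element
  input) maps every value to the lower bound (1).  A consequence is that a
  fully symmetric network (e.g. a single edge) gets IVI = 1 everywhere.
* Threshold comparison is ≥, so a zero-variance score vector prioritizes
  everything.
* log base 10 throughout, following GWAS convention.
* eGene significance: a gene is an eGene in a tissue when its cis-eQTL
  q ≤ 0.05, and is flagged *significant* only in the tissue(s) attaining
  its minimum q over all tissues; ties flag all tied tissues.
* Genes mapping to several proteins carry their score to every mapped
  protein; several genes mapping to one protein leave it the maximum.
* Self-loops and duplicate edges are removed at load time and counted in
  the load report.
* The scale-free diagnostic regresses log10 P(k) on log10 k over observed
  degrees ≥ 1 with nonzero frequency; with fewer than three distinct
  degrees the fit is skipped with a warning.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the distributional shape of real GWAS attribute
tables: −log10 p = 7.301 + Exponential(mean 12), truncated at 179.3
(heavy upper tail above the genome-wide threshold, matching the strongest
reported associations); SNP counts 1 + NegativeBinomial(r = 0.5, mean 2)
(overdispersed, most genes with few SNPs); publication counts
1 + Poisson(0.4) (mean 1.4 — the single-publication-dominated skew of
real tables); trait labels drawn independently per gene with probabilities
0.6/0.4/0.35 for SBP/DBP/PP and a catch-all OTHER when none fires; and
three tissues whose q-values fall below 0.05 with probability 0.3.  The
reference network is preferential attachment (n = 2000, m = 3), chosen
over a configuration model because it is connected by construction and
reproduces the scale-free degree diagnostic (R² ≈ 0.85–0.9).

Planted signal defines the ground truth for recovery tests: 20 of 1000
genes draw from shifted upper tails (−log10 p ≥ 40, SNPs ≥ 20, pubs ≥ 5)
and map onto 20 GWAS proteins given extra mutual edges with probability
0.9 (a cohesive near-clique).  The GWAS protein set is a degree-stratified
sample of half the network, sized so the gene table maps 1:1 onto it; this
GWAS fraction is far above the real interactome's (~7%) to keep the study
small, and is one config field away.  Attribute correlations arise only
through shared planted status (no copula); eQTL q-values are independent
across tissues.  Passing recovery tests therefore shows the pipeline
detects jointly extreme, topologically cohesive signal against realistic
marginals — not that it handles LD structure, correlated tissues, or the
real interactome's size and ascertainment biases.

Recovery is asserted at Criterion-1 recall ≥ 0.9 of the planted genes and
≥ 0.9 of planted clique members inside the IVI top decile of the extended
network, at fixed seeds.

## Problem sizes

The default synthetic study (1000 genes, 2000-node network) runs the full
pipeline in a few seconds.  Oracle checks use 200 random graphs of ≤ 8
nodes for the six centralities, ten 50-node graphs for the shortest-path
extension, and the complete (N, K, n, k) grid up to N = 30 for the
hypergeometric tail (~46k comparisons, exact rational arithmetic).

## Known limitations

* The DAVID-style enrichment cannot reproduce the service's exact universe
  or FDR variant; both plain hypergeometric and EASE modes are offered.
* Only unweighted, undirected simple graphs are supported; confidence
  tiers of PPI sources must be resolved before loading.
* The per-gene input schema cannot recover SNP-level statistics (e.g. a
  per-SNP median p-value); only per-gene summaries are reported.
* The ranking's C1∧C2 group placement is an extrapolation (see above), as
  is any within-group ordering beyond the stated keys.
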