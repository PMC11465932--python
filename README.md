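# gwasnet

Disease-agnostic prioritization of GWAS candidate genes through the human
protein–protein interaction (PPI) network.

Genome-wide association studies report variant–trait associations for
hundreds of loci, but the underlying pathophysiology of a complex phenotype
emerges from interacting protein pathways rather than isolated genes.
`gwasnet` integrates a per-gene GWAS attribute table with a reference PPI
network to score, extend and rank the candidate protein set:

1. **Integrated GWAS score (Criterion 1).** Each gene *i* gets
   `s_i = w_p·|log10 p_i|′ + w_SNP·#SNPs_i′ + w_Pub·#Pubs_i′`, where ′
   denotes min–max range normalization to [1, 100] across the table and the
   default weights are 0.45/0.35/0.20 for the minimum association p-value,
   the significant-SNP count and the supporting-publication count.  The
   weighted sums are rescaled to [1, 100]; genes with
   `s ≥ mean(s) + 1·SD(s)` are prioritized.
2. **Network extension (RbSP).** GWAS proteins present in the reference
   interactome split into the largest connected component of their induced
   subgraph ("blue" nodes, BN) and the rest ("green" nodes, GN).  Interior
   nodes of all shortest paths from each GN to its nearest BN ("yellow"
   nodes, YN) extend the network: the RbSP interactome is the reference
   subgraph induced on BN ∪ GN ∪ YN.
3. **Composite centrality (Criterion 2).** Each node's Integrated Value of
   Influence `IVI = (DC′+LH′)·((NC′+CR′)·(BC′+CI′))` combines degree,
   local H-index, neighborhood connectivity, ClusterRank, betweenness and
   collective influence, each normalized to [1, 100]; nodes with
   `IVI ≥ mean + 1.5·SD` are prioritized.
4. **Common neighbors (Criterion 3).** YNs adjacent to at least two
   GWAS-prioritized proteins, plus those proteins, form a subnetwork whose
   members are prioritized and IVI-ranked within it.
5. **Ranking.** The union of the three criteria sets is ordered by groups
   (all three; C1∧C3; C1∧C2; C2∧C3; C1 only; C3 only; C2 only), with the
   relevant score ordering members within each group.
6. **Enrichment.** Hypergeometric (or EASE) over-representation of any
   protein set against GMT gene-set collections with BH FDR, flagging sets
   whose overlap is dominated (>65%) by network-deduced YNs.

A synthetic-data module generates coupled gene tables, scale-free networks,
eQTL panels and planted ground truth with the statistical structure the
pipeline assumes, so every step is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study; each
is a thin driver over the library:

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_score_genes.py
python analysis/03_build_interactome.py
python analysis/04_prioritize_proteins.py
python analysis/05_enrich_pathways.py
```

With seed 1 this prints, among other lines:

```
criterion-1 threshold: 19.35
prioritized genes: 47 of 1000; planted recovered: 20/20
BN core: 928; GN: 72; YN intermediates: 157; unreachable GNs: 0
extended network scale-free fit: R^2 = 0.86 (slope -1.61)
criteria sizes: C1=47 C2=12 C3=24; union=65
criterion-1 recall of planted genes: 1.00 (precision 0.43)
planted clique members in the IVI top decile: 20/20
1 of 21 sets enriched at q < 0.05
  PLANTED: k=20/20, q=4.84e-04, fold=1.68, YN fraction=0.00
```

Reading: all 20 planted high-signal genes clear the Criterion-1 cut-off of
19.35 (on the 1–100 score scale); the GWAS-protein subgraph has a 928-node
connected core which the shortest-path extension connects to every detached
GN through 157 intermediates; every member of the planted 20-protein clique
lands in the top decile of IVI; and the planted module is the only
significantly enriched gene set.

The same steps are available as a CLI
(`gwasnet simulate|score|network|extend|ivi|criterion3|rank|enrich|run-all|validate`)
for use on real data: a TSV gene table (`gene_id`, `min_p`, `n_snps`,
`n_pubs`, optional `traits` and `q_<tissue>` columns), a two-column TSV or
SIF edge list, a gene→protein map and a GMT file.  All settings live in one
YAML config; `src/gwasnet/data/paper_defaults.yaml` holds the defaults.

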