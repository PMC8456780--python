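# scellintegrate

Batch integration for multi-sample single-cell RNA-seq, supervised by
cross-sample cluster matching — plus the statistics that surround it:
combined marker-gene tests, preranked gene set enrichment, rank-AUC lineage
scoring, and batch-mixing metrics. The package targets analyses of
heterogeneous compartments profiled across many donors or tissues (the
motivating case is hematopoietic stem/progenitor cells, where samples share
most cell types but some types exist in only a subset of samples), and it
ships a fully seeded multi-batch count simulator so every stage can be
validated against planted ground truth without any external data.

## The method

Standard soft-clustering batch correction (Harmony-style) mixes batches by
penalizing clusters whose batch composition deviates from the global one.
When a cell type is present in only some batches, that pressure can smear
the unique type into shared clusters. `scellintegrate` adds a supervision
step built from the data itself:

1. **Per-sample clustering.** Each sample is processed alone: library-size
   normalization to 10,000 counts with `log1p`, Brennecke-style
   variable-gene selection (gamma GLM of CV² against 1/μ), PCA, a cosine
   kNN graph reweighted by shared-neighbor counts, Louvain communities.
2. **Marker statistics.** Each cluster vs. the rest, per gene: a two-sided
   Wilcoxon rank-sum test on log-normalized expression and Fisher's exact
   test on expressing-cell frequency, combined by Fisher's method
   (−2Σln p ~ χ²₄) and BH-adjusted. Markers require |log2FC| ≥ 1.5,
   adjusted p < 0.05, expressing frequency > 0.3.
3. **Cluster matching by GSEA.** The top markers of every (sample, cluster)
   become a gene set; every cluster's ranked gene list
   (score = log2FC · −log10 p_adj) is tested against every set by preranked
   GSEA (weighted Kolmogorov–Smirnov running sum, gene-label permutation
   null). Positive, significant NES values form a square cluster-matching
   matrix; average-linkage hierarchical clustering with a
   silhouette-selected tree cut groups per-sample clusters into
   **meta-clusters**, flagged *common* (≥ 2 samples) or *unique*.
4. **Prior-aware correction.** Each cell gets a prior probability vector
   concentrated (w = 0.9) on its own meta-cluster. The correction then
   iterates soft assignment of cells to K = #meta-clusters centroids under
   cosine distance — multiplied by the batch-diversity factor
   ((E+1)/(O+1))^θ *and* by prior^w — with per-cluster ridge regression
   removing batch/covariate effects from the embedding. With a uniform
   prior the procedure reduces exactly to the unsupervised correction.

Quality is quantified with kBET (χ² test of local vs. global batch
composition, reported as acceptance rate), iLISI (inverse Simpson index of
batch labels in perplexity-weighted neighborhoods; higher = better mixed)
and cLISI (same for cell-type labels; lower = purer).

## Worked example

`examples/03_supervised_integration.py` simulates three batches of 400
cells: four cell types shared by all batches, a fifth present only in
batch 3, per-gene multiplicative batch effects, negative-binomial counts.

```
$ python examples/03_supervised_integration.py
5 meta-clusters from 13 per-batch clusters:
  batch1|0 -> meta 2 (common)
  ...
  batch3|0 -> meta 4 (unique)
  ...
median iLISI (batch mixing, 1..3): 1.02 -> 2.59
median cLISI (type purity, best 1): 1.00 -> 1.00
```

The 13 per-batch Louvain clusters collapse into exactly 5 meta-clusters;
the batch-3-only type is flagged *unique* and is not merged into any shared
cluster. After correction the median batch iLISI rises from 1.02 (batches
fully separated) to 2.59 (close to the theoretical 3 for three perfectly
mixed batches... the unique type caps it below 3), while cLISI stays at
1.00 — mixing was achieved without blending cell types.

The other examples cover simulation + per-sample clustering (`01`), marker
statistics (`02`), lineage scoring (`04`, AUCell-style rank-AUC with the
0.15 classification threshold) and the integration metrics on toy
embeddings (`05`). A thin CLI mirrors the library
(`scellintegrate simulate|preprocess|cluster|integrate|score|metrics|run-all`).

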