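# somportrait

Self-organizing-map (SOM) transcriptome portrayal for bulk RNA-seq cohorts,
with transfer of the learned subtype structure onto sparse (nanopore-like)
expression profiles.

The package targets the analysis style used to stratify chronic lymphocytic
leukemia (CLL) cohorts: expression profiles of tens of thousands of genes are
compressed onto a 2-D grid of *metagenes*, each sample's metagene activation
becomes a heatmap *portrait*, co-expressed gene modules appear as contiguous
*spots* on the grid, and samples are grouped into *pattern types* (PATs) by
the combination of spots active in their portraits. Spot activity is then
linked to clinical phenotypes by per-metagene categorical regression and to
outcome by Kaplan–Meier / Cox survival analysis, and a per-metagene support
vector regression layer (supSOM) projects new samples — measured on only a
few thousand high-expressed genes, as shallow nanopore cDNA libraries are —
into the trained SOM space so they can inherit a PAT label.

## Model sketch

* **Portrayal.** Genes are points in R^n (one coordinate per sample, after
  ComBat batch adjustment, log2(TPM+1), quantile normalization and gene-wise
  centering). A batch SOM with Gaussian neighborhood and PCA-plane
  initialization clusters them into an `r × c` grid (default 50 × 50 = 2,500
  metagenes); the codebook row of unit *m* is the mean profile of its genes.
  Sample portraits are codebook columns reshaped onto the grid.
* **Spots.** A summary map (per-cell variance or maximum over portraits) is
  thresholded at a map quantile; connected high regions — watershed-split at
  distinct peaks and boundary-refined by codebook correlation — become spots
  A, B, … with their member genes. Spot annotation uses the one-sided
  hypergeometric test P(X ≥ overlap) against a GMT gene-set collection with
  Benjamini–Hochberg q-values.
* **PATs.** A sample is *active* in a spot when its mean portrait value over
  the spot's cells exceeds τ = 0 (above the cohort mean). Samples sharing an
  active-spot combination form a PAT (label = sorted spot letters + `*`);
  rare combinations merge into the best-correlated anchor PAT.
* **Phenotype maps.** For a categorical clinical variable, each metagene is
  regressed on the category indicators without intercept, so each category's
  coefficient is exactly its mean metagene value; coefficient and p-value
  grids are read as phenotype portraits. Survival uses lifelines
  (product-limit curves, log-rank, Cox with Efron ties), stratified by
  gender × spot activation × PAT.
* **supSOM.** For every metagene, an ε-SVR (RBF kernel) predicts its value
  from the sample's expression of common genes whose best-matching unit lies
  within Chebyshev radius 4 of that metagene. Metagenes with no common gene
  in reach stay masked (white). Predicted portraits are assigned to the PAT
  whose mean portrait has the highest Pearson correlation of red/blue
  channel renderings.

A built-in simulator generates multi-cohort TPM matrices with planted
co-expression modules, batch effects, correlated clinical covariates,
proportional-hazards survival and a degraded nanopore-like companion
dataset, so the whole chain is testable without external downloads.

## Worked example

```bash
somportrait simulate --out demo/sim --n-genes 2000 --n-samples 150 --seed 3
somportrait portray --config demo/cfg.yaml \
    --expression demo/sim/expression.tsv \
    --annotation demo/sim/annotation.tsv --out demo/run --seed 3
somportrait project --train demo/sim/expression.tsv \
    --query demo/sim/expression_nanopore.tsv --out demo/run --seed 3
```

with `demo/cfg.yaml` holding a grid sized for 2,000 genes
(`grid_rows: 16`, `grid_cols: 16`, `epochs: 20`,
`spot_threshold_quantile: 0.9`, `spot_min_cells: 3`). The portray step
prints

```
256 metagenes, 6 spots, 7 PATs -> demo/run
```

— the 16 × 16 grid yields 256 metagenes, segmentation finds the six planted
co-expression modules as spots A–F, and the samples fall into seven pattern
types. `demo/run/pats.tsv` lists each sample's active spots and PAT label
(e.g. `s0000  DE  DE*`), and `demo/run/spots.tsv` the per-spot cell and gene
counts (e.g. spot A: 6 cells, 69 genes). The project step harmonizes the
shallow nanopore-like table with the reference (gene intersection, ComBat,
quantile normalization), fits the supSOM regressors, and prints per-query
assignments such as

```
ont_s0148   ACE*   0.965
ont_s0149   BEF*   0.941
```

i.e. sample `ont_s0148` is assigned PAT `ACE*` with channel correlation
0.97 to that PAT's mean portrait. Since the query here is a degraded twin
of the reference cohort, assignments can be checked against the reference
PATs — in this run all 150 query samples receive their reference label.

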