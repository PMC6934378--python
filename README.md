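# scrobust

Permutation-calibrated clustering and batch-robust cluster matching for
multi-replicate single-cell RNA-seq.

## The problem

Droplet scRNA-seq studies of T cell states — for example tumor-infiltrating
CD4⁺ T cells profiled alongside draining-lymph-node and acute-infection
reference cells, each tissue in two biological replicates — face two coupled
questions:

1. **At what resolution should each dataset be clustered?** KNN-graph
   community detection (the Phenograph recipe) reports high modularity even
   on structureless data, because cell-level coverage differences alone
   create graph structure.
2. **Which clusters correspond across datasets?** Tissue- and batch-specific
   expression shifts dominate raw expression distances, so naive matching
   groups clusters by batch instead of by cell state.

`scrobust` implements a pipeline that answers both: the clustering
resolution is calibrated against a within-cell permutation null, and
clusters are matched across datasets by the Pearson correlation of their
fold-change fingerprints, which cancels dataset-wide multiplicative effects.

## The method

Per dataset (tissue × replicate):

- **QC**: remove cells with < 500 detected genes; cells with detected genes
  or total UMIs strictly above the 98th sample quantile (doublets); and
  cells with > 10% of reads on 13 mitochondrial genes.
- **Normalization**: `norm_ji = ln(1 + 10⁴ · raw_ji / LS_j)`, with `LS_j`
  the library size of cell *j*.
- **Confound control** (optional): score an activation signature (e.g. the
  transcriptomic imprint of tetramer-based sorting on the TCR pathway)
  against background-matched control genes — the 10 nearest non-signature
  genes in (mean, variance) space per signature gene — and regress the
  score out of every gene.
- **Features**: highly variable genes by binned dispersion (z > 1 within
  equal-frequency mean-expression bins), then PCA; a gene-permutation test
  identifies components whose explained variance beats the rank-matched
  null.
- **Resolution selection**: for each KNN parameter *k*, compare the observed
  Louvain modularity *O_k* against *S_k*, the mean modularity of the same
  analysis on matrices whose values were permuted within each cell. Choose
  the highest-resolution *k* with *O_k/S_k* ≥ 2; report "none" when no *k*
  qualifies.
- **Contaminant purge**: drop clusters with high CD79⁺ (B cell) marker
  detection and cells scoring extremely on marker-driven components, then
  repeat the processing.

Across datasets:

- **Fingerprints**: per cluster *c* and gene *g*,
  `FC_gc = ⟨norm_g⟩_c / ⟨norm_g⟩_not-c` within the same dataset.
- **Matching**: Pearson correlation of log-FC vectors for all cross-dataset
  cluster pairs; a cluster is **robust** when its best replicate match
  exceeds the dataset's mean correlation by ~1.28 SD (upper-tail normal
  quantile at p = 0.1).
- **Meta-clustering**: average-linkage hierarchical clustering of robust
  clusters on 1 − r, so states group across tissues; the Euclidean distance
  between mean-expression vectors is kept as the contrast baseline (it
  groups by tissue when batch effects dominate).
- **Differential expression**: limma-style two-group moderated t-tests
  (empirical-Bayes variance shrinkage); cluster-defining genes must pass
  fold change > 1.25 and BH Q < 0.1 **independently in both replicates**,
  and subpopulation signatures additionally require a detection-rate
  difference.

A synthetic-cohort generator (`scrobust.synthetic`) produces multi-tissue,
multi-replicate UMI matrices with planted programs, per-dataset per-gene
batch factors, lognormal library sizes, doublets, mitochondrial
contamination, CD79⁺ contaminants and an activation-like confound, with full
ground truth — every stage of the pipeline is tested against it.

## Worked example

```python
import numpy as np
from scrobust import (CohortConfig, generate_cohort, filter_cells, normalize,
                      select_resolution, fold_change_vectors, correlate_clusters,
                      call_robust_clusters, meta_cluster)

cfg = CohortConfig(n_datasets=2, replicates_per_dataset=2, cells_per_dataset=600,
                   n_genes=1000, n_programs=4, batch_sd=0.8, seed=0)
cohort = generate_cohort(cfg)
profiles, by_ds = [], {}
for matrix, truth in cohort:
    filtered, report = filter_cells(matrix)
    norm = normalize(filtered)
    scan = select_resolution(norm, k_grid=[10, 20], n_shuffles=5, seed=0)
    print(f"{truth.dataset}: {report.n_retained}/{report.n_input} cells pass QC, "
          f"chosen k={scan.chosen_k}, {scan.chosen.n_clusters} clusters")
    ps = fold_change_vectors(norm, scan.chosen, dataset=truth.dataset)
    profiles += ps
    by_ds[truth.dataset] = ps

matches = correlate_clusters(by_ds["tissue0_rep1"], by_ds["tissue0_rep2"])
robust = call_robust_clusters(matches)
print(f"tissue0: {int(robust.sum())}/{len(robust)} clusters robust")
meta = meta_cluster(profiles, cut=4)
```

Output:

```
tissue0_rep1: 574/600 cells pass QC, chosen k=20, 4 clusters
tissue0_rep2: 572/600 cells pass QC, chosen k=20, 4 clusters
tissue1_rep1: 569/600 cells pass QC, chosen k=20, 4 clusters
tissue1_rep2: 573/600 cells pass QC, chosen k=20, 4 clusters
tissue0: 6/8 clusters robust
```

Each of the four datasets is clustered at the permutation-calibrated
resolution (k = 20 here, with observed/null modularity ratios ≈ 2.3) and
recovers the four planted programs. Cross-replicate FC correlation calls
most clusters robust, and the meta-clustering groups the 16 cluster
fingerprints into 4 meta-clusters that each contain one cluster per dataset
— i.e. the same cell state found in every tissue and replicate, despite
per-dataset batch factors with SD 0.8 on every gene.

The same pipeline is available from the shell:

```sh
scrobust simulate --out fixtures --seed 0 --datasets 2 --cells 600
scrobust run-all --config pipeline.yaml
scrobust report out/
```

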