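# snclock

Circulating small-noncoding RNAs (miRNA, tRNA fragments, piRNA, snRNA,
snoRNA, scRNA) shift in abundance as people age, and their cell-free
expression profiles in plasma and serum can be turned into an *aging clock*:
a regression model that predicts a donor's chronological age from an exRNA
count matrix. `snclock` implements that analysis end to end for
transcriptomics researchers working with blood exRNA-seq cohorts:

1. **Sample QC** — keep samples with ≥ 100,000 transcriptome-aligned reads
   and a transcriptome/total read ratio strictly above 0.5.
2. **Normalization** — counts-per-million over TMM-scaled effective library
   sizes (trimmed mean of M-values, the edgeR default; verified against it).
3. **Detection filters** — "expressed" (≥ 1 CPM in ≥ 30% of an age group)
   and "highly expressed" (≥ 10 CPM) gene sets, plus biotype composition
   summaries across young (20–30), adult (31–60) and aged (61+) donors.
4. **Batch correction** — parametric empirical-Bayes location/scale
   adjustment (the ComBat model, verified against sva) on log2(CPM + 1),
   with a principal-component diagnostic of batch structure before/after.
5. **Age-association screening** — a from-scratch implementation of the
   maximal information coefficient: for every grid shape (k × l) within the
   budget B(n) = ⌈n^0.6⌉, the mutual information of the induced
   discretization is maximized over grid placements (clump-merging dynamic
   program) and normalized by log min(k, l). MIC is the largest entry, TIC
   the mean entry; genes with MIC ≥ 0.7 **and** TIC ≥ 0.7 against age are
   retained. MIC − ρ² (ρ² the squared Pearson correlation) flags nonlinear
   relationships.
6. **Clock fitting** — linear regression, elastic net, AdaBoost, gradient
   boosting and random forest regressors, evaluated by age-group-stratified
   fivefold cross-validation (R², RMSE, MAE in years), with impurity-based
   feature importances normalized to sum to 1, plus a male↔female
   cross-prediction mode.
7. **Consensus** — per-method importance ranks (1 = most important) summed
   into a rank-sum score; genes ranked by all three ensembles with the
   smallest sums are the *core* age-related sncRNAs.

A synthetic-cohort generator with full ground truth (ages 20–99, multiple
batches with location/scale effects, six biotypes, an age-linked gene
minority with linear/saturating/quadratic/step relationships,
negative-binomial counts over log-normal library sizes, and an optional
miRNA-down/tRNA-up composition drift with age) makes every stage testable
without any data download.

## Worked example

Run the whole pipeline on a simulated 300-donor cohort:

```sh
snclock run --outdir demo --seed 7
```

which prints (abridged):

```
snclock run report
==================
status: PASSED
  simulate   PASSED   {'mode': 'simulate', 'genes': 1000, 'samples': 300}
  qc         PASSED   {'retained': 300, 'removed': 0}
  normalize  PASSED   {'tmm': True}
  detect     PASSED   {'expressed': 1000}
  correct    PASSED   {'pc1_batch_r2_before': 0.0647, 'pc1_batch_r2_after': 0.0}
  screen     PASSED   {'tested': 1000, 'selected': 4}
  clock      PASSED   {'methods': 5, 'features': 4}
  consensus  PASSED   {'core': 4}

clock metrics (out-of-fold averages):
                       r2    rmse     mae
method
linear_regression  0.9701  4.0789  3.2529
elastic_net        0.9485  5.3519  4.1334
adaptive_boosting  0.9565  4.9283  3.8730
gradient_boosting  0.9609  4.6529  3.6035
random_forest      0.9611  4.6401  3.6242

top core age-related genes (rank sum ascending):
            adaboost  gb  rf  in_all_three  rank_sum  core
gene_id
snRNA_0080         1   1   1          True         3  True
miRNA_0296         2   2   2          True         6  True
snRNA_0011         3   3   4          True        10  True
miRNA_0266         4   4   3          True        11  True
```

Reading the output: the batch diagnostic shows the share of PC1 variance
explained by batch label before and after correction; `selected` is the
number of genes passing the dual MIC/TIC ≥ 0.7 screen against age; the clock
metrics are out-of-fold averages over the stratified folds (R² near 0.96
with errors of ~4 years, from only four selected features here); and the
consensus table sums each gene's importance rank across the three ensembles
— `snRNA_0080` is rank 1 in all three, the smallest possible rank sum of 3.

Every stage is also a library call (`snclock.qc_filter`, `tmm_factors`,
`cpm`, `detection_filter`, `combat_cpm`, `screen`, `fit_predict_cv`,
`rank_sum_core`, ...) and a CLI subcommand (`simulate`, `qc`, `normalize`,
`correct`, `screen`, `clock`, `consensus`, `run`, `report`); intermediate
artifacts are plain tab-delimited text.

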