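# samgsr — gene-set-guided feature selection for two-class expression data

Diagnostic signatures built from microarray or RNA-seq expression data have
to cope with tens of thousands of genes and a few dozen samples. One way to
tame that imbalance is to let curated pathway knowledge (MSigDB-style gene
sets) steer the search: first find the gene sets whose joint expression
separates the two phenotype classes, then pick individual genes only from
inside those sets. This package implements two such pipelines for binary
phenotypes (diseased vs. control), together with the evaluation metrics and
a ground-truth synthetic-data generator:

* **SAM-GSR** (significance analysis of microarray — gene-set reduction):
  score every gene set with the SAM-GS permutation statistic, then peel
  each significant set down to a *core subset* by removing genes in order
  of significance until the residual set is no longer significant; a plain
  linear SVM on the pooled cores classifies samples.
* **Modified SAM-GSR**: keep the SAM-GS screening step, but replace the
  per-set reduction with a single sparse classifier — a linear SVM with a
  SCAD (smoothly clipped absolute deviation) penalty — fitted on the union
  of all member genes of significant sets, so that gene selection hinges on
  each gene's contribution to the separating hyperplane.

## The statistics

For gene *i* with group means x̄_d(i), x̄_c(i) and SAM-convention pooled
standard deviation s(i), the moderated statistic is

    d_i = (x̄_d(i) − x̄_c(i)) / (s(i) + s₀),

with s₀ a small fudge constant protecting low-variance genes. A gene set
*j* scores

    SAMGS_j = Σ_{i ∈ j} d_i² ,

whose significance comes from shuffling phenotype labels (the same shuffles
serve every gene and set). In the reduction step, genes are ordered by
their permutation p-values; c_k, the set-level p-value of the residual
after removing the top k genes, is computed on the *stored* shuffles, and
the core subset is the shortest prefix whose removal de-significates the
set. The c_k cutoff is tuned on a grid (0.05–0.50) by SVM training error.

The modified pipeline minimizes

    Σ_i (1 − y_i f(x_i))₊ + Σ_g p_λ(w_g),     f(x) = Σ_g w_g x_g + b,

where p_λ is the SCAD penalty (LASSO-like near zero, constant beyond
α·λ, α = 3.7), solved by local linear approximation over weighted-L1 hinge
linear programs, with λ tuned by stratified 5-fold cross-validation over
2⁻⁸ … 2¹⁴. Classifiers are scored with four metrics: misclassification
error, Generalized Brier Score, Belief Confusion Metric, and area under
the precision–recall curve.

## Worked example

```python
from samgsr import (shared_marker_config, simulate, msamgsr_select, evaluate)

cfg = shared_marker_config(seed=7)          # 5 markers at 2 SD, 3 carrier sets
ds, sets, markers = simulate(cfg)           # 1000 genes x 60 samples
print("true markers:", markers)

result = msamgsr_select(ds, sets, B=500, seed=7)
print("significant sets:", result.significant_sets)
print("selected:", result.selected_genes, "at lambda =", result.model.lam)

test, _, _ = simulate(shared_marker_config(seed=8))   # independent draw
print(evaluate(result.predict_beliefs(test)))
```

prints

```
true markers: ['g0001', 'g0002', 'g0003', 'g0004', 'g0005']
significant sets: ['S01', 'S02', 'S03']
selected: ['g0001', 'g0002', 'g0004', 'g0005'] at lambda = 16.0
{'error': 0.11666666666666667, 'gbs': 0.1054579509209808,
 'bcm': 0.8702975606764838, 'aupr': 0.9625319341094134}
```

The screen finds exactly the three marker-carrying sets; the SCAD-SVM keeps
four of the five true markers (the fifth is redundant for this draw's
separating hyperplane — correlated markers carry overlapping information)
and no noise gene, and the model transfers to an unseen draw with about 12%
error and a true-class belief of 0.87.

The same pipelines are available from the shell (`samgsr --help`), with
subcommands `samgsr`, `msamgsr`, `compare`, `simulate` and `evaluate`;
every run writes a JSON manifest so outputs are reproducible from the
recorded seed.

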