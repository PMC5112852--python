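# Methods

## Scope and model

The package operates on a genes × samples matrix of log2-scale expression
values with a binary phenotype (coded +1 diseased / −1 control) and a
collection of named gene sets. Both pipelines assume: expression has been
normalized upstream (no background correction, quantile normalization or
batch adjustment is performed here); each class has at least two samples;
missing values are a hard error rather than being imputed. Probe-level
data are collapsed to gene level beforehand by keeping, per gene, the
probe with the largest absolute between-group difference of means on the
log scale (ties to the lexicographically smallest probe id, so builds are
deterministic).

## SAM-GS screening

The per-gene statistic d_i = (x̄_d − x̄_c)/(s + s₀) uses the SAM
convention for the pooled standard deviation,
s = sqrt((1/n_d + 1/n_c)(SS_d + SS_c)/(n_d + n_c − 2)), and a fudge
constant s₀ ≥ 0 that keeps low-variance genes from dominating. s₀ defaults
to the 5th percentile (numpy linear-interpolation quantile) of the
per-gene pooled SDs — a deterministic stand-in for SAM's
coefficient-of-variation tuning, which is deliberately out of scope; a
fixed value can be supplied instead. The set statistic is
SAMGS_j = Σ d_i² over members.

Significance comes from label shuffles. B = 500 shuffles by default; when
the number of distinct label assignments is at most 10,000 the
implementation switches to exhaustive enumeration and reports exact
proportions (identity assignment included). Monte-Carlo p-values use the
add-one convention (1 + #{null ≥ observed})/(B + 1), so they can never be
zero and their floor 1/(B+1) bounds how small a usable significance
threshold can be. s₀ is re-chosen inside every shuffle by default (labels
change the pooled SDs); reusing the observed s₀ is available as a flag for
speed. One shuffle set serves all genes and sets, and the per-shuffle
d-matrix is retained so the reduction step scores residual subsets against
the identical null sample — this makes the whole reduction deterministic
given the draw. Sets are declared significant at raw permutation
p ≤ 0.05 by default; a Benjamini–Hochberg mode is available and the choice
is recorded in the run manifest.

## Reduction to core subsets

Within each significant set, genes are ordered by ascending permutation
p-value of |d| (ties: larger |d| first, then gene id). For k = 1, 2, …,
c_k is the stored-permutation p-value of the residual after removing the
top k genes; the core subset is the smallest k whose residual exceeds the
cutoff, or the whole set if none does. The c_k sequence is *not* assumed
monotone — each c_k compares a different statistic against its own null —
so the scan is strictly sequential and stops at the first crossing. The
cutoff is tuned over 0.05, 0.10, …, 0.50: for each value, the union of
core subsets across significant sets is scored by the training error of a
plain linear SVM (unit cost, features standardized on training data);
minimum error wins, ties broken by fewer pooled genes, then by the smaller
cutoff. The final classifier is the same plain SVM refitted on the winning
union. The gene ordering is computed once per set, not re-derived after
each removal.

## SCAD-penalized SVM

The modified pipeline pools all member genes of significant sets
(one feature per gene regardless of how many sets carry it) and fits a
linear SVM with per-coefficient SCAD penalty: λ|w| for |w| ≤ λ, a
quadratic blend on (λ, αλ], constant (α+1)λ²/2 beyond. α = 3.7, the
standard default. The hinge term is an unscaled sum, matching the
objective as written; the λ grid 2⁻⁸ … 2¹⁴ is wide enough to absorb that
convention.

The nonconvex objective is minimized by local linear approximation: the
penalty is linearized at the current |w|, giving a weighted-L1 hinge
problem that is solved *exactly* as a linear program (HiGHS). Because SCAD
is concave in |w|, the linearization majorizes the objective, so the true
objective is non-increasing across iterations (tracked in the model; a
violation is a bug). Numerical choices: initialization from the L1 SVM at
the same λ (the LP with all weights λ); convergence when max|Δw| < 1e-4;
at most 50 outer iterations (non-convergence returns the last iterate with
a warning flag); weights below 1e-6 snapped to exactly zero; the intercept
is never penalized; features are standardized internally (the penalty is
scale-sensitive) and the constants travel with the model. λ is chosen by
stratified 5-fold CV on misclassification error, ties toward the larger λ
(the sparser model). One consequence of the LP geometry worth knowing: on
linearly separable training data the subproblem returns a minimal-norm
vertex, so groups of mutually correlated informative genes are represented
by a subset rather than all members — parsimony trades against exhaustive
marker recovery.

## Class beliefs and metrics

Both final models produce class-+1 beliefs by Platt scaling: a logistic
fit (lightly regularized, on the 1-D training decision values) gives
p(+1|f) = σ(a·f + c); the logit is clipped to ±30 so beliefs stay strictly
inside (0, 1) in double precision. Metrics on an n × K belief matrix:

* error rate — argmax-belief class vs. truth (ties to the first class);
* GBS = (1/2n) Σ_ik (Y_ik − p_ik)², 0 perfect, 1 maximally wrong;
* BCM — mean belief assigned to the true class, macro-averaged over
  classes. The source challenge publishes no closed form; this literal
  "average belief in the true class" reading is an interpretation and is
  flagged as such;
* AUPR — per-class average precision (step-curve convention, which avoids
  the overestimate of trapezoidal PR interpolation), macro-averaged; tied
  beliefs are ranked in sample order with a warning rather than
  tie-averaged.

## Synthetic data

The generator emulates log-scale two-group expression with set-structured
differential signal: gene values are σ-scaled Gaussians, within-set
correlation ρ enters through a shared per-set standard-normal factor
(value = √ρ·factor + √(1−ρ)·noise, preserving unit marginal variance
before σ), and each marker gene gains a mean shift δ in the diseased class
only. A gene in several sets takes the factor of the first set containing
it; genes in no set are independent. Defaults define the package's
reference scenario: n = 30 + 30 samples, 1000 genes, 10 sets of 10 genes
of which 3 carry all 5 markers, δ = 2σ, ρ = 0.2, σ = 1 (log2 units) —
sample sizes and effect magnitudes typical of the case-control microarray
studies this method targets, with ρ = 0.2 a modest within-pathway
co-expression. Named presets vary the markers' set membership
(many sets / one set / no set / pure null) to probe the structural
property that set-guided selection cannot find markers outside the
collection.

What the generator does **not** emulate: heavy-tailed or count-based
noise, gene-specific variances, correlated *between*-set structure, batch
effects, or class-imbalanced designs beyond what n_per_class encodes.
Passing tests therefore demonstrate correctness of the algorithms under a
clean Gaussian factor model, not robustness to real microarray artifacts.

Per-gene variance fluctuates with sampling noise (SD ≈ σ²·√(2/n)), so the
generator's variance guarantee is checked as the mean per-gene variance
(within 10% of σ²) rather than gene-by-gene.

## Problem sizes

Simulation-backed checks use the reference scenario at 1000 genes and
n = 60 with B = 200 shuffles and 20 replicate seeds; oracle-equivalence
checks run on tiny matrices (G ≤ 20, n ≤ 12) where exhaustive enumeration
and naive per-gene loops are feasible; the null-calibration check uses 200
replicate datasets at B = 199. The acceptance script uses 10 recovery and
30 null replicates. These sizes are the package's reference conditions and
are recorded in each run's manifest.

## Known limitations

* Strictly two-class phenotypes; no survival or multi-class support.
* SAM's full s₀ tuning and its order-statistic FDR machinery are not
  implemented; s₀ is a quantile rule.
* The reduction's single fixed gene ordering follows the single-pass
  description; implementations that re-rank after each removal would
  differ on sets with near-tied genes.
* BCM/AUPR per-class weighting is macro-averaging by interpretation (see
  above).
* With strongly correlated markers the SCAD-SVM keeps a representative
  subset rather than every marker (see the LP geometry note); sensitivity
  for *individual* markers is accordingly below 1 even at large effects.
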