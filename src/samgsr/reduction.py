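"""Gene-set reduction: peel each significant set down to its core subset.

Member genes are ordered by increasing SAM-statistic permutation p-value
(ties: larger |d| first, then gene id). For k = 1, 2, ... the residual set
(everything after the first k genes) gets a set-level permutation p-value
c_k on the SAME stored label shuffles used for the original significance
call. The core subset R_k is the shortest prefix whose removal leaves a
non-significant residual: the smallest k with c_k > cutoff, or the whole
set if no residual ever loses significance.

The cutoff doubles as the method's tuning parameter: over a grid
(default 0.05 ... 0.50 step 0.05) each candidate cutoff's pooled core genes
are scored by the training error of a plain linear SVM, choosing minimal
error, then fewest genes, then smallest cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_genesets import ExpressionDataset, GeneSetCollection
from .samgs import (
    DEFAULT_B,
    DEFAULT_SET_P_THRESHOLD,
    SamGsResult,
    child_seed,
    permutation_null,
    significant_sets,
)

DEFAULT_CK_GRID: tuple[float, ...] = tuple(round(0.05 * k, 2) for k in range(1, 11))


@dataclass(frozen=True)
class ReductionTrace:
    """Record of one set's reduction: ordering, c_k sequence, chosen core."""

    set_id: str
    ordered_genes: list[str]
    ck_sequence: list[float]      # c_k for k = 1 .. |j|-1 (as far as computed)
    chosen_k: int
    cutoff: float

    @property
    def core_subset(self) -> list[str]:
        return self.ordered_genes[: self.chosen_k]

    @property
    def residual(self) -> list[str]:
        return self.ordered_genes[self.chosen_k:]


def order_genes(set_id: str, members: list[str], result: SamGsResult) -> list[str]:
    """Significance order: ascending gene p, then descending |d|, then id."""
    gene_p = result.sam.gene_p
    d = result.sam.d
    return sorted(members, key=lambda g: (gene_p[g], -abs(d[g]), g))


def reduce_set(set_id: str, result: SamGsResult, cutoff: float,
               coll: GeneSetCollection) -> ReductionTrace:
    """Peel one set to its core subset at the given c_k cutoff.

    Residual p-values reuse the stored permutations, so the trace is a
    deterministic function of the original permutation draw. The c_k
    sequence need not be monotone (removing the most significant gene can
    raise or lower the residual's rank against its own null).
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    members = coll.members(set_id)
    if len(members) < 2:
        raise ValueError(f"set {set_id!r} has fewer than 2 genes")
    ordered = order_genes(set_id, members, result)
    ck: list[float] = []
    chosen_k = len(ordered)
    for k in range(1, len(ordered)):
        residual = ordered[k:]
        c_k = result.pvalue_for_genes(residual)
        ck.append(c_k)
        if c_k > cutoff:
            chosen_k = k
            break
    return ReductionTrace(set_id=set_id, ordered_genes=ordered,
                          ck_sequence=ck, chosen_k=chosen_k, cutoff=cutoff)


def _union_preserving_order(gene_lists: list[list[str]]) -> list[str]:
    seen: dict[str, None] = {}
    for genes in gene_lists:
        for g in genes:
            seen.setdefault(g)
    return list(seen)


def _plain_svm():
    # linear kernel, unit cost, features standardized on the training data
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))


def _training_error(ds: ExpressionDataset, genes: list[str]) -> float:
    X = ds.values.loc[genes].to_numpy(dtype=float).T
    y = ds.y
    clf = _plain_svm().fit(X, y)
    return float((clf.predict(X) != y).mean())


def tune_cutoff(ds: ExpressionDataset, sig_sets: list[str], result: SamGsResult,
                coll: GeneSetCollection,
                grid: tuple[float, ...] = DEFAULT_CK_GRID):
    """Pick the c_k cutoff by training error of a plain linear SVM.

    Returns ``(best_cutoff, table)`` where the table has one row per grid
    value with the pooled gene count and training misclassification error.
    Ties go to fewer selected genes, then the smaller cutoff.
    """
    if not grid:
        raise ValueError("cutoff grid must be non-empty")
    if any(not 0.0 < c < 1.0 for c in grid):
        raise ValueError("cutoff grid values must lie in (0, 1)")
    if not sig_sets:
        raise ValueError(
            "no significant gene sets: nothing to reduce "
            "(lower the set-p threshold or check the data)"
        )
    rows = []
    for cutoff in grid:
        traces = [reduce_set(s, result, cutoff, coll) for s in sig_sets]
        genes = _union_preserving_order([t.core_subset for t in traces])
        err = _training_error(ds, genes)
        rows.append({"cutoff": cutoff, "n_genes": len(genes), "error": err})
    table = pd.DataFrame(rows)
    best = table.sort_values(["error", "n_genes", "cutoff"],
                             kind="stable").iloc[0]
    return float(best["cutoff"]), table


@dataclass
class SamGsrSelection:
    """Full SAM-GSR output: selected genes, final SVM, traces, manifest."""

    selected_genes: list[str]
    model: object | None          # fitted sklearn pipeline, or None if empty
    traces: list[ReductionTrace]
    samgs_result: SamGsResult
    significant_sets: list[str]
    cutoff: float | None
    cutoff_table: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.selected_genes

    def predict_beliefs(self, ds: ExpressionDataset):
        from .metrics import PredictionSet
        if self.model is None:
            raise ValueError("no model was fitted (empty selection)")
        X = ds.values.loc[self.selected_genes].to_numpy(dtype=float).T
        f = self.model.decision_function(X)
        p_pos = _platt_predict(self._platt, f)
        beliefs = np.column_stack([p_pos, 1.0 - p_pos])
        return PredictionSet.from_labels(beliefs, ds.y, class_names=("diseased", "control"))


def _platt_fit(f: np.ndarray, y: np.ndarray):
    """Platt scaling: logistic fit of class membership on decision values.

    Returns (a, b) of p(+1 | f) = sigmoid(a * f + b). A plain (lightly
    regularized) logistic regression on the 1-D decision value; degenerate
    constant decision values collapse to the base-rate intercept.
    """
    from sklearn.linear_model import LogisticRegression
    lr = LogisticRegression(C=1e6, max_iter=1000)
    lr.fit(f.reshape(-1, 1), y)
    # orient toward the +1 class regardless of sklearn's class ordering
    pos_index = list(lr.classes_).index(1)
    sign = 1.0 if pos_index == 1 else -1.0
    return sign * float(lr.coef_[0, 0]), sign * float(lr.intercept_[0])


def _platt_predict(ab: tuple[float, float], f: np.ndarray) -> np.ndarray:
    a, b = ab
    # clip keeps beliefs strictly inside (0, 1) in double precision
    z = np.clip(a * np.asarray(f, dtype=float) + b, -30, 30)
    return 1.0 / (1.0 + np.exp(-z))


def samgsr_select(ds: ExpressionDataset, coll: GeneSetCollection, *,
                  B: int = DEFAULT_B, seed: int = 0,
                  set_p_threshold: float = DEFAULT_SET_P_THRESHOLD,
                  fdr: bool = False,
                  ck_grid: tuple[float, ...] = DEFAULT_CK_GRID,
                  s0_method: str = "quantile", s0_q: float = 0.05,
                  s0_fixed: float = 0.0, s0_recompute: bool = True,
                  exhaustive: str = "auto") -> SamGsrSelection:
    """End-to-end SAM-GSR feature selection.

    Permutation SAM-GS -> significant sets -> cutoff tuning -> reduction at
    the optimal cutoff -> deduplicated union of core subsets -> final plain
    linear SVM on the selected genes. Returns an empty selection (no model)
    when no set clears the significance threshold.
    """
    result = permutation_null(
        ds, coll, B=B, seed=child_seed(seed, "permutation"),
        s0_method=s0_method, s0_q=s0_q, s0_fixed=s0_fixed,
        s0_recompute=s0_recompute, exhaustive=exhaustive,
    )
    sig = significant_sets(result, threshold=set_p_threshold, fdr=fdr)
    manifest = {
        "method": "samgsr",
        "B": result.B,
        "seed": int(seed),
        "exhaustive": result.exhaustive,
        "s0": result.sam.s0,
        "s0_mode": result.s0_mode,
        "set_p_threshold": set_p_threshold,
        "fdr": fdr,
        "ck_grid": list(ck_grid),
        "significant_sets": sig,
    }
    if not sig:
        return SamGsrSelection(
            selected_genes=[], model=None, traces=[], samgs_result=result,
            significant_sets=[], cutoff=None, cutoff_table=None,
            manifest=manifest | {"selected_genes": [], "cutoff": None},
        )
    cutoff, table = tune_cutoff(ds, sig, result, coll, grid=ck_grid)
    traces = [reduce_set(s, result, cutoff, coll) for s in sig]
    genes = _union_preserving_order([t.core_subset for t in traces])
    X = ds.values.loc[genes].to_numpy(dtype=float).T
    model = _plain_svm().fit(X, ds.y)
    selection = SamGsrSelection(
        selected_genes=genes, model=model, traces=traces, samgs_result=result,
        significant_sets=sig, cutoff=cutoff, cutoff_table=table,
        manifest=manifest | {"selected_genes": genes, "cutoff": cutoff},
    )
    selection._platt = _platt_fit(model.decision_function(X), ds.y)
    return selection
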