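"""Modified SAM-GSR: SAM-GS set screening followed by SCAD-SVM selection.

Instead of peeling each significant set to a core subset by SAM-statistic
magnitude, the modified algorithm pools every member gene of every
significant set and hands the pooled candidates to a SCAD-penalized linear
SVM, which selects genes and classifies in one step. A gene's chance of
selection then hinges on its contribution to the separating hyperplane
rather than on the size of its SAM statistic or on how many sets carry it
(the candidate pool keeps one feature per gene however many sets contain
it). The flip side is structural: a marker in no significant set can never
be selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_genesets import ExpressionDataset, GeneSetCollection
from .metrics import evaluate
from .reduction import SamGsrSelection, samgsr_select
from .samgs import (
    DEFAULT_B,
    DEFAULT_SET_P_THRESHOLD,
    SamGsResult,
    child_seed,
    permutation_null,
    significant_sets,
)
from .scad_svm import (
    DEFAULT_ALPHA,
    DEFAULT_FOLDS,
    DEFAULT_LAMBDA_GRID,
    ScadSvmModel,
    fit,
    predict_beliefs,
    tune_lambda,
)


@dataclass
class PipelineResult:
    """Modified SAM-GSR output."""

    significant_sets: list[str]
    candidate_genes: list[str]
    model: ScadSvmModel | None
    samgs_result: SamGsResult
    manifest: dict = field(default_factory=dict)

    @property
    def selected_genes(self) -> list[str]:
        return self.model.selected_genes if self.model is not None else []

    @property
    def empty(self) -> bool:
        return self.model is None

    def predict_beliefs(self, ds: ExpressionDataset):
        if self.model is None:
            raise ValueError("no model was fitted (empty candidate pool)")
        return predict_beliefs(self.model, ds)


def _candidate_union(sig: list[str], coll: GeneSetCollection) -> list[str]:
    seen: dict[str, None] = {}
    for name in sig:
        for g in coll.members(name):
            seen.setdefault(g)
    return list(seen)


def msamgsr_select(ds: ExpressionDataset, coll: GeneSetCollection, *,
                   B: int = DEFAULT_B, seed: int = 0,
                   set_p_threshold: float = DEFAULT_SET_P_THRESHOLD,
                   fdr: bool = False, alpha: float = DEFAULT_ALPHA,
                   lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
                   folds: int = DEFAULT_FOLDS,
                   s0_method: str = "quantile", s0_q: float = 0.05,
                   s0_fixed: float = 0.0, s0_recompute: bool = True,
                   exhaustive: str = "auto") -> PipelineResult:
    """Run the modified SAM-GSR pipeline end to end.

    Permutation SAM-GS -> sets with p <= threshold -> deduplicated union of
    their members -> lambda tuned by stratified CV -> SCAD-SVM fit at the
    best lambda. Deterministic given ``seed``. An empty candidate pool
    yields an explicit empty result with no model.
    """
    result = permutation_null(
        ds, coll, B=B, seed=child_seed(seed, "permutation"),
        s0_method=s0_method, s0_q=s0_q, s0_fixed=s0_fixed,
        s0_recompute=s0_recompute, exhaustive=exhaustive,
    )
    sig = significant_sets(result, threshold=set_p_threshold, fdr=fdr)
    candidates = _candidate_union(sig, coll)
    manifest = {
        "method": "msamgsr",
        "B": result.B,
        "seed": int(seed),
        "exhaustive": result.exhaustive,
        "s0": result.sam.s0,
        "s0_mode": result.s0_mode,
        "set_p_threshold": set_p_threshold,
        "fdr": fdr,
        "alpha": alpha,
        "lambda_grid": list(lambda_grid),
        "folds": folds,
        "significant_sets": sig,
        "n_candidates": len(candidates),
    }
    if not candidates:
        return PipelineResult(
            significant_sets=sig, candidate_genes=[], model=None,
            samgs_result=result,
            manifest=manifest | {"lambda": None, "selected_genes": []},
        )
    ds_sub = ds.subset_genes(candidates)
    lam, cv_table = tune_lambda(ds_sub, alpha=alpha, grid=lambda_grid,
                                folds=folds, seed=child_seed(seed, "cv"))
    model = fit(ds_sub, lam, alpha)
    model.cv_table = cv_table
    return PipelineResult(
        significant_sets=sig, candidate_genes=candidates, model=model,
        samgs_result=result,
        manifest=manifest | {"lambda": lam, "selected_genes": model.selected_genes},
    )


def _metric_row(method: str, split: str, n_selected: int, pred) -> dict:
    m = evaluate(pred)
    return {
        "method": method, "split": split, "n_selected": n_selected,
        "error_pct": 100.0 * m["error"], "GBS": m["gbs"],
        "BCM": m["bcm"], "AUPR": m["aupr"],
    }


def compare_methods(ds_train: ExpressionDataset, ds_test: ExpressionDataset,
                    coll: GeneSetCollection, *, seed: int = 0,
                    **config) -> pd.DataFrame:
    """Train SAM-GSR and modified SAM-GSR on one dataset, score on both.

    Returns a tidy table with one row per (method, split) carrying the
    number of selected genes, the error percentage, GBS, BCM and AUPR.
    ``config`` is forwarded to both pipelines where applicable. A method
    with an empty selection yields NaN metrics for its rows.
    """
    samgsr_keys = {"B", "set_p_threshold", "fdr", "ck_grid", "s0_method",
                   "s0_q", "s0_fixed", "s0_recompute", "exhaustive"}
    msam_keys = {"B", "set_p_threshold", "fdr", "alpha", "lambda_grid",
                 "folds", "s0_method", "s0_q", "s0_fixed", "s0_recompute",
                 "exhaustive"}
    unknown = set(config) - (samgsr_keys | msam_keys)
    if unknown:
        raise TypeError(f"unknown config keys: {sorted(unknown)}")
    sel: SamGsrSelection = samgsr_select(
        ds_train, coll, seed=seed,
        **{k: v for k, v in config.items() if k in samgsr_keys})
    mod = msamgsr_select(
        ds_train, coll, seed=seed,
        **{k: v for k, v in config.items() if k in msam_keys})

    rows = []
    for method, obj in (("SAM-GSR", sel), ("M-SAM-GSR", mod)):
        n_sel = len(obj.selected_genes)
        for split, ds in (("train", ds_train), ("test", ds_test)):
            if obj.empty:
                rows.append({"method": method, "split": split,
                             "n_selected": 0, "error_pct": np.nan,
                             "GBS": np.nan, "BCM": np.nan, "AUPR": np.nan})
            else:
                rows.append(_metric_row(method, split, n_sel,
                                        obj.predict_beliefs(ds)))
    return pd.DataFrame(rows)
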