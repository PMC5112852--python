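"""SAM statistics and the SAM-GS gene-set statistic with permutation p-values.

The per-gene SAM statistic is a moderated standardized mean difference

    d_i = (xbar_d(i) - xbar_c(i)) / (s(i) + s0)

where s(i) is the SAM-convention pooled standard deviation

    s(i) = sqrt( (1/n_d + 1/n_c) * (SS_d + SS_c) / (n_d + n_c - 2) )

(SS_g the within-group sum of squared deviations) and s0 is a small
nonnegative fudge constant protecting low-variance genes. The set-level
statistic is the squared L2 norm of the member genes' SAM statistics,

    SAMGS_j = sum_{i in j} d_i^2 ,

and its significance is assessed by shuffling the phenotype labels.

The permutation draw is shared across all genes and sets, and the
per-permutation d matrix is retained so the reduction step can compute
residual-subset p-values on the very same null sample.
"""

from __future__ import annotations

import itertools
import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_genesets import CONTROL, DISEASED, ExpressionDataset, GeneSetCollection

DEFAULT_B = 500
DEFAULT_S0_QUANTILE = 0.05
DEFAULT_SET_P_THRESHOLD = 0.05
EXHAUSTIVE_LIMIT = 10_000


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stable, < 2**31).

    Keyed on the stage name so adding a stage does not shift the random
    streams of the others.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# scalar / per-gene statistics


def pooled_sd(x_d, x_c) -> float:
    """SAM-convention pooled standard deviation for one gene."""
    x_d = np.asarray(x_d, dtype=float)
    x_c = np.asarray(x_c, dtype=float)
    n_d, n_c = x_d.size, x_c.size
    if n_d < 2 or n_c < 2:
        raise ValueError("each group needs >= 2 values for a pooled SD")
    ss_d = float(((x_d - x_d.mean()) ** 2).sum())
    ss_c = float(((x_c - x_c.mean()) ** 2).sum())
    return math.sqrt((1.0 / n_d + 1.0 / n_c) * (ss_d + ss_c) / (n_d + n_c - 2))


def sam_statistic(x_d, x_c, s0: float) -> float:
    """SAM statistic d = (mean_d - mean_c) / (pooled_sd + s0) for one gene."""
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    s = pooled_sd(x_d, x_c)
    denom = s + s0
    if denom == 0:
        raise ValueError("degenerate gene: pooled SD + s0 is zero")
    return (float(np.mean(x_d)) - float(np.mean(x_c))) / denom


def choose_s0(all_pooled_sd, method: str = "quantile",
              q: float = DEFAULT_S0_QUANTILE, fixed_value: float = 0.0) -> float:
    """Pick the fudge constant s0 from the per-gene pooled SDs.

    ``quantile`` (default) takes the q-th empirical quantile (linear
    interpolation, numpy convention) of the pooled SDs; ``fixed`` returns
    ``fixed_value`` unchanged.
    """
    if method == "fixed":
        if fixed_value < 0:
            raise ValueError("fixed s0 must be nonnegative")
        return float(fixed_value)
    if method != "quantile":
        raise ValueError(f"unknown s0 method {method!r}")
    sds = np.asarray(all_pooled_sd, dtype=float)
    if sds.size == 0:
        raise ValueError("cannot choose s0 from an empty SD list")
    if not 0.0 <= q <= 1.0:
        raise ValueError("quantile q must be in [0, 1]")
    return float(np.quantile(sds, q))


def samgs_statistic(d: pd.Series, member_genes: list[str]) -> float:
    """Sum of squared SAM statistics over a set's member genes."""
    missing = [g for g in member_genes if g not in d.index]
    if missing:
        raise KeyError(f"genes missing from SAM statistics: {missing[:5]}")
    vals = d.loc[member_genes].to_numpy(dtype=float)
    return float((vals**2).sum())


# ---------------------------------------------------------------------------
# vectorized statistics over permutations


def _group_stats(X: np.ndarray, D: np.ndarray):
    """Means, pooled SDs for every gene under every label assignment.

    ``X`` is genes x samples; ``D`` is assignments x samples boolean
    (True = diseased). Returns (mean_d, mean_c, s) each genes x assignments.
    """
    n = X.shape[1]
    Df = D.astype(float).T            # samples x B
    Cf = 1.0 - Df
    n_d = Df.sum(axis=0)              # per-assignment group sizes
    n_c = n - n_d
    if (n_d < 2).any() or (n_c < 2).any():
        raise ValueError("each group needs >= 2 samples")
    X2 = X**2
    sum_d = X @ Df                    # genes x B
    sum_c = X @ Cf
    mean_d = sum_d / n_d
    mean_c = sum_c / n_c
    ss_d = X2 @ Df - n_d * mean_d**2
    ss_c = X2 @ Cf - n_c * mean_c**2
    ss = np.clip(ss_d + ss_c, 0.0, None)  # guard tiny negative round-off
    s = np.sqrt((1.0 / n_d + 1.0 / n_c) * ss / (n_d + n_c - 2))
    return mean_d, mean_c, s


@dataclass(frozen=True)
class SamStatistics:
    """Observed per-gene SAM statistics and their permutation p-values."""

    d: pd.Series
    mean_d: pd.Series
    mean_c: pd.Series
    s: pd.Series
    s0: float
    gene_p: pd.Series


@dataclass(frozen=True)
class SamGsResult:
    """Set-level SAM-GS statistics with permutation p-values.

    ``d_perm`` (permutations x genes) is the SAM-statistic matrix under the
    retained label shuffles; the reduction step reuses it so that residual
    p-values are computed against the identical null sample. ``exhaustive``
    marks full enumeration of label assignments, in which case p-values are
    exact proportions over all assignments (the identity assignment
    included) rather than add-one Monte-Carlo estimates.
    """

    samgs: pd.Series
    set_p: pd.Series
    sam: SamStatistics
    B: int
    permutation_seed: int
    exhaustive: bool
    d_perm: np.ndarray
    gene_index: pd.Index
    s0_mode: str

    def pvalue_for_genes(self, member_genes: list[str]) -> float:
        """Permutation p-value of SAMGS over an arbitrary gene subset,
        computed on the retained permutations."""
        idx = self.gene_index.get_indexer(member_genes)
        if (idx < 0).any():
            bad = [g for g, i in zip(member_genes, idx) if i < 0]
            raise KeyError(f"unknown genes: {bad[:5]}")
        obs = float((self.sam.d.to_numpy()[idx] ** 2).sum())
        null = (self.d_perm[:, idx] ** 2).sum(axis=1)
        return _pvalue(null, obs, self.exhaustive)


def _pvalue(null: np.ndarray, obs: float, exhaustive: bool) -> float:
    count = int((null >= obs - 1e-12).sum())
    if exhaustive:
        return count / null.shape[0]
    return (1 + count) / (null.shape[0] + 1)


def _enumerate_assignments(y: np.ndarray) -> np.ndarray:
    """All distinct diseased/control assignments with the observed group sizes."""
    n = y.size
    n_d = int((y == DISEASED).sum())
    combos = itertools.combinations(range(n), n_d)
    D = np.zeros((math.comb(n, n_d), n), dtype=bool)
    for row, picks in zip(D, combos):
        row[list(picks)] = True
    return D


def observed_sam(ds: ExpressionDataset, s0_method: str = "quantile",
                 s0_q: float = DEFAULT_S0_QUANTILE, s0_fixed: float = 0.0):
    """Observed per-gene statistics (no permutations)."""
    ds.require_two_groups()
    X = ds.values.to_numpy(dtype=float)
    D = (ds.y == DISEASED)[None, :]
    mean_d, mean_c, s = (a[:, 0] for a in _group_stats(X, D))
    s0 = choose_s0(s, method=s0_method, q=s0_q, fixed_value=s0_fixed)
    denom = s + s0
    if (denom == 0).any():
        bad = list(ds.values.index[denom == 0])
        raise ValueError(f"degenerate genes with zero pooled SD and s0=0: {bad[:5]}")
    d = (mean_d - mean_c) / denom
    idx = ds.values.index
    return d, mean_d, mean_c, s, s0, idx


def permutation_null(ds: ExpressionDataset, coll: GeneSetCollection,
                     B: int = DEFAULT_B, seed: int = 0,
                     s0_method: str = "quantile", s0_q: float = DEFAULT_S0_QUANTILE,
                     s0_fixed: float = 0.0, s0_recompute: bool = True,
                     exhaustive: str = "auto") -> SamGsResult:
    """Per-gene and per-set permutation p-values under label shuffles.

    ``B`` random label shuffles are drawn from ``seed`` (the same shuffles
    serve every gene and set); per shuffle all d_i are recomputed, with s0
    re-chosen from the shuffled pooled SDs unless ``s0_recompute`` is False
    (then the observed s0 is reused). P-values use the add-one convention
    (1 + #{null >= observed}) / (B + 1), so they live in [1/(B+1), 1].

    ``exhaustive``: "auto" switches to full enumeration of all label
    assignments when there are at most 10,000 of them; "always" forces it
    (error if too many); "never" disables it. Exhaustive p-values are exact
    proportions over all assignments.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if exhaustive not in ("auto", "always", "never"):
        raise ValueError(f"unknown exhaustive mode {exhaustive!r}")
    ds.require_two_groups()
    X = ds.values.to_numpy(dtype=float)
    y = ds.y
    n = y.size
    n_d = int((y == DISEASED).sum())

    n_assign = math.comb(n, n_d)
    use_exhaustive = exhaustive == "always" or (
        exhaustive == "auto" and n_assign <= EXHAUSTIVE_LIMIT
    )
    if exhaustive == "always" and n_assign > EXHAUSTIVE_LIMIT:
        raise ValueError(f"{n_assign} label assignments exceed the exhaustive limit")

    # observed statistics
    d_obs, mean_d, mean_c, s_obs, s0_obs, gene_index = observed_sam(
        ds, s0_method=s0_method, s0_q=s0_q, s0_fixed=s0_fixed
    )

    if use_exhaustive:
        D = _enumerate_assignments(y)
        B_eff = D.shape[0]
    else:
        rng = np.random.default_rng(seed)
        D = np.empty((B, n), dtype=bool)
        base = y == DISEASED
        for b in range(B):
            D[b] = base[rng.permutation(n)]
        B_eff = B

    pm_d, pm_c, pm_s = _group_stats(X, D)
    if s0_recompute:
        s0_b = np.array(
            [choose_s0(pm_s[:, b], method=s0_method, q=s0_q, fixed_value=s0_fixed)
             for b in range(B_eff)]
        )
    else:
        s0_b = np.full(B_eff, s0_obs)
    denom = pm_s + s0_b[None, :]
    if (denom == 0).any():
        raise ValueError("degenerate gene under permutation: pooled SD + s0 is zero")
    d_perm = ((pm_d - pm_c) / denom).T        # B_eff x genes

    # per-gene two-sided p-values
    abs_obs = np.abs(d_obs)
    gene_counts = (np.abs(d_perm) >= abs_obs[None, :] - 1e-12).sum(axis=0)
    if use_exhaustive:
        gene_p = gene_counts / B_eff
    else:
        gene_p = (1 + gene_counts) / (B_eff + 1)

    sam = SamStatistics(
        d=pd.Series(d_obs, index=gene_index),
        mean_d=pd.Series(mean_d, index=gene_index),
        mean_c=pd.Series(mean_c, index=gene_index),
        s=pd.Series(s_obs, index=gene_index),
        s0=float(s0_obs),
        gene_p=pd.Series(gene_p, index=gene_index),
    )

    d2_perm = d_perm**2
    samgs_vals: dict[str, float] = {}
    set_p: dict[str, float] = {}
    for name in coll.set_ids():
        members = coll.members(name)
        idx = gene_index.get_indexer(members)
        if (idx < 0).any():
            bad = [g for g, i in zip(members, idx) if i < 0]
            raise KeyError(f"set {name!r} has genes outside the dataset: {bad[:5]}")
        obs = float((d_obs[idx] ** 2).sum())
        null = d2_perm[:, idx].sum(axis=1)
        samgs_vals[name] = obs
        set_p[name] = _pvalue(null, obs, use_exhaustive)

    return SamGsResult(
        samgs=pd.Series(samgs_vals, dtype=float),
        set_p=pd.Series(set_p, dtype=float),
        sam=sam,
        B=B_eff,
        permutation_seed=int(seed),
        exhaustive=use_exhaustive,
        d_perm=d_perm,
        gene_index=gene_index,
        s0_mode="recompute" if s0_recompute else "observed",
    )


def significant_sets(result: SamGsResult,
                     threshold: float = DEFAULT_SET_P_THRESHOLD,
                     fdr: bool = False) -> list[str]:
    """Set ids passing the significance threshold.

    By default raw permutation p <= threshold; with ``fdr`` the
    Benjamini-Hochberg adjusted p-values are thresholded instead.
    """
    p = result.set_p
    if fdr:
        p = benjamini_hochberg(p)
    return list(p.index[p <= threshold])


def benjamini_hochberg(p: pd.Series) -> pd.Series:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    m = len(p)
    order = np.argsort(p.to_numpy(), kind="stable")
    ranked = p.to_numpy()[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return pd.Series(out, index=p.index)


def result_table(result: SamGsResult, coll: GeneSetCollection) -> pd.DataFrame:
    """Per-set summary (set_id, set_size, SAMGS, p_value) for TSV export."""
    rows = [
        {"set_id": name, "set_size": len(coll.members(name)),
         "SAMGS": result.samgs[name], "p_value": result.set_p[name]}
        for name in result.samgs.index
    ]
    return pd.DataFrame(rows)
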