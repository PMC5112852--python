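"""Sparse linear SVM with the SCAD penalty.

Fits f(x) = sum_i w_i x_i + b by minimizing

    sum_i (1 - y_i f(x_i))_+  +  sum_j p_lambda(w_j)

where p_lambda is the smoothly clipped absolute deviation (SCAD) penalty:
LASSO-like (lambda * |w|) near zero, a quadratic blend on (lambda,
alpha*lambda], and a constant (alpha+1)*lambda^2/2 beyond alpha*lambda, so
large coefficients are not shrunk. alpha defaults to 3.7.

The nonconvex objective is minimized by local linear approximation (LLA):
the penalty is linearized at the current |w|, turning each step into a
weighted-L1 hinge problem, which is an exact linear program (solved with
HiGHS via scipy). The LLA surrogate majorizes the true objective (SCAD is
concave in |w|), so the objective is non-increasing across iterations.
lambda is tuned by stratified K-fold cross-validation over the grid
2^-8 ... 2^14.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from sklearn.model_selection import StratifiedKFold

from .io_genesets import ExpressionDataset
from .metrics import PredictionSet

DEFAULT_ALPHA = 3.7
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-8, 15))
DEFAULT_FOLDS = 5
LLA_TOL = 1e-4
LLA_MAX_ITER = 50
ZERO_TOL = 1e-6


def _check_params(lam: float, alpha: float) -> None:
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if alpha <= 2:
        raise ValueError("SCAD alpha must exceed 2")


def scad_penalty(w, lam: float, alpha: float = DEFAULT_ALPHA):
    """SCAD penalty p_lambda(w) (even in w, nondecreasing in |w|).

    Three branches: lam*|w| for |w| <= lam;
    -(|w|^2 - 2*alpha*lam*|w| + lam^2) / (2*(alpha-1)) for lam < |w| <= alpha*lam;
    (alpha+1)*lam^2/2 beyond.
    """
    _check_params(lam, alpha)
    a = np.abs(np.asarray(w, dtype=float))
    out = np.where(
        a <= lam,
        lam * a,
        np.where(
            a <= alpha * lam,
            -(a**2 - 2 * alpha * lam * a + lam**2) / (2 * (alpha - 1)),
            (alpha + 1) * lam**2 / 2,
        ),
    )
    return out if out.ndim else float(out)


def scad_derivative(w_abs, lam: float, alpha: float = DEFAULT_ALPHA):
    """d/d|w| of the SCAD penalty: lam, then a linear taper, then 0."""
    _check_params(lam, alpha)
    a = np.asarray(w_abs, dtype=float)
    if (a < 0).any() if a.ndim else a < 0:
        raise ValueError("w_abs must be nonnegative")
    out = np.where(
        a <= lam,
        lam,
        np.where(a <= alpha * lam, (alpha * lam - a) / (alpha - 1), 0.0),
    )
    return out if out.ndim else float(out)


def _weighted_l1_hinge(X: np.ndarray, y: np.ndarray, pen: np.ndarray):
    """Exact minimizer of sum hinge + sum pen_j |w_j| via an LP.

    Variables: w = wp - wm (split positive/negative parts), free intercept
    b = bp - bm, slacks xi_i >= hinge violations. Returns (w, b).
    """
    n, G = X.shape
    c = np.concatenate([pen, pen, [0.0, 0.0], np.ones(n)])
    # y_i (x_i . w + b) >= 1 - xi_i   ->   -y_i x_i . (wp-wm) - y_i(bp-bm) - xi_i <= -1
    yX = y[:, None] * X
    A = np.hstack([-yX, yX, -y[:, None], y[:, None], -np.eye(n)])
    res = linprog(c, A_ub=A, b_ub=-np.ones(n), bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"LP subproblem failed: {res.message}")
    z = res.x
    w = z[:G] - z[G:2 * G]
    b = z[2 * G] - z[2 * G + 1]
    return w, float(b)


def _hinge_sum(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float) -> float:
    margins = 1.0 - y * (X @ w + b)
    return float(np.clip(margins, 0.0, None).sum())


def _objective(X, y, w, b, lam, alpha) -> float:
    return _hinge_sum(X, y, w, b) + float(np.sum(scad_penalty(w, lam, alpha)))


@dataclass
class ScadSvmModel:
    """Fitted SCAD-SVM: weights on the original (unstandardized) gene scale
    are NOT stored; predictions standardize with the training constants."""

    gene_ids: list[str]
    w: np.ndarray                 # weights on standardized features
    b: float
    lam: float
    alpha: float
    center: np.ndarray            # per-gene training mean
    scale: np.ndarray             # per-gene training SD (zero-variance -> 1)
    platt: tuple[float, float]    # sigmoid p(+1|f) = 1/(1+exp(-(a f + c)))
    converged: bool = True
    objective_path: list[float] = field(default_factory=list)
    cv_table: pd.DataFrame | None = None

    @property
    def selected_genes(self) -> list[str]:
        return [g for g, wi in zip(self.gene_ids, self.w) if wi != 0.0]

    def decision_function(self, ds: ExpressionDataset) -> np.ndarray:
        missing = [g for g in self.gene_ids if g not in ds.values.index]
        if missing:
            raise KeyError(f"model genes absent from data: {missing[:5]}")
        X = ds.values.loc[self.gene_ids].to_numpy(dtype=float).T
        Z = (X - self.center) / self.scale
        return Z @ self.w + self.b

    def predict(self, ds: ExpressionDataset) -> np.ndarray:
        f = self.decision_function(ds)
        return np.where(f >= 0, 1, -1)

    def to_json(self) -> str:
        payload = {
            "gene_ids": self.gene_ids,
            "w": self.w.tolist(),
            "b": self.b,
            "lambda": self.lam,
            "alpha": self.alpha,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "platt": list(self.platt),
            "converged": self.converged,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScadSvmModel":
        p = json.loads(text)
        return cls(
            gene_ids=p["gene_ids"], w=np.asarray(p["w"], dtype=float),
            b=float(p["b"]), lam=float(p["lambda"]), alpha=float(p["alpha"]),
            center=np.asarray(p["center"], dtype=float),
            scale=np.asarray(p["scale"], dtype=float),
            platt=tuple(p["platt"]), converged=bool(p["converged"]),
        )


def _standardize(X: np.ndarray):
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (X - center) / scale, center, scale


def _platt_fit(f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    from sklearn.linear_model import LogisticRegression
    lr = LogisticRegression(C=1e6, max_iter=1000)
    lr.fit(f.reshape(-1, 1), y)
    sign = 1.0 if list(lr.classes_).index(1) == 1 else -1.0
    return sign * float(lr.coef_[0, 0]), sign * float(lr.intercept_[0])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clip keeps beliefs strictly inside (0, 1) in double precision
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def fit(ds: ExpressionDataset, lam: float, alpha: float = DEFAULT_ALPHA, *,
        tol: float = LLA_TOL, max_iter: int = LLA_MAX_ITER,
        zero_tol: float = ZERO_TOL) -> ScadSvmModel:
    """Fit the SCAD-penalized linear SVM on all genes of ``ds``.

    Initializes from the L1-penalized SVM at the same lambda, then iterates
    LLA steps (weighted-L1 hinge LPs with weights scad_derivative(|w|))
    until max |delta w| < tol or ``max_iter`` outer iterations; weights with
    |w| < zero_tol are snapped to exactly 0. Features are standardized
    internally; the intercept is never penalized.
    """
    _check_params(lam, alpha)
    ds.require_two_groups()
    X_raw = ds.values.to_numpy(dtype=float).T
    y = ds.y.astype(float)
    X, center, scale = _standardize(X_raw)
    G = X.shape[1]

    # L1 initialization: the LASSO-like region of SCAD
    w, b = _weighted_l1_hinge(X, y, np.full(G, lam))
    path = [_objective(X, y, w, b, lam, alpha)]
    converged = False
    for _ in range(max_iter):
        pen = scad_derivative(np.abs(w), lam, alpha)
        w_new, b_new = _weighted_l1_hinge(X, y, np.asarray(pen, dtype=float))
        path.append(_objective(X, y, w_new, b_new, lam, alpha))
        delta = float(np.max(np.abs(w_new - w))) if G else 0.0
        w, b = w_new, b_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("SCAD-SVM LLA did not converge; returning last iterate",
                      stacklevel=2)
    w = np.where(np.abs(w) < zero_tol, 0.0, w)

    f_train = X @ w + b
    platt = _platt_fit(f_train, ds.y)
    return ScadSvmModel(
        gene_ids=list(ds.values.index), w=w, b=b, lam=lam, alpha=alpha,
        center=center, scale=scale, platt=platt, converged=converged,
        objective_path=path,
    )


def tune_lambda(ds: ExpressionDataset, alpha: float = DEFAULT_ALPHA,
                grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
                folds: int = DEFAULT_FOLDS, seed: int = 0):
    """Pick lambda by stratified K-fold CV misclassification error.

    Ties go to the LARGER lambda (sparser model). Returns
    ``(best_lambda, cv_table)``.
    """
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    y = ds.y
    n_minority = min(int((y == 1).sum()), int((y == -1).sum()))
    k = min(folds, n_minority)
    if k < 2:
        raise ValueError("too few samples in the minority class for CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    sample_ids = np.array(ds.sample_ids)
    errors = np.zeros((len(grid), k))
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        ds_tr = ExpressionDataset(ds.values.iloc[:, tr], ds.labels.iloc[tr])
        X_va = ds.values.iloc[:, va].to_numpy(dtype=float).T
        y_va = y[va]
        for li, lam in enumerate(grid):
            model = fit(ds_tr, lam, alpha)
            Z = (X_va - model.center) / model.scale
            pred = np.where(Z @ model.w + model.b >= 0, 1, -1)
            errors[li, fold] = float((pred != y_va).mean())
    mean_err = errors.mean(axis=1)
    table = pd.DataFrame({"lambda": grid, "cv_error": mean_err})
    best = min(
        range(len(grid)),
        key=lambda i: (mean_err[i], -grid[i]),  # ties -> larger lambda
    )
    return float(grid[best]), table


def predict_beliefs(model: ScadSvmModel, ds: ExpressionDataset) -> PredictionSet:
    """Class beliefs for new samples via the model's Platt sigmoid.

    Genes are aligned by id (a model gene missing from the data is an
    error); the stored standardization is applied before the decision
    function. Column 0 holds the +1 (diseased) class belief.
    """
    f = model.decision_function(ds)
    a, c = model.platt
    p_pos = _sigmoid(a * f + c)
    beliefs = np.column_stack([p_pos, 1.0 - p_pos])
    return PredictionSet.from_labels(beliefs, ds.y,
                                     class_names=("diseased", "control"))
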