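"""BLUP prediction at fixed variance components and K-fold cross-validation.

Predictions for held-out individuals use the joint-normal conditional mean:
with training covariance V = K_tt sigma_A2 (+ D_tt sigma_D2) + F_t sigma_E2
and GLS mean mu, the predicted breeding values are
u_hat = sigma_A2 K[:, t] V^-1 (y_t - mu) (and analogously v_hat through D),
so validation phenotypes never enter the equations. Accuracy is the Pearson
correlation between validation yield deviations and predictions; bias is the
slope of the regression of yield deviation on prediction (1 = unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .containers import VarianceComponents
from .varcomp import ModelSpec
from .relmat import RelationshipMatrix

__all__ = [
    "FoldAssignment",
    "CVResult",
    "blup_solve",
    "make_folds",
    "cross_validate",
]


@dataclass
class FoldAssignment:
    ids: np.ndarray
    fold: np.ndarray  # 1..K per individual
    K: int
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(self.fold, minlength=self.K + 1)[1:]
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most one")


@dataclass
class CVResult:
    """Per-fold and pooled accuracy/bias statistics.

    ``per_fold`` has one row per fold with columns r_u, b_u (and r_g, b_g
    for the dominance model); ``mean`` and ``se`` summarise over folds with
    SE = sd(folds)/sqrt(K).
    """

    per_fold: pd.DataFrame
    mean: pd.Series
    se: pd.Series
    model: str


def _mat(M) -> np.ndarray:
    return M.values if isinstance(M, RelationshipMatrix) else np.asarray(M, dtype=float)


def blup_solve(
    spec: ModelSpec,
    components: VarianceComponents,
    matrices: dict,
    train: np.ndarray,
    predict: np.ndarray,
) -> dict:
    """Solve the mixed model on ``train`` records and predict effects for
    ``predict`` indices (positions into y / the relationship matrices).

    Returns {"mu", "u", "v", "g"} with arrays over ``predict``; v is zero
    for additive models.
    """
    train = np.asarray(train)
    predict = np.asarray(predict)
    y_t = spec.y[train]
    K = _mat(matrices["A" if spec.model == "MA" else "G"])
    if predict.max(initial=-1) >= K.shape[0] or train.max(initial=-1) >= K.shape[0]:
        raise IndexError("individual index outside the relationship matrices")
    F_t = np.diag(1.0 / spec.eop[train])
    V = components.sigma_A2 * K[np.ix_(train, train)] + components.sigma_E2 * F_t
    use_dom = spec.model == "MGD"
    if use_dom:
        D = _mat(matrices["D"])
        V = V + components.sigma_D2 * D[np.ix_(train, train)]
    cho = linalg.cho_factor(V, lower=True)
    ones = np.ones(train.size)
    Vinv_1 = linalg.cho_solve(cho, ones)
    mu = float(ones @ linalg.cho_solve(cho, y_t) / (ones @ Vinv_1))
    w = linalg.cho_solve(cho, y_t - mu)
    u = components.sigma_A2 * (K[np.ix_(predict, train)] @ w)
    if use_dom:
        v = components.sigma_D2 * (D[np.ix_(predict, train)] @ w)
    else:
        v = np.zeros_like(u)
    return {"mu": mu, "u": u, "v": v, "g": u + v}


def make_folds(ids, K: int = 10, seed: int = 0) -> FoldAssignment:
    """Uniform random partition into K folds with sizes differing by at most
    one; deterministic given ``seed``."""
    ids = np.asarray(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold = np.empty(len(ids), dtype=int)
    for f, chunk in enumerate(np.array_split(order, K), start=1):
        fold[chunk] = f
    return FoldAssignment(ids=ids, fold=fold, K=K, seed=seed)


def _fold_stats(
    y_val: np.ndarray, pred: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation and slope of y on pred; optionally weighted."""
    if weights is None:
        r = float(np.corrcoef(y_val, pred)[0, 1])
        b = float(np.cov(y_val, pred, ddof=1)[0, 1] / np.var(pred, ddof=1))
        return r, b
    w = weights / weights.sum()
    my, mp = float(w @ y_val), float(w @ pred)
    cov = float(w @ ((y_val - my) * (pred - mp)))
    vy = float(w @ (y_val - my) ** 2)
    vp = float(w @ (pred - mp) ** 2)
    return cov / np.sqrt(vy * vp), cov / vp


def cross_validate(
    spec: ModelSpec,
    components: VarianceComponents,
    matrices: dict,
    folds: FoldAssignment,
    eop_weighted: bool = False,
) -> CVResult:
    """K-fold cross-validation of predicted breeding values (and total
    genetic values under the dominance model).

    Each fold serves once as validation set; the model is solved on the
    remaining folds at the given (fixed) variance components, and within the
    validation fold the Pearson correlation r(YD, prediction) and the
    regression slope b of YD on the prediction are computed (EOP-weighted
    when ``eop_weighted``; unweighted by default). Folds with fewer than 3
    individuals are rejected.
    """
    rows = []
    for f in range(1, folds.K + 1):
        val = np.where(folds.fold == f)[0]
        train = np.where(folds.fold != f)[0]
        if val.size < 3:
            raise ValueError(f"fold {f} has fewer than 3 individuals")
        pred = blup_solve(spec, components, matrices, train, val)
        y_val = spec.y[val]
        w = spec.eop[val] if eop_weighted else None
        r_u, b_u = _fold_stats(y_val, pred["u"], w)
        row = {"fold": f, "r_u": r_u, "b_u": b_u}
        if spec.model == "MGD":
            r_g, b_g = _fold_stats(y_val, pred["g"], w)
            row.update(r_g=r_g, b_g=b_g)
        rows.append(row)
    per_fold = pd.DataFrame(rows).set_index("fold")
    mean = per_fold.mean()
    se = per_fold.std(ddof=1) / np.sqrt(folds.K)
    return CVResult(per_fold=per_fold, mean=mean, se=se, model=spec.model)
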