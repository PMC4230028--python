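"""Variance-component estimation by restricted maximum likelihood.

Fits the animal-level mixed models

  MA :  y = mu + u + e,  V(u) = A sigma_A^2
  MG :  y = mu + u + e,  V(u) = G sigma_A^2
  MGD:  y = mu + u + v + e,  V(u) = G sigma_A^2, V(v) = D sigma_D^2

with heteroscedastic residuals V(e) = F sigma_E^2, F = diag(1/EOP). One
record per individual, the overall mean as the only fixed effect.

The optimizer is average-information REML with expectation-maximization
fallback: AI proposals that leave the parameter space or decrease the
restricted likelihood are replaced by the (monotone) EM update. The reported
-2 log restricted likelihood includes all terms,

  -2 logL = log|V| + log|X'V^-1 X| + y'Py + (n - 1) log(2 pi),

so differences between nested fits on the same data are valid likelihood
ratio statistics. A single variance component on the boundary makes the
usual chi-square(1) reference anti-conservative, so the LRT uses an equal
mixture of chi-square distributions with 0 and 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .containers import VarianceComponents
from .relmat import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "ModelFit",
    "LRTResult",
    "reml_fit",
    "neg2_restricted_loglik",
    "mixture_lrt",
    "marker_to_animal_variance",
    "animal_to_marker_variance",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelSpec:
    """Response, residual weights and model tag for a variance-component fit."""

    model: str  # MA | MG | MGD
    y: np.ndarray
    eop: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.eop is None:
            self.eop = np.ones_like(self.y)
        self.eop = np.asarray(self.eop, dtype=float).ravel()
        if self.eop.shape != self.y.shape:
            raise ValueError("EOP weights must match y in length")
        if np.any(self.eop <= 0):
            raise ValueError("EOP weights must be positive")
        if self.model not in ("MA", "MG", "MGD"):
            raise ValueError(f"unknown model tag {self.model!r}")


@dataclass
class ModelFit:
    model: str
    components: VarianceComponents
    neg2logL: float
    mu: float
    u: np.ndarray
    v: np.ndarray | None
    converged: bool
    n_iter: int

    @property
    def g(self) -> np.ndarray:
        """Predicted total genetic values u + v (v = 0 for additive models)."""
        return self.u if self.v is None else self.u + self.v


@dataclass
class LRTResult:
    chi2: float
    p_value: float


def _values(M) -> np.ndarray:
    return M.values if isinstance(M, RelationshipMatrix) else np.asarray(M, dtype=float)


def _model_terms(spec: ModelSpec, matrices: dict) -> list[tuple[str, np.ndarray]]:
    if spec.model == "MA":
        keys = [("sigma_A2", "A")]
    elif spec.model == "MG":
        keys = [("sigma_A2", "G")]
    else:
        keys = [("sigma_A2", "G"), ("sigma_D2", "D")]
    terms = []
    for pname, mkey in keys:
        if mkey not in matrices:
            raise KeyError(f"model {spec.model} requires matrix {mkey!r}")
        V_i = _values(matrices[mkey])
        if V_i.shape[0] != spec.y.size:
            raise ValueError(f"matrix {mkey!r} does not match y in dimension")
        terms.append((pname, V_i))
    return terms


def _neg2_from_parts(cho, X, y, n):
    """-2 logL pieces shared by the fit loop and the standalone evaluator."""
    logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Vinv_X = linalg.cho_solve(cho, X)
    XtVinvX = X.T @ Vinv_X
    logdetX = float(np.log(XtVinvX[0, 0]))
    Vinv_y = linalg.cho_solve(cho, y)
    beta = float((X.T @ Vinv_y)[0] / XtVinvX[0, 0])
    Py = Vinv_y - Vinv_X[:, 0] * beta
    yPy = float(y @ Py)
    neg2 = logdetV + logdetX + yPy + (n - 1) * _LOG2PI
    return neg2, Py, Vinv_X, XtVinvX, beta


def neg2_restricted_loglik(
    y: np.ndarray,
    structures: list[np.ndarray],
    variances: list[float],
    eop: np.ndarray | None = None,
) -> float:
    """-2 log restricted likelihood of y ~ N(1 mu, sum_i sigma_i^2 V_i) with
    the residual term F = diag(1/EOP) appended as the last structure.

    ``structures`` lists the genetic covariance structures; the residual F is
    added internally from ``eop``. Used for grid evaluation and diagnostics.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    eop = np.ones(n) if eop is None else np.asarray(eop, dtype=float).ravel()
    F = np.diag(1.0 / eop)
    mats = [np.asarray(S, dtype=float) for S in structures] + [F]
    V = sum(s2 * M for s2, M in zip(variances, mats))
    cho = linalg.cho_factor(V, lower=True)
    X = np.ones((n, 1))
    neg2, *_ = _neg2_from_parts(cho, X, y, n)
    return neg2


def reml_fit(
    spec: ModelSpec,
    matrices: dict,
    tol: float = 1e-8,
    max_iter: int = 200,
    fixed: dict | None = None,
) -> ModelFit:
    """Average-information REML with EM fallback.

    Parameters
    ----------
    spec
        Response, EOP weights and model tag.
    matrices
        Mapping with keys "A" (MA), "G" (MG/MGD), "D" (MGD); values are
        RelationshipMatrix or plain arrays, blended/positive definite.
    tol
        Convergence on the maximum relative parameter change.
    fixed
        Optional {name: value} pinning components (e.g. sigma_D2 = 0 turns
        MGD into MG with an identical likelihood surface).

    Raises on a non-positive-definite covariance structure, naming the term.
    Non-convergence within ``max_iter`` returns a flagged fit.
    """
    fixed = dict(fixed or {})
    y, n = spec.y, spec.y.size
    X = np.ones((n, 1))
    F = np.diag(1.0 / spec.eop)
    terms = _model_terms(spec, matrices) + [("sigma_E2", F)]
    names = [t[0] for t in terms]
    for pname, M in terms:
        try:
            linalg.cho_factor(M + 0.0, lower=True)
        except linalg.LinAlgError as err:
            if pname != "sigma_E2":
                raise ValueError(
                    f"covariance structure for {pname} is not positive definite"
                ) from err

    vary = float(np.var(y))
    if vary == 0:
        vary = 1.0
    floor = 1e-10 * vary
    n_free = sum(1 for nm in names if nm not in fixed)
    theta = np.array(
        [
            fixed.get(nm, vary / max(n_free, 1))
            for nm in names
        ]
    )
    free = np.array([nm not in fixed for nm in names])
    theta = np.maximum(theta, np.where(free, floor, theta))

    def evaluate(th):
        V = sum(s2 * M for s2, (_, M) in zip(th, terms))
        try:
            cho = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError as err:
            raise ValueError("working covariance matrix not positive definite") from err
        neg2, Py, _, _, mu = _neg2_from_parts(cho, X, y, n)
        return neg2, Py, cho, mu

    neg2, Py, cho, mu = evaluate(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P_mats = []  # V_i @ Py and trace(P V_i) pieces
        Vinv = linalg.cho_solve(cho, np.eye(n))
        Vinv_X = Vinv @ X
        XtVinvX = float((X.T @ Vinv_X)[0, 0])
        P = Vinv - (Vinv_X @ Vinv_X.T) / XtVinvX
        score = np.zeros(len(terms))
        ViPy = []
        for k, (_, M) in enumerate(terms):
            MPy = M @ Py
            ViPy.append(MPy)
            tr = float(np.sum(P * M))  # trace(P M) for symmetric M
            score[k] = -0.5 * (tr - float(Py @ MPy))
            P_mats.append(tr)
        # average-information matrix: 0.5 * (Py' Vi P Vj Py)
        PViPy = [P @ w for w in ViPy]
        AI = 0.5 * np.array([[float(ViPy[i] @ PViPy[j]) for j in range(len(terms))]
                             for i in range(len(terms))])

        idx = np.where(free)[0]
        accepted = False
        if idx.size > 0:
            try:
                delta = np.linalg.solve(AI[np.ix_(idx, idx)], score[idx])
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(8):
                    prop = theta.copy()
                    prop[idx] = theta[idx] + step * delta
                    if np.all(prop[idx] >= floor):
                        try:
                            cand = evaluate(prop)
                        except ValueError:
                            cand = None
                        if cand is not None and cand[0] <= neg2 + 1e-10:
                            theta_new = prop
                            neg2_new, Py_new, cho_new, mu_new = cand
                            accepted = True
                            break
                    step *= 0.5
        if not accepted:
            # EM update: monotone in the restricted likelihood
            prop = theta.copy()
            for k in idx:
                prop[k] = theta[k] + (theta[k] ** 2 / n) * (
                    float(Py @ ViPy[k]) - P_mats[k]
                )
            prop[idx] = np.maximum(prop[idx], floor)
            neg2_new, Py_new, cho_new, mu_new = evaluate(prop)
            if neg2_new > neg2 + 1e-6 * (1.0 + abs(neg2)):
                raise RuntimeError(
                    "EM step decreased the restricted likelihood — numerical "
                    "breakdown in REML"
                )
            theta_new = prop

        rel_change = np.max(
            np.abs(theta_new - theta) / np.maximum(np.abs(theta), floor)
        ) if idx.size else 0.0
        theta, neg2, Py, cho, mu = theta_new, neg2_new, Py_new, cho_new, mu_new
        if rel_change < tol:
            converged = True
            break

    comp_map = dict(zip(names, (float(t) for t in theta)))
    components = VarianceComponents(
        sigma_A2=comp_map.get("sigma_A2", 0.0),
        sigma_D2=comp_map.get("sigma_D2", 0.0),
        sigma_E2=comp_map.get("sigma_E2", 0.0),
    )
    u = comp_map["sigma_A2"] * (_model_terms(spec, matrices)[0][1] @ Py)
    v = None
    if spec.model == "MGD":
        v = comp_map["sigma_D2"] * (_values(matrices["D"]) @ Py)
    return ModelFit(
        model=spec.model,
        components=components,
        neg2logL=float(neg2),
        mu=float(mu),
        u=u,
        v=v,
        converged=converged,
        n_iter=it,
    )


def mixture_lrt(neg2logL_reduced: float, neg2logL_full: float) -> LRTResult:
    """Boundary likelihood-ratio test for one variance component.

    chi2 = -2logL(reduced) - (-2logL(full)); under the null the statistic is
    distributed as an equal mixture of a point mass at zero and chi-square
    with 1 df, so P = 0.5 * Pr(chi2_1 >= observed) for positive statistics
    and P = 1 otherwise (small negative statistics arise from incomplete
    maximisation and are treated as zero evidence).
    """
    chi2 = float(neg2logL_reduced - neg2logL_full)
    if chi2 <= 0:
        return LRTResult(chi2=chi2, p_value=1.0)
    return LRTResult(chi2=chi2, p_value=float(0.5 * stats.chi2.sf(chi2, df=1)))


def marker_to_animal_variance(
    sigma_a2: float, sigma_d2: float, freqs: np.ndarray
) -> tuple[float, float]:
    """Animal-level variances implied by common per-marker variances:

    sigma_A^2 = sum 2 p q sigma_a^2 + sum 2 p q (q - p)^2 sigma_d^2,
    sigma_D^2 = sum 4 p^2 q^2 sigma_d^2.
    """
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    s_pq = float(np.sum(2.0 * p * q))
    s_pq_qp2 = float(np.sum(2.0 * p * q * (q - p) ** 2))
    s_p2q2 = float(np.sum(4.0 * p**2 * q**2))
    sigma_A2 = s_pq * sigma_a2 + s_pq_qp2 * sigma_d2
    sigma_D2 = s_p2q2 * sigma_d2
    return sigma_A2, sigma_D2


def animal_to_marker_variance(
    sigma_A2: float, sigma_D2: float, freqs: np.ndarray
) -> tuple[float, float]:
    """Invert :func:`marker_to_animal_variance`:

    sigma_d^2 = sigma_D^2 / sum 4 p^2 q^2;
    sigma_a^2 = (sigma_A^2 - sum 2 p q (q-p)^2 sigma_d^2) / sum 2 p q.

    Raises if all loci are monomorphic or if the inputs imply a negative
    per-marker additive variance.
    """
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    s_pq = float(np.sum(2.0 * p * q))
    s_pq_qp2 = float(np.sum(2.0 * p * q * (q - p) ** 2))
    s_p2q2 = float(np.sum(4.0 * p**2 * q**2))
    if s_pq <= 0 or s_p2q2 <= 0:
        raise ValueError("all loci monomorphic: conversion denominators are zero")
    sigma_d2 = sigma_D2 / s_p2q2
    sigma_a2 = (sigma_A2 - s_pq_qp2 * sigma_d2) / s_pq
    if sigma_a2 < 0:
        raise ValueError(
            "inputs imply negative per-marker additive variance "
            f"(sigma_a2 = {sigma_a2:.3g})"
        )
    return sigma_a2, sigma_d2
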