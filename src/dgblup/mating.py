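"""Planned matings from estimated SNP effects.

From per-marker additive and dominance effects (BLUP-SNP at fixed
variances), the expected total genetic value g_hat and breeding value u_hat
of the offspring of every bull x cow pair follow from Mendelian genotype
probabilities:

  g_hat_ij = sum_k [Pr(A1A1) a_k + Pr(A1A2) d_k - Pr(A2A2) a_k]
  u_hat_ij = sum_k [Pr(A1A1)(2-2p) + Pr(A1A2)(1-2p) + Pr(A2A2)(-2p)] alpha_k

with alpha = a + d(q-p). Matings are then selected per cow, maximising
g_hat (total genetic value, realised only in the next generation) or u_hat
(additive gain, accumulable), under a per-bull usage cap. The expected
superiorities Delta-G and Delta-U of a plan are differences between the mean
score of selected matings and the mean over all possible matings, also
expressed relative to the SD over all matings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .containers import GenotypeMatrix, MarkerEffects, VarianceComponents
from .gibbs import snp_design

__all__ = [
    "MatingScores",
    "MatingPlan",
    "snp_blup_effects",
    "offspring_genotype_probs",
    "predict_mating",
    "mating_score_matrices",
    "allocate_matings",
    "gain_summary",
    "relative_criterion_change",
]


@dataclass
class MatingScores:
    """g_hat and u_hat for every bull x cow pair (bulls index rows)."""

    g_hat: np.ndarray
    u_hat: np.ndarray
    bull_ids: np.ndarray
    cow_ids: np.ndarray

    def matrix(self, criterion: str) -> np.ndarray:
        if criterion == "g":
            return self.g_hat
        if criterion == "u":
            return self.u_hat
        raise ValueError("criterion must be 'g' or 'u'")


@dataclass
class MatingPlan:
    """Per-cow bull assignment under a per-bull capacity cap."""

    cow_ids: np.ndarray
    assigned_bull: np.ndarray  # bull index per cow
    bull_usage: np.ndarray  # count per bull
    criterion: str
    cap: int


def snp_blup_effects(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    components: VarianceComponents,
    eop: np.ndarray | None = None,
) -> MarkerEffects:
    """BLUP of per-marker additive and dominance effects at fixed variances.

    Solves the ridge-type joint system for y = 1 mu + T a + X d + e with
    V(a) = I sigma_a2, V(d) = I sigma_d2, V(e) = diag(1/EOP) sigma_E2, via
    the equivalent n-dimensional system (a_hat = sigma_a2 T'V^-1(y - mu),
    d_hat = sigma_d2 X'V^-1(y - mu)); marker-level variances typically come
    from :func:`dgblup.varcomp.animal_to_marker_variance`.
    """
    if components.sigma_a2 is None or components.sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be provided and positive")
    sa2 = float(components.sigma_a2)
    sd2 = float(components.sigma_d2 or 0.0)
    sE2 = float(components.sigma_E2)
    y = np.asarray(y, dtype=float).ravel()
    T, X = snp_design(genotypes)
    n = y.size
    F = np.ones(n) if eop is None else 1.0 / np.asarray(eop, dtype=float).ravel()
    V = sa2 * (T @ T.T) + sE2 * np.diag(F)
    if sd2 > 0:
        V += sd2 * (X @ X.T)
    cho = linalg.cho_factor(V, lower=True)
    ones = np.ones(n)
    mu = float(ones @ linalg.cho_solve(cho, y) / (ones @ linalg.cho_solve(cho, ones)))
    w = linalg.cho_solve(cho, y - mu)
    a_hat = sa2 * (T.T @ w)
    d_hat = sd2 * (X.T @ w) if sd2 > 0 else np.zeros(T.shape[1])
    return MarkerEffects(a=a_hat, d=d_hat)


def offspring_genotype_probs(
    sire_codes: np.ndarray, dam_codes: np.ndarray
) -> np.ndarray:
    """Per-locus offspring genotype distribution [Pr(A1A1), Pr(A1A2),
    Pr(A2A2)] from independent transmission of one allele per parent.

    Parental codes must be complete (0/1/2); the transmission probability of
    A1 is code/2. Returns an (m, 3) array.
    """
    s = np.asarray(sire_codes, dtype=float) / 2.0
    t = np.asarray(dam_codes, dtype=float) / 2.0
    if np.isnan(s).any() or np.isnan(t).any():
        raise ValueError("missing parental genotypes are not supported")
    pr_AA = s * t
    pr_Aa = s * (1 - t) + (1 - s) * t
    pr_aa = (1 - s) * (1 - t)
    return np.stack([pr_AA, pr_Aa, pr_aa], axis=-1)


def predict_mating(
    probs: np.ndarray, effects: MarkerEffects, freqs: np.ndarray
) -> tuple[float, float]:
    """Expected total genetic value and breeding value of one mating from
    its per-locus offspring genotype probabilities."""
    p = np.asarray(freqs, dtype=float)
    alpha = effects.alpha(p)
    pr_AA, pr_Aa, pr_aa = probs[:, 0], probs[:, 1], probs[:, 2]
    g_hat = float(np.sum(pr_AA * effects.a + pr_Aa * effects.d - pr_aa * effects.a))
    w = pr_AA * (2 - 2 * p) + pr_Aa * (1 - 2 * p) + pr_aa * (-2 * p)
    u_hat = float(np.sum(w * alpha))
    return g_hat, u_hat


def mating_score_matrices(
    bulls: GenotypeMatrix, cows: GenotypeMatrix, effects: MarkerEffects,
    freqs: np.ndarray,
) -> MatingScores:
    """g_hat and u_hat for all bull x cow pairs, in closed form.

    With s, t the parents' transmission probabilities of A1,
    Pr(A1A1) - Pr(A2A2) = s + t - 1 and Pr(A1A2) = s + t - 2 s t, so both
    scores decompose into per-parent terms plus one bulls x cows product for
    the heterozygosity term.
    """
    p = np.asarray(freqs, dtype=float)
    alpha = effects.alpha(p)
    S = bulls.codes / 2.0
    C = cows.codes / 2.0
    if np.isnan(S).any() or np.isnan(C).any():
        raise ValueError("missing parental genotypes are not supported")
    # u_hat: parent-average of centered-dosage breeding values
    u_bull = (bulls.codes - 2 * p) @ alpha
    u_cow = (cows.codes - 2 * p) @ alpha
    u_hat = 0.5 * (u_bull[:, None] + u_cow[None, :])
    # g_hat = sum a(s+t-1) + d(s+t) - 2 d s t
    ga_b = (S - 0.5) @ effects.a + S @ effects.d
    ga_c = (C - 0.5) @ effects.a + C @ effects.d
    cross = (S * effects.d) @ C.T
    g_hat = ga_b[:, None] + ga_c[None, :] - 2.0 * cross
    return MatingScores(
        g_hat=g_hat, u_hat=u_hat, bull_ids=bulls.ids, cow_ids=cows.ids
    )


def allocate_matings(
    scores: MatingScores, criterion: str = "g", cap: int = 200
) -> MatingPlan:
    """Greedy global mate selection under a per-bull capacity cap.

    All bull x cow pairs are sorted by score (descending, ties broken by
    bull then cow index); a pair is accepted when the cow is still unmated
    and the bull below the cap. Every cow ends up assigned provided
    bulls * cap >= cows.
    """
    M = scores.matrix(criterion)
    n_bulls, n_cows = M.shape
    if n_bulls * cap < n_cows:
        raise ValueError("infeasible: bulls * cap < number of cows")
    order = np.lexsort(
        (np.tile(np.arange(n_cows), n_bulls),
         np.repeat(np.arange(n_bulls), n_cows),
         -M.ravel())
    )
    assigned = np.full(n_cows, -1, dtype=int)
    usage = np.zeros(n_bulls, dtype=int)
    remaining = n_cows
    for flat in order:
        b, c = divmod(int(flat), n_cows)
        if assigned[c] >= 0 or usage[b] >= cap:
            continue
        assigned[c] = b
        usage[b] += 1
        remaining -= 1
        if remaining == 0:
            break
    return MatingPlan(
        cow_ids=scores.cow_ids,
        assigned_bull=assigned,
        bull_usage=usage,
        criterion=criterion,
        cap=cap,
    )


def gain_summary(plan: MatingPlan, scores: MatingScores) -> dict:
    """Expected total genetic superiority (Delta-G) and additive genetic
    gain (Delta-U) of a plan: mean score of selected matings minus the mean
    over all possible matings, absolute and relative to the SD over all
    possible matings."""
    sel = (plan.assigned_bull, np.arange(len(plan.cow_ids)))
    out = {"criterion": plan.criterion}
    for name, M in (("G", scores.g_hat), ("U", scores.u_hat)):
        delta = float(M[sel].mean() - M.mean())
        sd = float(M.std(ddof=0))
        out[f"delta_{name}"] = delta
        out[f"sd_{name.lower()}_hat"] = sd
        out[f"delta_{name}_relative"] = delta / sd if sd > 0 else 0.0
    return out


def relative_criterion_change(rel_on_g: float, rel_on_u: float) -> float:
    """Percentage change of an SD-relative gain between selection criteria,
    100 * (value under g-selection - value under u-selection) / value under
    u-selection. Positive for the total-genetic-superiority increase of
    g-selection; negative magnitudes quantify the additive-gain reduction."""
    if rel_on_u == 0:
        raise ValueError("reference gain is zero")
    return 100.0 * (rel_on_g - rel_on_u) / rel_on_u
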