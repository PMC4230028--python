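"""Gibbs samplers for the dominance mixed model, at animal and marker level.

``gibbs_animal`` samples the MGD model (y = mu + u + v + e) with blockwise
updates: each genetic effect vector is drawn from its multivariate-normal
full conditional, variance components from their scaled inverse chi-square
conditionals under flat (improper) priors. ``gibbs_snp`` samples the
equivalent marker model y = 1 mu + T a + X d + e with single-site updates of
per-marker additive and dominance effects; with variances held fixed it is
the BLUP-SNP sampler used to feed mate allocation.

Convergence is assessed (never assumed) with the Geweke diagnostic — a
z-score comparing the mean of the early part of the chain against the late
part, with spectral-density variance estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .containers import GenotypeMatrix, VarianceComponents
from .varcomp import ModelSpec, marker_to_animal_variance
from .relmat import RelationshipMatrix

__all__ = [
    "MCMCChain",
    "gibbs_animal",
    "gibbs_snp",
    "geweke_diagnostic",
]


@dataclass
class MCMCChain:
    """Retained posterior samples, one array per parameter."""

    samples: dict
    n_iterations: int
    burn_in: int
    thinning: int
    seed: int
    effect_means: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        expected = (self.n_iterations - self.burn_in) // self.thinning
        for name, arr in self.samples.items():
            if len(arr) != expected:
                raise ValueError(
                    f"chain {name!r} has {len(arr)} samples, expected {expected}"
                )

    def summary(self) -> dict:
        """Posterior mean and SD per parameter (SD across retained samples)."""
        return {
            name: (float(np.mean(arr)), float(np.std(arr, ddof=1)))
            for name, arr in self.samples.items()
        }


def _sample_effect_block(rng, Kinv, sigma2, Finv, sigmaE2, resid):
    """Draw u | rest ~ N(C^-1 r, C^-1), C = Kinv/sigma2 + Finv/sigmaE2."""
    C = Kinv / sigma2 + np.diag(Finv / sigmaE2)
    L = linalg.cholesky(C, lower=True)
    r = Finv * resid / sigmaE2
    mean = linalg.cho_solve((L, True), r)
    z = rng.standard_normal(r.size)
    return mean + linalg.solve_triangular(L, z, lower=True, trans="T")


def _scaled_inv_chi2(rng, ss: float, df: float, floor: float) -> float:
    """Draw from ss / chi2_df (flat-prior variance conditional), floored."""
    if df <= 0:
        return max(ss, floor)
    draw = ss / rng.chisquare(df)
    return max(float(draw), floor)


def gibbs_animal(
    spec: ModelSpec,
    matrices: dict,
    n_iter: int = 20000,
    burn_in: int = 2000,
    thin: int = 10,
    seed: int = 0,
    start: VarianceComponents | None = None,
) -> MCMCChain:
    """Gibbs sampler for the animal-level dominance model MGD.

    Retains (sigma_A2, sigma_D2, sigma_E2) and the per-sample dominance
    ratio sigma_D2/(sigma_A2+sigma_D2); posterior SDs of the ratio therefore
    come from the ratio chain itself rather than a delta-method shortcut.
    Deterministic given ``seed``.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    if spec.model != "MGD":
        raise ValueError("gibbs_animal samples model MGD")
    rng = np.random.default_rng(seed)
    y, n = spec.y, spec.y.size
    Finv = spec.eop.copy()  # F = diag(1/EOP) so F^-1 = diag(EOP)
    G = matrices["G"].values if isinstance(matrices["G"], RelationshipMatrix) else matrices["G"]
    D = matrices["D"].values if isinstance(matrices["D"], RelationshipMatrix) else matrices["D"]
    Ginv = linalg.cho_solve(linalg.cho_factor(G, lower=True), np.eye(n))
    Dinv = linalg.cho_solve(linalg.cho_factor(D, lower=True), np.eye(n))

    vary = float(np.var(y)) or 1.0
    floor = 1e-10 * vary
    if start is None:
        sA2 = sD2 = sE2 = vary / 3.0
    else:
        sA2, sD2, sE2 = (
            max(start.sigma_A2, floor),
            max(start.sigma_D2, floor),
            max(start.sigma_E2, floor),
        )
    u = np.zeros(n)
    v = np.zeros(n)
    mu = float(np.average(y, weights=Finv))

    keep_A, keep_D, keep_E, keep_ratio = [], [], [], []
    u_mean = np.zeros(n)
    v_mean = np.zeros(n)
    kept = 0
    for it in range(n_iter):
        # mean
        resid = y - u - v
        w = float(np.sum(Finv))
        mu = rng.normal(float(np.sum(Finv * resid)) / w, np.sqrt(sE2 / w))
        # genetic effect blocks
        u = _sample_effect_block(rng, Ginv, sA2, Finv, sE2, y - mu - v)
        v = _sample_effect_block(rng, Dinv, sD2, Finv, sE2, y - mu - u)
        # variances: flat priors -> scaled inverse chi-square with df = n - 2
        sA2 = _scaled_inv_chi2(rng, float(u @ Ginv @ u), n - 2, floor)
        sD2 = _scaled_inv_chi2(rng, float(v @ Dinv @ v), n - 2, floor)
        e = y - mu - u - v
        sE2 = _scaled_inv_chi2(rng, float(e @ (Finv * e)), n - 2, floor)
        if it >= burn_in and (it - burn_in) % thin == 0:
            keep_A.append(sA2)
            keep_D.append(sD2)
            keep_E.append(sE2)
            keep_ratio.append(sD2 / (sA2 + sD2))
            u_mean += u
            v_mean += v
            kept += 1
    return MCMCChain(
        samples={
            "sigma_A2": np.array(keep_A),
            "sigma_D2": np.array(keep_D),
            "sigma_E2": np.array(keep_E),
            "dominance_ratio": np.array(keep_ratio),
        },
        n_iterations=n_iter,
        burn_in=burn_in,
        thinning=thin,
        seed=seed,
        effect_means={"u": u_mean / max(kept, 1), "v": v_mean / max(kept, 1)},
    )


def snp_design(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Marker-model incidence matrices: T coded {-1, 0, 1} (codes 0, 1, 2)
    and X coded {0, 1, 0} (heterozygote indicator)."""
    codes = genotypes.codes
    if genotypes.has_missing:
        raise ValueError("genotypes contain missing codes; run QC first")
    T = codes - 1.0
    X = (codes == 1.0).astype(float)
    return T, X


def gibbs_snp(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    n_iter: int = 20000,
    burn_in: int = 2000,
    thin: int = 10,
    seed: int = 0,
    eop: np.ndarray | None = None,
    fixed_variances: tuple[float, float, float] | None = None,
) -> MCMCChain:
    """Single-site Gibbs sampler for the marker-level model
    y = 1 mu + T a + X d + e, V(a) = I sigma_a2, V(d) = I sigma_d2.

    With ``fixed_variances`` = (sigma_a2, sigma_d2, sigma_E2) the variance
    components are held constant (BLUP-SNP); posterior means of the marker
    effects are then the BLUP solutions. Animal-level variances are derived
    per retained sample from the sampled (sigma_a2, sigma_d2). Sampling
    order per iteration: all additive effects, all dominance effects, then
    the variances.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    y = np.asarray(y, dtype=float).ravel()
    T, X = snp_design(genotypes)
    n, m = T.shape
    p = genotypes.allele_freq()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic marker columns present; run QC first")
    rng = np.random.default_rng(seed)
    Finv = np.ones(n) if eop is None else np.asarray(eop, dtype=float).ravel()

    # weighted column cross-products
    tFt = np.einsum("ij,ij->j", T * Finv[:, None], T)
    xFx = np.einsum("ij,ij->j", X * Finv[:, None], X)
    w_sum = float(np.sum(Finv))

    vary = float(np.var(y)) or 1.0
    floor_m = 1e-12 * vary
    if fixed_variances is not None:
        sa2, sd2, sE2 = fixed_variances
        if sa2 <= 0:
            raise ValueError("fixed sigma_a2 must be positive")
        update_var = False
    else:
        sa2 = vary / (2.0 * m)
        sd2 = vary / (4.0 * m)
        sE2 = vary / 2.0
        update_var = True

    a = np.zeros(m)
    d = np.zeros(m)
    mu = float(np.average(y, weights=Finv))
    e = y - mu  # running residual

    keep: dict[str, list] = {k: [] for k in (
        "sigma_a2", "sigma_d2", "sigma_A2", "sigma_D2", "sigma_E2", "dominance_ratio"
    )}
    a_mean = np.zeros(m)
    d_mean = np.zeros(m)
    kept = 0
    for it in range(n_iter):
        # mean
        e += mu
        mu = rng.normal(float(np.sum(Finv * e)) / w_sum, np.sqrt(sE2 / w_sum))
        e -= mu
        # additive effects
        for k in range(m):
            col = T[:, k]
            e += col * a[k]
            prec = tFt[k] / sE2 + 1.0 / sa2
            mean = (col @ (Finv * e)) / sE2 / prec
            a[k] = rng.normal(mean, np.sqrt(1.0 / prec))
            e -= col * a[k]
        # dominance effects
        denom_d = 1.0 / sd2 if sd2 > 0 else np.inf
        for k in range(m):
            col = X[:, k]
            e += col * d[k]
            prec = xFx[k] / sE2 + denom_d
            if np.isinf(prec):
                d[k] = 0.0
            else:
                mean = (col @ (Finv * e)) / sE2 / prec
                d[k] = rng.normal(mean, np.sqrt(1.0 / prec))
            e -= col * d[k]
        if update_var:
            sa2 = _scaled_inv_chi2(rng, float(a @ a), m - 2, floor_m)
            sd2 = _scaled_inv_chi2(rng, float(d @ d), m - 2, floor_m)
            sE2 = _scaled_inv_chi2(rng, float(e @ (Finv * e)), n - 2, floor_m)
        if it >= burn_in and (it - burn_in) % thin == 0:
            sA2, sD2 = marker_to_animal_variance(sa2, sd2, p)
            keep["sigma_a2"].append(sa2)
            keep["sigma_d2"].append(sd2)
            keep["sigma_A2"].append(sA2)
            keep["sigma_D2"].append(sD2)
            keep["sigma_E2"].append(sE2)
            keep["dominance_ratio"].append(sD2 / (sA2 + sD2) if sA2 + sD2 > 0 else 0.0)
            a_mean += a
            d_mean += d
            kept += 1
    return MCMCChain(
        samples={k: np.array(vals) for k, vals in keep.items()},
        n_iterations=n_iter,
        burn_in=burn_in,
        thinning=thin,
        seed=seed,
        effect_means={"a": a_mean / max(kept, 1), "d": d_mean / max(kept, 1),
                      "mu": mu},
    )


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a chain at frequency zero, via a Bartlett-windowed
    autocovariance sum (Newey-West) with bandwidth ~ sqrt(length)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    bw = max(1, int(np.sqrt(n)))
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for lag in range(1, bw + 1):
        gamma = float(xc[lag:] @ xc[:-lag]) / n
        s += 2.0 * (1.0 - lag / (bw + 1.0)) * gamma
    return s


def geweke_diagnostic(
    chain: MCMCChain | np.ndarray, first: float = 0.1, last: float = 0.5
) -> dict | float:
    """Geweke convergence z-score: mean of the first ``first`` fraction of
    the retained chain vs the mean of the last ``last`` fraction, with
    spectral-density (autocorrelation-robust) variance estimates.

    Returns a {parameter: z} dict for an MCMCChain, or a single z for a
    plain array. A constant chain has zero spectral density and yields NaN.
    """

    def _z(x: np.ndarray) -> float:
        n = x.size
        na = max(int(first * n), 2)
        nb = max(int(last * n), 2)
        xa, xb = x[:na], x[-nb:]
        s = _spectral_density_zero(xa) / na + _spectral_density_zero(xb) / nb
        if s <= 0:
            return float("nan")
        return float((xa.mean() - xb.mean()) / np.sqrt(s))

    if isinstance(chain, MCMCChain):
        return {name: _z(np.asarray(arr)) for name, arr in chain.samples.items()}
    return _z(np.asarray(chain, dtype=float))
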