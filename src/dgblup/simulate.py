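"""Synthetic cow-cohort generator.

Emulates a single-generation phenotyped cohort typical of dairy genomic
studies: unrelated founder sires and dams with Hardy-Weinberg genotypes,
offspring produced by gene dropping, many paternal half-sib families and a
small, controlled fraction of full sibs. Trait architecture is additive plus
dominance at a subset of QTL, phenotypes are yield deviations with
heteroscedastic residuals weighted by the effective number of own
performances (EOP).

Loci are simulated unlinked; no linkage map is modelled because none of the
downstream covariance constructions requires one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MarkerEffects, VarianceComponents, make_pedigree_table

__all__ = [
    "SimConfig",
    "simulate_population",
    "assign_effects",
    "simulate_phenotypes",
    "true_variance_components",
    "full_sib_individual_fraction",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the scale of a ~2000-cow single-breed study: 20 sires,
    one offspring cohort with 3% full sibs, MAF uniform on (0.05, 0.5),
    additive:dominance:residual variance of roughly 200:100:150 (arbitrary
    trait units squared) and EOP weights uniform on (1, 3).
    """

    n_sires: int = 20
    n_dams: int = 1000
    n_offspring: int = 2000
    full_sib_fraction: float = 0.03
    m_loci: int = 5000
    n_qtl: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_sigmaA2: float = 200.0
    target_sigmaD2: float = 100.0
    sigmaE2: float = 150.0
    eop_range: tuple[float, float] = (1.0, 3.0)
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl > self.m_loci:
            raise ValueError("n_qtl must not exceed m_loci")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.full_sib_fraction <= 1.0):
            raise ValueError("full_sib_fraction must lie in [0, 1]")
        for name in ("target_sigmaA2", "target_sigmaD2", "sigmaE2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _founder_genotypes(rng: np.random.Generator, n: int, p: np.ndarray) -> np.ndarray:
    # Hardy-Weinberg: each individual carries two independent alleles.
    return (
        rng.binomial(1, p, size=(n, p.size)) + rng.binomial(1, p, size=(n, p.size))
    ).astype(float)


def _gene_drop(rng: np.random.Generator, parent_codes: np.ndarray) -> np.ndarray:
    """Sample one transmitted allele per locus from each parent genotype row."""
    # Pr(transmit A1) = code / 2 for codes {0, 1, 2}
    return rng.binomial(1, parent_codes / 2.0).astype(float)


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Generate pedigree and genotypes for founders plus one offspring cohort.

    Founder genotypes are drawn from Hardy-Weinberg proportions at MAFs
    uniform on ``config.maf_range``; offspring receive one allele per parent
    per locus (gene dropping). ``full_sib_fraction`` is realized exactly (up
    to rounding) as the fraction of offspring that have at least one full
    sib: full-sib pairs are created by repeat matings of a dam to her sire,
    all remaining offspring of a dam are by distinct sires.

    Returns the pedigree table (id, sire, dam, generation) and the genotype
    matrix over all individuals (founders first, generation 0).
    """
    rng = np.random.default_rng(config.seed)
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.m_loci)

    sire_ids = [f"S{i + 1}" for i in range(config.n_sires)]
    dam_ids = [f"D{i + 1}" for i in range(config.n_dams)]
    n_found = config.n_sires + config.n_dams

    n_fs_pairs = int(round(config.full_sib_fraction * config.n_offspring / 2.0))
    n_single = config.n_offspring - 2 * n_fs_pairs
    if n_fs_pairs > config.n_dams:
        raise ValueError(
            "full_sib_fraction requires more repeat-mated dams than available"
        )
    if config.n_offspring > 0 and (config.n_sires == 0 or config.n_dams == 0):
        raise ValueError("offspring require at least one sire and one dam")

    # full-sib pairs: first n_fs_pairs dams (after shuffling) mated twice to
    # one sire; remaining offspring spread round-robin over the other dams,
    # each mating to a sire not previously used by that dam.
    dam_order = rng.permutation(config.n_dams)
    matings: list[tuple[int, int]] = []  # (sire_idx, dam_idx) per offspring
    for k in range(n_fs_pairs):
        d = dam_order[k]
        s = rng.integers(config.n_sires)
        matings.append((s, d))
        matings.append((s, d))
    other_dams = dam_order[n_fs_pairs:]
    if n_single > 0:
        if other_dams.size == 0:
            raise ValueError("not enough dams for the requested offspring count")
        per_dam = -(-n_single // other_dams.size)  # ceil
        if per_dam > config.n_sires:
            raise ValueError(
                "mating design infeasible: a dam would need more distinct sires "
                "than exist"
            )
        used: dict[int, list[int]] = {}
        for j in range(n_single):
            d = other_dams[j % other_dams.size]
            taken = used.setdefault(d, [])
            choices = np.setdiff1d(np.arange(config.n_sires), taken)
            s = int(rng.choice(choices))
            taken.append(s)
            matings.append((s, d))

    ids = sire_ids + dam_ids + [f"O{i + 1}" for i in range(config.n_offspring)]
    sires = [""] * n_found + [sire_ids[s] for s, _ in matings]
    dams = [""] * n_found + [dam_ids[d] for _, d in matings]
    gen = [0] * n_found + [1] * config.n_offspring
    pedigree = make_pedigree_table(ids, sires, dams, gen)

    codes = np.empty((n_found + config.n_offspring, config.m_loci))
    codes[:n_found] = _founder_genotypes(rng, n_found, p)
    for i, (s, d) in enumerate(matings):
        paternal = _gene_drop(rng, codes[s])
        maternal = _gene_drop(rng, codes[config.n_sires + d])
        codes[n_found + i] = paternal + maternal

    locus_ids = np.array([f"snp{k + 1}" for k in range(config.m_loci)])
    genotypes = GenotypeMatrix(codes=codes, ids=np.array(ids), locus_ids=locus_ids)
    return pedigree, genotypes


def full_sib_individual_fraction(pedigree: pd.DataFrame) -> float:
    """Fraction of non-founder individuals with at least one full sib,
    counted exhaustively over all pairs sharing both (known) parents."""
    off = pedigree[(pedigree["sire"] != "") & (pedigree["dam"] != "")]
    if len(off) == 0:
        return 0.0
    sizes = off.groupby(["sire", "dam"]).size()
    return float(sizes[sizes > 1].sum()) / float(len(off))


def assign_effects(genotypes: GenotypeMatrix, config: SimConfig) -> MarkerEffects:
    """Draw additive/dominance QTL effects and rescale them so the implied
    animal-level variances hit the configured targets exactly.

    ``n_qtl`` loci receive a_k, d_k from zero-mean normals; each vector is
    then multiplied by a single scalar such that
    ``true_variance_components`` returns (target_sigmaA2, target_sigmaD2).
    Because the substitution effect mixes a and d, the additive scalar solves
    a quadratic in closed form.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    m = genotypes.m
    a = np.zeros(m)
    d = np.zeros(m)
    if config.n_qtl == 0:
        if config.target_sigmaA2 > 0 or config.target_sigmaD2 > 0:
            raise ValueError("positive variance targets require n_qtl > 0")
        return MarkerEffects(a=a, d=d)

    qtl = rng.choice(m, size=config.n_qtl, replace=False)
    a_raw = rng.standard_normal(config.n_qtl)
    d_raw = rng.standard_normal(config.n_qtl)
    p = genotypes.allele_freq()[qtl]
    q = 1.0 - p
    two_pq = 2.0 * p * q

    # dominance first: sigma_D^2 = sum (2 p q d)^2 scales quadratically in d
    sD_raw = np.sum((two_pq * d_raw) ** 2)
    s_d = np.sqrt(config.target_sigmaD2 / sD_raw) if config.target_sigmaD2 > 0 else 0.0
    d_q = s_d * d_raw

    # additive: sigma_A^2 = sum 2 p q (s_a * a + d_q (q-p))^2, quadratic in s_a
    qp = q - p
    A2 = np.sum(two_pq * a_raw**2)
    B = 2.0 * np.sum(two_pq * a_raw * d_q * qp)
    C = np.sum(two_pq * (d_q * qp) ** 2)
    if config.target_sigmaA2 == 0 and C == 0 and B == 0:
        s_a = 0.0
    else:
        disc = B**2 - 4.0 * A2 * (C - config.target_sigmaA2)
        if disc < 0 or A2 == 0:
            raise ValueError(
                "additive target unattainable for the drawn effects/frequencies"
            )
        s_a = (-B + np.sqrt(disc)) / (2.0 * A2)
    a[qtl] = s_a * a_raw
    d[qtl] = d_q
    return MarkerEffects(a=a, d=d)


def true_variance_components(
    genotypes: GenotypeMatrix, effects: MarkerEffects
) -> VarianceComponents:
    """Animal-level (sigma_A^2, sigma_D^2) implied by realized per-locus
    effects and observed allele frequencies.

    sigma_A^2 = sum_k 2 p q alpha_k^2 with alpha = a + d(q-p);
    sigma_D^2 = sum_k (2 p q d_k)^2.
    """
    p = genotypes.allele_freq()
    q = 1.0 - p
    alpha = effects.alpha(p)
    sigma_A2 = float(np.sum(2.0 * p * q * alpha**2))
    sigma_D2 = float(np.sum((2.0 * p * q * effects.d) ** 2))
    return VarianceComponents(sigma_A2=sigma_A2, sigma_D2=sigma_D2)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    effects: MarkerEffects,
    config: SimConfig,
    ids=None,
) -> pd.DataFrame:
    """Yield deviations with EOP-weighted residual variance.

    y_i = mu + sum_k gv(code_ik) + e_i with e_i ~ N(0, sigmaE2 / EOP_i) and
    EOP_i ~ Uniform(eop_range). ``ids`` restricts phenotyping to a subset
    (default: all individuals in ``genotypes``) — typically the offspring
    cohort, matching a design where only the youngest generation is recorded.
    """
    if genotypes.has_missing:
        raise ValueError("genotypes contain missing codes; run QC first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if ids is None:
        rows = np.arange(genotypes.n)
    else:
        index = {v: i for i, v in enumerate(genotypes.ids)}
        rows = np.array([index[i] for i in ids])
    codes = genotypes.codes[rows]
    g = effects.genotypic_values(codes)
    eop = rng.uniform(config.eop_range[0], config.eop_range[1], size=rows.size)
    e = rng.standard_normal(rows.size) * np.sqrt(config.sigmaE2 / eop)
    y = config.mu + g + e
    return pd.DataFrame({"id": genotypes.ids[rows], "yd": y, "eop": eop})
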