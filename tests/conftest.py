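import numpy as np
import pytest

from dgblup.containers import GenotypeMatrix
from dgblup.relmat import build_D, build_G, pedigree_A
from dgblup.simulate import (
    SimConfig,
    assign_effects,
    simulate_phenotypes,
    simulate_population,
    true_variance_components,
)


def make_genotypes(codes, p_override=None):
    codes = np.asarray(codes, dtype=float)
    n, m = codes.shape
    return GenotypeMatrix(
        codes=codes,
        ids=np.array([f"i{k}" for k in range(n)]),
        locus_ids=np.array([f"l{k}" for k in range(m)]),
    )


def build_cohort(cfg: SimConfig) -> dict:
    """Simulate a cohort and assemble everything downstream stages need."""
    pedigree, genotypes = simulate_population(cfg)
    effects = assign_effects(genotypes, cfg)
    offspring = pedigree.loc[pedigree["generation"] > 0, "id"].to_numpy()
    phen = simulate_phenotypes(genotypes, effects, cfg, ids=offspring)
    index = {v: i for i, v in enumerate(genotypes.ids)}
    rows = np.array([index[i] for i in phen["id"]])
    cohort_geno = genotypes.subset(rows=rows)
    A = pedigree_A(pedigree).subset(list(phen["id"]))
    G = build_G(cohort_geno, A)
    D = build_D(cohort_geno)
    return {
        "config": cfg,
        "pedigree": pedigree,
        "genotypes": genotypes,
        "cohort_geno": cohort_geno,
        "effects": effects,
        "truth": true_variance_components(genotypes, effects),
        "phenotypes": phen,
        "y": phen["yd"].to_numpy(),
        "eop": phen["eop"].to_numpy(),
        "A": A,
        "G": G,
        "D": D,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-cow cohort with 10 sires, dominance at a third of the genetic
    variance, shared across tests that only need realistic structure."""
    cfg = SimConfig(
        n_sires=10,
        n_dams=150,
        n_offspring=300,
        m_loci=800,
        n_qtl=100,
        seed=3,
    )
    return build_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
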