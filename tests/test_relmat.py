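"""Relationship matrices: textbook pedigree values, an independent kinship
oracle, design-matrix algebra and scaling/blending behaviour."""

import numpy as np
import pandas as pd
import pytest

from dgblup.containers import make_pedigree_table
from dgblup.relmat import (
    RelationshipMatrix,
    blend,
    build_D,
    build_D_star,
    build_G,
    build_G_star,
    identity_matrix,
    marker_design,
    offdiag_summary,
    pedigree_A,
    scale_to_A,
)
from dgblup.simulate import SimConfig, simulate_population

from conftest import make_genotypes


def kinship_oracle(ped: pd.DataFrame):
    """Independent coancestry recursion (Karigl): f(i,j) memoised on ids;
    A_ij = 2 f(i,j). Used only on tiny pedigrees."""
    parents = {r.id: (r.sire or None, r.dam or None) for r in ped.itertuples(index=False)}
    order = {v: k for k, v in enumerate(ped["id"])}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i, j):
        if i is None or j is None:
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        s, d = parents[i]
        if i == j:
            return 0.5 + 0.5 * f(s, d)
        return 0.5 * (f(s, j) + f(d, j))

    return lambda i, j: 2.0 * f(i, j)


class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        ped = make_pedigree_table(["a", "b"], ["", ""], ["", ""], [0, 0])
        np.testing.assert_array_equal(pedigree_A(ped).values, np.eye(2))

    def test_parent_offspring_half(self):
        ped = make_pedigree_table(["s", "o"], ["", "s"], ["", ""], [0, 1])
        A = pedigree_A(ped).values
        assert A[0, 1] == pytest.approx(0.5)
        assert A[1, 1] == pytest.approx(1.0)

    def test_full_sibs_half_related(self):
        ped = make_pedigree_table(
            ["s", "d", "o1", "o2"], ["", "", "s", "s"], ["", "", "d", "d"], [0, 0, 1, 1]
        )
        A = pedigree_A(ped).values
        assert A[2, 3] == pytest.approx(0.5)
        assert A[2, 2] == pytest.approx(1.0)

    def test_matches_kinship_oracle_on_small_pedigrees(self):
        cfg = SimConfig(n_sires=2, n_dams=3, n_offspring=5, m_loci=5, n_qtl=1,
                        full_sib_fraction=0.4, seed=13)
        ped, _ = simulate_population(cfg)
        A = pedigree_A(ped)
        oracle = kinship_oracle(ped)
        for i, idi in enumerate(A.ids):
            for j, idj in enumerate(A.ids):
                assert A.values[i, j] == pytest.approx(oracle(idi, idj))

    def test_unordered_pedigree_raises(self):
        ped = pd.DataFrame(
            {"id": ["o", "s"], "sire": ["s", ""], "dam": ["", ""], "generation": [1, 0]}
        )
        with pytest.raises(ValueError, match="not listed before|ordered"):
            pedigree_A(ped)


class TestGStar:
    def test_two_homozygotes_single_locus(self):
        # p = 0.5 is enforced by overriding observed freqs
        g = make_genotypes([[2.0], [2.0]])
        G = build_G_star(g, freqs=np.array([0.5]))
        assert G.values[0, 1] == pytest.approx(2.0)

    def test_heterozygote_row_zero(self):
        g = make_genotypes([[1.0], [2.0], [0.0]])
        G = build_G_star(g, freqs=np.array([0.5]))
        np.testing.assert_allclose(G.values[0], 0.0, atol=1e-12)

    def test_cross_product_equals_brute_force(self, rng):
        codes = rng.integers(0, 3, size=(8, 20)).astype(float)
        g = make_genotypes(codes)
        md = marker_design(g)
        G = build_G_star(g).values
        D = build_D_star(g).values
        for i in range(8):
            for j in range(8):
                assert G[i, j] == pytest.approx(
                    sum(md.W_a[i, k] * md.W_a[j, k] for k in range(20)) / md.denom_a
                )
                assert D[i, j] == pytest.approx(
                    sum(md.W_d[i, k] * md.W_d[j, k] for k in range(20)) / md.denom_d
                )


class TestDStar:
    def test_two_heterozygotes(self):
        g = make_genotypes([[1.0], [1.0]])
        D = build_D_star(g, freqs=np.array([0.5]))
        assert D.values[0, 1] == pytest.approx(1.0)

    def test_het_times_homozygote(self):
        g = make_genotypes([[1.0], [2.0]])
        D = build_D_star(g, freqs=np.array([0.5]))
        assert D.values[0, 1] == pytest.approx(-1.0)

    def test_wd_column_sums_to_zero_in_exact_hwe(self):
        # counts 25/50/25 at p=0.5: p^2(-2q^2) + 2pq(2pq) + q^2(-2p^2) = 0
        codes = np.array([2.0] * 25 + [1.0] * 50 + [0.0] * 25)[:, None]
        md = marker_design(make_genotypes(codes))
        assert md.W_d[:, 0].sum() == pytest.approx(0.0, abs=1e-10)


class TestScaleBlend:
    def test_fixed_point_when_means_match(self, rng):
        codes = rng.integers(0, 3, size=(30, 200)).astype(float)
        G = build_G_star(make_genotypes(codes))
        scaled = scale_to_A(G, G)
        np.testing.assert_allclose(scaled.values, G.values, atol=1e-10)

    def test_two_by_two_moment_solution(self):
        # G* with mean diag 1.2, mean offdiag 0.2 against A = I
        n = 4
        Gv = np.full((n, n), 0.2) + np.eye(n)
        G = RelationshipMatrix(values=Gv, kind="G_star", ids=np.arange(n))
        A = identity_matrix(np.arange(n))
        scaled = scale_to_A(G, A)
        np.testing.assert_allclose(scaled.values, Gv - 0.2, atol=1e-12)

    def test_output_moments_match_exactly(self, small_cohort):
        G = small_cohort["G"]
        A = small_cohort["A"]
        n = G.n
        assert np.trace(G.values) / n == pytest.approx(np.trace(A.values) / n)
        off = lambda M: (M.sum() - np.trace(M)) / (n * (n - 1))
        assert off(G.values) == pytest.approx(off(A.values))

    def test_degenerate_scaling_raises(self):
        M = RelationshipMatrix(values=np.ones((3, 3)), kind="G_star", ids=np.arange(3))
        A = identity_matrix(np.arange(3))
        with pytest.raises(ValueError, match="degenerate"):
            scale_to_A(M, A)

    @pytest.mark.parametrize("weight,expect", [(1.0, "star"), (0.0, "partner")])
    def test_blend_endpoints(self, weight, expect, rng):
        codes = rng.integers(0, 3, size=(10, 50)).astype(float)
        D = build_D_star(make_genotypes(codes))
        I = identity_matrix(D.ids)
        out = blend(D, I, weight)
        ref = D.values if expect == "star" else I.values
        np.testing.assert_allclose(out.values, ref, atol=1e-12)

    def test_blended_D_min_eigenvalue(self, small_cohort):
        evals = np.linalg.eigvalsh(small_cohort["D"].values)
        assert evals.min() >= 0.05 - 1e-8

    def test_scale_preserves_positive_definiteness(self, small_cohort):
        evals = np.linalg.eigvalsh(small_cohort["G"].values)
        assert evals.min() > 0


class TestOffdiagSummary:
    def test_identity(self):
        s = offdiag_summary(identity_matrix(np.arange(5)), 0.05)
        assert s["mean"] == 0.0 and s["sd"] == 0.0 and s["prop_extreme"] == 0.0

    def test_direct_count(self):
        M = np.eye(3)
        M[0, 1] = M[1, 0] = 0.06
        M[0, 2] = M[2, 0] = -0.06
        M[1, 2] = M[2, 1] = 0.01
        s = offdiag_summary(RelationshipMatrix(values=M, kind="G", ids=np.arange(3)), 0.05)
        assert s["prop_extreme"] == pytest.approx(2 / 3)

    def test_cohort_offdiag_means_zero_and_D_tighter_than_G(self):
        """Half-sib-structured cohort: mean off-diagonals ~ 0 for both
        matrices, while the dominance matrix is less dispersed than the
        additive one (half sibs share additive but essentially no dominance
        relationship)."""
        cfg = SimConfig(n_sires=10, n_dams=250, n_offspring=500, m_loci=3000,
                        n_qtl=10, seed=21)
        ped, geno = simulate_population(cfg)
        off = ped.loc[ped["generation"] > 0, "id"]
        rows = np.array([list(geno.ids).index(i) for i in off])
        cohort = geno.subset(rows=rows)
        G = build_G_star(cohort)
        D = build_D_star(cohort)
        sG = offdiag_summary(G)
        sD = offdiag_summary(D)
        assert abs(sG["mean"]) < 0.01
        assert abs(sD["mean"]) < 0.01
        assert sD["sd"] < sG["sd"]
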