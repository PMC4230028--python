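"""Mate allocation: Mendelian genotype probabilities, expected progeny
values, greedy allocation under capacity, and gain summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgblup.containers import MarkerEffects, VarianceComponents
from dgblup.mating import (
    MatingScores,
    allocate_matings,
    gain_summary,
    mating_score_matrices,
    offspring_genotype_probs,
    predict_mating,
    relative_criterion_change,
    snp_blup_effects,
)
from dgblup.simulate import SimConfig

from conftest import build_cohort, make_genotypes


class TestGenotypeProbs:
    @pytest.mark.parametrize(
        "s,d,expected",
        [
            (2, 0, (0, 1, 0)),
            (1, 1, (0.25, 0.5, 0.25)),
            (2, 1, (0.5, 0.5, 0)),
            (0, 0, (0, 0, 1)),
        ],
    )
    def test_known_crosses(self, s, d, expected):
        probs = offspring_genotype_probs(np.array([s]), np.array([d]))
        np.testing.assert_allclose(probs[0], expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=1, max_size=10),
           st.lists(st.integers(0, 2), min_size=1, max_size=10))
    def test_triples_sum_to_one_and_quartered(self, s, d):
        m = min(len(s), len(d))
        probs = offspring_genotype_probs(np.array(s[:m]), np.array(d[:m]))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)
        assert np.isin(probs, [0.0, 0.25, 0.5, 1.0]).all()

    def test_missing_parent_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            offspring_genotype_probs(np.array([np.nan]), np.array([1.0]))


class TestPredictMating:
    def test_het_by_het_hand_value(self):
        eff = MarkerEffects(a=np.array([2.0]), d=np.array([1.0]))
        probs = offspring_genotype_probs(np.array([1]), np.array([1]))
        g, _ = predict_mating(probs, eff, np.array([0.5]))
        assert g == pytest.approx(0.25 * 2 + 0.5 * 1 - 0.25 * 2) == 0.5

    def test_het_by_het_breeding_value_zero_at_half(self):
        eff = MarkerEffects(a=np.array([3.0]), d=np.array([1.5]))
        probs = offspring_genotype_probs(np.array([1]), np.array([1]))
        _, u = predict_mating(probs, eff, np.array([0.5]))
        assert u == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_effects(self, rng):
        m = 12
        eff = MarkerEffects(a=rng.standard_normal(m), d=rng.standard_normal(m))
        eff2 = MarkerEffects(a=2 * eff.a, d=2 * eff.d)
        p = rng.uniform(0.1, 0.5, m)
        probs = offspring_genotype_probs(
            rng.integers(0, 3, m), rng.integers(0, 3, m)
        )
        g1, u1 = predict_mating(probs, eff, p)
        g2, u2 = predict_mating(probs, eff2, p)
        assert g2 == pytest.approx(2 * g1)
        assert u2 == pytest.approx(2 * u1)


@pytest.fixture(scope="module")
def fixture(rng):
    m = 30
    bulls = make_genotypes(rng.integers(0, 3, size=(5, m)).astype(float))
    cows = make_genotypes(rng.integers(0, 3, size=(12, m)).astype(float))
    eff = MarkerEffects(a=rng.standard_normal(m), d=rng.standard_normal(m))
    p = rng.uniform(0.05, 0.5, m)
    return bulls, cows, eff, p


class TestScoreMatrices:
    def test_matches_per_pair_evaluation(self, fixture):
        bulls, cows, eff, p = fixture
        scores = mating_score_matrices(bulls, cows, eff, p)
        for i in range(bulls.n):
            for j in range(cows.n):
                probs = offspring_genotype_probs(bulls.codes[i], cows.codes[j])
                g, u = predict_mating(probs, eff, p)
                assert scores.g_hat[i, j] == pytest.approx(g, abs=1e-10)
                assert scores.u_hat[i, j] == pytest.approx(u, abs=1e-10)

    def test_g_matches_gamete_enumeration_oracle(self, fixture):
        """Expected total genetic value equals the average over the four
        equiprobable gamete combinations at each locus."""
        bulls, cows, eff, p = fixture

        def gamete_oracle(sire, dam):
            total = 0.0
            for k in range(len(sire)):
                vals = []
                s_gams = [1] * int(sire[k]) + [0] * (2 - int(sire[k]))
                d_gams = [1] * int(dam[k]) + [0] * (2 - int(dam[k]))
                for gs, gd in itertools.product(s_gams, d_gams):
                    c = gs + gd
                    vals.append(eff.a[k] if c == 2 else eff.d[k] if c == 1 else -eff.a[k])
                total += np.mean(vals)
            return total

        scores = mating_score_matrices(bulls, cows, eff, p)
        for i in range(3):
            for j in range(4):
                assert scores.g_hat[i, j] == pytest.approx(
                    gamete_oracle(bulls.codes[i], cows.codes[j]), abs=1e-10
                )

    def test_parent_average_law_exact(self, fixture):
        bulls, cows, eff, p = fixture
        alpha = eff.alpha(p)
        u_b = (bulls.codes - 2 * p) @ alpha
        u_c = (cows.codes - 2 * p) @ alpha
        scores = mating_score_matrices(bulls, cows, eff, p)
        np.testing.assert_allclose(
            scores.u_hat, 0.5 * (u_b[:, None] + u_c[None, :]), atol=1e-10
        )


class TestAllocation:
    def _scores(self, M):
        M = np.asarray(M, dtype=float)
        return MatingScores(
            g_hat=M, u_hat=M,
            bull_ids=np.arange(M.shape[0]), cow_ids=np.arange(M.shape[1]),
        )

    def test_uncapped_gives_argmax(self, rng):
        M = rng.standard_normal((4, 9))
        plan = allocate_matings(self._scores(M), "g", cap=9)
        np.testing.assert_array_equal(plan.assigned_bull, M.argmax(axis=0))

    def test_greedy_trace_and_brute_force(self):
        """Bull 1 best for all cows but capped at 2: the greedy result also
        maximises the total score over all feasible plans."""
        M = np.array([[5.0, 4.0, 3.0], [2.0, 1.0, 0.0]])
        plan = allocate_matings(self._scores(M), "g", cap=2)
        np.testing.assert_array_equal(plan.assigned_bull, [0, 0, 1])
        np.testing.assert_array_equal(plan.bull_usage, [2, 1])
        best = max(
            (sum(M[b, c] for c, b in enumerate(combo)), combo)
            for combo in itertools.product([0, 1], repeat=3)
            if max(np.bincount(combo, minlength=2)) <= 2
        )
        assert sum(M[plan.assigned_bull[c], c] for c in range(3)) == best[0]

    def test_capacity_never_violated(self, rng):
        M = rng.standard_normal((6, 50))
        plan = allocate_matings(self._scores(M), "g", cap=10)
        assert plan.bull_usage.max() <= 10
        assert (plan.assigned_bull >= 0).all()

    def test_infeasible_raises(self, rng):
        M = rng.standard_normal((2, 50))
        with pytest.raises(ValueError, match="infeasible"):
            allocate_matings(self._scores(M), "g", cap=10)


class TestGainSummary:
    def test_all_matings_selected_zero_gain(self):
        M = np.full((2, 4), 3.0)
        scores = MatingScores(g_hat=M, u_hat=M, bull_ids=np.arange(2),
                              cow_ids=np.arange(4))
        plan = allocate_matings(scores, "g", cap=4)
        out = gain_summary(plan, scores)
        assert out["delta_G"] == pytest.approx(0.0)
        assert out["delta_U"] == pytest.approx(0.0)

    def test_constant_locus_offset_cancels_in_delta(self, rng):
        M = rng.standard_normal((3, 8))
        U = rng.standard_normal((3, 8))
        s1 = MatingScores(g_hat=M, u_hat=U, bull_ids=np.arange(3), cow_ids=np.arange(8))
        s2 = MatingScores(g_hat=M + 5.0, u_hat=U, bull_ids=np.arange(3),
                          cow_ids=np.arange(8))
        p1 = allocate_matings(s1, "g", cap=8)
        p2 = allocate_matings(s2, "g", cap=8)
        assert gain_summary(p1, s1)["delta_G"] == pytest.approx(
            gain_summary(p2, s2)["delta_G"]
        )

    @pytest.mark.parametrize(
        "rel_g,rel_u,expected",
        [(1.01, 0.88, 14.8), (1.01, 0.79, 27.8), (0.85, 0.89, -4.5), (0.74, 0.76, -2.6)],
    )
    def test_published_relative_changes(self, rel_g, rel_u, expected):
        """SD-relative gains under the two selection criteria reproduce the
        published percentage changes for milk and protein yield."""
        assert relative_criterion_change(rel_g, rel_u) == pytest.approx(
            expected, abs=0.05
        )


class TestEndToEnd:
    def test_g_selection_dominates_in_total_genetic_value(self):
        """On simulated cohorts, the plan selected on g-hat achieves mean
        g-hat at least as high as the plan selected on u-hat."""
        wins = 0
        for seed in (31, 32, 33):
            cfg = SimConfig(n_sires=6, n_dams=80, n_offspring=160, m_loci=400,
                            n_qtl=80, seed=seed)
            data = build_cohort(cfg)
            geno = data["cohort_geno"]
            p = geno.allele_freq()
            from dgblup.varcomp import animal_to_marker_variance

            sa2, sd2 = animal_to_marker_variance(200.0, 100.0, p)
            comp = VarianceComponents(sigma_A2=200.0, sigma_D2=100.0,
                                      sigma_E2=150.0, sigma_a2=sa2, sigma_d2=sd2)
            eff = snp_blup_effects(data["y"], geno, comp, eop=data["eop"])
            top = np.argsort(-((geno.codes - 2 * p) @ eff.alpha(p)))[:10]
            cows = np.setdiff1d(np.arange(geno.n), top)
            scores = mating_score_matrices(
                geno.subset(rows=top), geno.subset(rows=cows), eff, p
            )
            g_plan = allocate_matings(scores, "g", cap=30)
            u_plan = allocate_matings(scores, "u", cap=30)
            gg = gain_summary(g_plan, scores)["delta_G"]
            gu = gain_summary(u_plan, scores)["delta_G"]
            wins += gg >= gu - 1e-12
        assert wins == 3

    def test_snp_blup_recovers_effects_in_low_noise_limit(self):
        """Near-zero residual variance with n >> m: BLUP shrinkage vanishes
        and the generating effects are recovered."""
        rng = np.random.default_rng(5)
        n, m = 300, 15
        codes = rng.integers(0, 3, size=(n, m)).astype(float)
        geno = make_genotypes(codes)
        a_true = rng.standard_normal(m)
        d_true = rng.standard_normal(m) * 0.5
        eff_true = MarkerEffects(a=a_true, d=d_true)
        y = eff_true.genotypic_values(codes)
        comp = VarianceComponents(sigma_A2=1.0, sigma_D2=1.0, sigma_E2=1e-8,
                                  sigma_a2=10.0, sigma_d2=10.0)
        est = snp_blup_effects(y, geno, comp)
        np.testing.assert_allclose(est.a, a_true, atol=1e-3)
        np.testing.assert_allclose(est.d, d_true, atol=1e-3)
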