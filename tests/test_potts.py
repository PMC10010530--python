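import itertools

import numpy as np
import pytest

import evopotts as ep
from evopotts.potts import (
    field_contributions,
    n_double_mutant_combinations,
    pair_indices,
)
from tests.conftest import random_potts


class TestScore:
    def test_zero_model_scores_zero(self, rng):
        model = ep.PottsModel.zeros(8)
        seq = rng.integers(0, 20, 8)
        assert ep.score(model, seq) == 0.0

    def test_single_site_model_is_field(self, rng):
        h = rng.normal(0, 1, (1, 20))
        model = ep.PottsModel(h, np.zeros((0, 20, 20)))
        for a in range(20):
            assert ep.score(model, np.array([a])) == pytest.approx(h[0, a])

    def test_matches_explicit_sum(self, rng):
        model = random_potts(5, seed=3)
        seq = rng.integers(0, 20, 5)
        expected = model.h[np.arange(5), seq].sum()
        for i in range(5):
            for j in range(i + 1, 5):
                expected += model.coupling_block(i, j)[seq[i], seq[j]]
        assert ep.score(model, seq) == pytest.approx(expected)

    def test_linear_in_parameters(self, rng):
        m1, m2 = random_potts(4, 1), random_potts(4, 2)
        both = ep.PottsModel(m1.h + m2.h, m1.e + m2.e)
        seq = rng.integers(0, 20, 4)
        assert ep.score(both, seq) == pytest.approx(
            ep.score(m1, seq) + ep.score(m2, seq)
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ep.score(ep.PottsModel.zeros(4), "ACD")


class TestZeroSumGauge:
    def test_row_and_column_sums_vanish(self):
        model = random_potts(6, seed=11)
        ep_gauged = ep.zero_sum_gauge(model)
        assert np.abs(ep_gauged.sum(axis=1)).max() < 1e-10
        assert np.abs(ep_gauged.sum(axis=2)).max() < 1e-10

    def test_idempotent(self):
        model = random_potts(6, seed=12)
        once = ep.zero_sum_gauge(model)
        twice = ep.zero_sum_gauge(ep.PottsModel(model.h, once))
        assert np.allclose(once, twice)

    def test_score_differences_preserved(self, rng):
        model = random_potts(7, seed=13)
        gauged = ep.to_zero_sum_gauge(model)
        for _ in range(20):
            s1, s2 = rng.integers(0, 20, (2, 7))
            d_orig = ep.score(model, s1) - ep.score(model, s2)
            d_gauge = ep.score(gauged, s1) - ep.score(gauged, s2)
            assert d_gauge == pytest.approx(d_orig, rel=1e-9, abs=1e-9)

    def test_random_gauge_shift_preserves_differences(self, rng):
        # adding per-site constants to h and absorbing per-(i, a) shifts
        # between h and e changes no score difference
        model = random_potts(5, seed=14)
        iu, ju = pair_indices(5)
        h2, e2 = model.h.copy(), model.e.copy()
        h2 += rng.normal(0, 1, (5, 1))  # per-site constants
        for p in range(iu.size):
            shift = rng.normal(0, 1, 20)  # depends on i's amino acid only
            e2[p] += shift[:, None]
            h2[iu[p]] -= shift
        shifted = ep.PottsModel(h2, e2)
        for _ in range(10):
            s1, s2 = rng.integers(0, 20, (2, 5))
            assert ep.score(shifted, s1) - ep.score(shifted, s2) == pytest.approx(
                ep.score(model, s1) - ep.score(model, s2), rel=1e-9, abs=1e-9
            )


class TestMutationEffectMap:
    def test_wildtype_entries_zero(self, rng):
        model = random_potts(6, seed=21)
        wt = rng.integers(0, 20, 6)
        eff = ep.mutation_effect_map(model, wt)
        assert np.allclose(eff[np.arange(6), wt], 0.0)

    def test_coupling_free_model_reduces_to_fields(self, rng):
        h = rng.normal(0, 1, (6, 20))
        model = ep.PottsModel(h, np.zeros((15, 20, 20)))
        wt = rng.integers(0, 20, 6)
        eff = ep.mutation_effect_map(model, wt)
        assert np.allclose(eff, h - h[np.arange(6), wt][:, None])

    def test_matches_direct_score_differences(self, rng):
        model = random_potts(5, seed=22)
        wt = rng.integers(0, 20, 5)
        eff = ep.mutation_effect_map(model, wt)
        base = ep.score(model, wt)
        for i in range(5):
            for a in range(20):
                mut = wt.copy()
                mut[i] = a
                assert eff[i, a] == pytest.approx(ep.score(model, mut) - base)


class TestInteractionScores:
    def test_zero_couplings_zero_scores(self):
        model = ep.PottsModel.zeros(10)
        assert ep.interaction_scores(model).F.max() == 0.0

    def test_planted_block_tops_ranking(self, rng):
        model = ep.PottsModel.zeros(12)
        iu, ju = pair_indices(12)
        p = int(np.flatnonzero((iu == 1) & (ju == 9))[0])
        model.e[p] = rng.normal(0, 1, (20, 20))
        ranked = ep.interaction_scores(model).ranked_long_range_pairs()
        assert (ranked[0, 0], ranked[0, 1]) == (1, 9)

    def test_frobenius_matches_brute_force(self, rng):
        model = random_potts(8, seed=31)
        scores = ep.interaction_scores(model)
        gauged = ep.zero_sum_gauge(model)
        iu, ju = pair_indices(8)
        p = 5
        brute = np.sqrt(sum(gauged[p][a, b] ** 2 for a in range(20) for b in range(20)))
        assert scores.F[iu[p], ju[p]] == pytest.approx(brute)

    def test_symmetry_and_zero_diagonal(self):
        model = random_potts(6, seed=32)
        F = ep.interaction_scores(model).F
        assert np.allclose(F, F.T) and np.allclose(np.diag(F), 0)

    def test_short_range_pairs_excluded_from_ranking(self):
        model = random_potts(10, seed=33)
        ranked = ep.interaction_scores(model, min_separation=5).ranked_long_range_pairs()
        assert (ranked[:, 1] - ranked[:, 0] > 5).all()

    def test_gauge_invariance_of_scores(self, rng):
        model = random_potts(6, seed=34)
        gauged = ep.to_zero_sum_gauge(model)
        F1 = ep.interaction_scores(model).F
        F2 = ep.interaction_scores(gauged).F
        assert np.allclose(F1, F2, atol=1e-10)


def brute_force_epistasis(model, wt, tol):
    """Independent 4-genotype enumeration over every pair and mutant combo."""
    L = model.L
    counts = {"additive": 0, "sign": 0, "reciprocal": 0}
    base = ep.score(model, wt)
    for i, j in itertools.combinations(range(L), 2):
        for a in range(20):
            if a == wt[i]:
                continue
            for b in range(20):
                if b == wt[j]:
                    continue
                sa = wt.copy(); sa[i] = a
                sb = wt.copy(); sb[j] = b
                sab = sa.copy(); sab[j] = b
                dA = ep.score(model, sa) - base
                dB = ep.score(model, sb) - base
                dAB = ep.score(model, sab) - ep.score(model, sb)
                dBA = ep.score(model, sab) - ep.score(model, sa)
                flipA = abs(dA) >= tol and abs(dAB) >= tol and np.sign(dA) != np.sign(dAB)
                flipB = abs(dB) >= tol and abs(dBA) >= tol and np.sign(dB) != np.sign(dBA)
                if flipA and flipB:
                    counts["reciprocal"] += 1
                elif flipA or flipB:
                    counts["sign"] += 1
                else:
                    counts["additive"] += 1
    return counts


class TestEpistasis:
    def test_coupling_free_model_is_purely_additive(self, rng):
        h = rng.normal(0, 1, (8, 20))
        model = ep.PottsModel(h, np.zeros((28, 20, 20)))
        wt = rng.integers(0, 20, 8)
        res = ep.classify_epistasis(model, wt)
        assert res.n_sign == 0 and res.n_reciprocal == 0
        assert res.n_additive == n_double_mutant_combinations(8)

    def test_constructed_reciprocal_sign_pair(self):
        # two mutations individually beneficial but deleterious combined
        model = ep.PottsModel.zeros(2)
        model.h[0, 1] = 1.0  # A->C at site 1 beneficial
        model.h[1, 1] = 1.0
        model.e[0][1, 1] = -5.0  # strong negative interaction
        wt = np.array([0, 0])
        res = ep.classify_epistasis(model, wt)
        assert res.n_reciprocal >= 1
        assert [1, 1] in res.reciprocal_pairs[:, 2:].tolist()

    def test_matches_brute_force_enumeration(self, rng):
        model = random_potts(6, seed=41, coupling_scale=0.5)
        wt = rng.integers(0, 20, 6)
        res = ep.classify_epistasis(model, wt, tolerance=1e-9)
        brute = brute_force_epistasis(model, wt, tol=1e-9)
        assert res.n_additive == brute["additive"]
        assert res.n_sign == brute["sign"]
        assert res.n_reciprocal == brute["reciprocal"]

    def test_candidate_count_formula(self):
        assert n_double_mutant_combinations(186) == 6_211_005


class TestSerialization:
    def test_model_round_trip(self, tmp_path):
        model = random_potts(5, seed=51)
        path = tmp_path / "model.npz"
        model.save(path)
        back = ep.PottsModel.load(path)
        assert np.allclose(back.h, model.h) and np.allclose(back.e, model.e)


class TestFieldContributions:
    def test_consistent_with_score(self, rng):
        model = random_potts(6, seed=61)
        aa = rng.integers(0, 20, 6)
        E = field_contributions(model, aa)
        # score equals sum of E at the sequence minus double-counted couplings
        coupling = ep.score(model, aa) - model.h[np.arange(6), aa].sum()
        assert E[np.arange(6), aa].sum() == pytest.approx(
            model.h[np.arange(6), aa].sum() + 2 * coupling
        )
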