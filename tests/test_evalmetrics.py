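from itertools import combinations

import numpy as np
import pytest

from modmindy import (
    ModulationMatrix,
    gamma_value_summary,
    masked_correlation,
    modulation_impact,
    split_half_reliability,
)


def pearson_oracle(a, b):
    """From-definition covariance-ratio Pearson correlation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum()))


class TestMaskedCorrelation:
    def test_self_correlation_is_one(self, small_bundle):
        p = small_bundle.params
        rep = masked_correlation(p, p)
        assert rep.r_full_W == pytest.approx(1.0, abs=1e-12)
        assert rep.r_Wee == pytest.approx(1.0, abs=1e-12)
        assert rep.r_Wei == pytest.approx(1.0, abs=1e-12)
        for r in rep.r_gamma_ee + rep.r_gamma_ei:
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_uniform_scaling_invariance(self, small_bundle):
        """Parameters are identified up to scale; the metric must not
        penalize a uniform rescaling."""
        p = small_bundle.params
        q = p.copy()
        q.W.Wee *= 2.0
        q.W.Wei *= 2.0
        q.W.Wie *= 2.0
        q.W.Wii *= 2.0
        rep = masked_correlation(p, q)
        assert rep.r_full_W == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_pearson_oracle(self, small_bundle):
        rng = np.random.default_rng(2)
        p = small_bundle.params
        q = p.copy()
        q.W.Wee = np.abs(p.W.Wee + rng.normal(scale=0.2, size=p.W.Wee.shape))
        q.W.Wee[~p.W.mask_ee] = 0
        rep = masked_correlation(p, q)
        want = pearson_oracle(p.W.Wee[p.W.mask_ee], q.W.Wee[p.W.mask_ee])
        assert rep.r_Wee == pytest.approx(want, abs=1e-12)

    def test_symmetric_in_arguments(self, small_bundle):
        rng = np.random.default_rng(3)
        p = small_bundle.params
        q = p.copy()
        q.W.Wei = np.abs(p.W.Wei + rng.normal(scale=0.3, size=p.W.Wei.shape))
        q.W.Wei[~p.W.mask_ei] = 0
        assert masked_correlation(p, q).r_Wei == pytest.approx(
            masked_correlation(q, p).r_Wei, abs=1e-12)

    def test_degenerate_block_raises(self, small_bundle):
        p = small_bundle.params
        q = p.copy()
        q.W.Wee[:] = 0.0
        q.W.Wee[np.diag_indices(4)] = 0.0
        with pytest.raises(ValueError):
            masked_correlation(p, q)


class TestSplitHalf:
    def test_identical_halves_give_unit_within(self):
        rng = np.random.default_rng(0)
        fits = {s: (rng.normal(size=(5, 5)),) * 2 for s in "abc"}
        within, across, p = split_half_reliability(fits)
        assert np.allclose(within, 1.0)
        assert len(within) == 3

    def test_independent_subjects_have_across_near_zero(self):
        rng = np.random.default_rng(1)
        acrosses = []
        for _ in range(30):
            fits = {s: (rng.normal(size=(8, 8)), rng.normal(size=(8, 8)))
                    for s in range(4)}
            _, across, _ = split_half_reliability(fits)
            acrosses.append(across.mean())
        assert abs(np.mean(acrosses)) < 0.05

    def test_matches_all_pairs_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        halves = {s: [rng.normal(size=16), rng.normal(size=16)]
                  for s in range(3)}
        within, across, _ = split_half_reliability(
            {s: (h[0], h[1]) for s, h in halves.items()})
        w_want = [pearson_oracle(halves[s][0], halves[s][1]) for s in range(3)]
        a_want = [pearson_oracle(halves[s1][h1], halves[s2][h2])
                  for s1, s2 in combinations(range(3), 2)
                  for h1 in (0, 1) for h2 in (0, 1)]
        assert np.allclose(np.sort(within), np.sort(w_want), atol=1e-12)
        assert np.allclose(np.sort(across), np.sort(a_want), atol=1e-12)

    def test_pair_counts_match_combinatorics(self):
        rng = np.random.default_rng(3)
        n_subj = 5
        fits = {s: (rng.normal(size=10), rng.normal(size=10))
                for s in range(n_subj)}
        within, across, _ = split_half_reliability(fits)
        assert len(within) == n_subj
        assert len(across) == 4 * n_subj * (n_subj - 1) // 2

    def test_requires_two_halves(self):
        with pytest.raises(ValueError):
            split_half_reliability({0: (np.ones(4),),
                                    1: (np.ones(4), np.ones(4))})


class TestModulationImpact:
    def test_equal_modulations_give_zero(self, small_bundle):
        p = small_bundle.params
        g = p.gammas[0]
        imp = modulation_impact(p.W, g, g)
        assert not imp.value.any()

    def test_antisymmetry(self, small_bundle):
        p = small_bundle.params
        a, b = p.gammas[0], p.gammas[1]
        fwd = modulation_impact(p.W, a, b)
        back = modulation_impact(p.W, b, a)
        assert np.array_equal(fwd.value, -back.value)

    def test_hand_built_case_matches_elementwise_oracle(self):
        W = np.array([[1.0, -2.0, 0.5],
                      [0.0, 3.0, -1.0],
                      [2.0, 0.25, 4.0]])
        Ga = np.outer([1, 1, 1], [1, 1, 1]).astype(float)
        Gb = np.outer([0.5, 1.0, 2.0], [1.0, 0.5, 1.0])
        imp = modulation_impact(W, Ga, Gb)
        for i in range(3):
            for j in range(3):
                assert imp.value[i, j] == pytest.approx(
                    W[i, j] * (Gb[i, j] - Ga[i, j]), abs=1e-12)

    def test_postsynaptic_aggregation_is_row_mean(self):
        W = np.eye(3)
        imp = modulation_impact(W, np.zeros((3, 3)), np.ones((3, 3)))
        assert np.allclose(imp.postsynaptic(), imp.value.mean(axis=1))


class TestGammaValueSummary:
    def test_all_ones_counts_as_not_greater(self):
        g = ModulationMatrix.ones(1, 6)
        (s,) = gamma_value_summary([g])
        assert s["frac_greater_than_1"] == 0.0
        assert s["frac_in_unit_interval"] == 0.0  # exactly 1 is outside [0,1)

    def test_half_amplitude_all_in_unit_interval(self):
        g = ModulationMatrix(1, np.full(6, np.sqrt(0.5)), np.full(6, np.sqrt(0.5)))
        (s,) = gamma_value_summary([g])
        assert s["frac_in_unit_interval"] == 1.0

    def test_random_rank_one_matches_full_scan(self):
        rng = np.random.default_rng(4)
        g = ModulationMatrix(1, rng.uniform(0.5, 1.5, 7), rng.uniform(0.5, 1.5, 7))
        (s,) = gamma_value_summary([g])
        vals = g.dense().ravel()
        assert s["n_greater_than_1"] == int(sum(1 for v in vals if v > 1))
        assert s["n_in_unit_interval"] == int(sum(1 for v in vals if 0 <= v < 1))
        assert s["median"] == pytest.approx(np.median(vals))

    def test_mask_restricts_scanned_entries(self, small_bundle):
        p = small_bundle.params
        stats = gamma_value_summary(p.gammas, mask_ee=p.W.mask_ee,
                                    mask_ei=p.W.mask_ei, n_exc=p.n_exc)
        n_eff = int(p.W.mask_ee.sum() + p.W.mask_ei.sum())
        assert all(s["n_entries"] == n_eff for s in stats)
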