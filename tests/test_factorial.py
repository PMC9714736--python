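"""Aligned-rank-transform ANOVA, effect sizes, posthocs, rank correlation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from gametherm.factorial import (
    FactorialDataset,
    art_align,
    art_anova,
    bonferroni_pairwise,
    classify_cohens_d,
    cohens_d,
    partial_eta_squared,
    spearman_rho,
)


def balanced_dataset(rng, na=3, nb=3, n_per_cell=3, a_effect=0.0, b_effect=0.0,
                     ab_effect=0.0, noise=1.0):
    rows_y, rows_a, rows_b = [], [], []
    for i in range(na):
        for j in range(nb):
            mu = (a_effect * i + b_effect * j
                  + ab_effect * i * j)
            y = mu + noise * rng.standard_normal(n_per_cell)
            rows_y.extend(y)
            rows_a.extend([i] * n_per_cell)
            rows_b.extend([j] * n_per_cell)
    return FactorialDataset(np.array(rows_y), np.array(rows_a), np.array(rows_b))


class TestAlignment:
    def test_two_by_two_hand_computation(self):
        # single-replicate 2x2 with values 1..4:
        # grand 2.5, row means (1.5, 3.5), column means (2, 3), zero residuals
        data = FactorialDataset(np.array([1.0, 2.0, 3.0, 4.0]),
                                np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]))
        assert np.allclose(art_align(data, "A"), [-1, -1, 1, 1])
        assert np.allclose(art_align(data, "B"), [-0.5, 0.5, -0.5, 0.5])
        assert np.allclose(art_align(data, "AB"), [0, 0, 0, 0])

    def test_aligned_sums_are_zero(self, rng):
        for _ in range(20):
            data = balanced_dataset(rng, a_effect=rng.normal(), b_effect=rng.normal(),
                                    ab_effect=rng.normal())
            for effect in ("A", "B", "AB"):
                assert abs(art_align(data, effect).sum()) < 1e-8

    def test_pure_a_effect_leaves_no_b_signal(self, rng):
        data = balanced_dataset(rng, a_effect=5.0, noise=0.0)
        aligned_b = art_align(data, "B")
        for j in np.unique(data.b):
            assert np.allclose(aligned_b[data.b == j].mean(), 0.0, atol=1e-10)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty cells"):
            FactorialDataset(np.array([1.0, 2.0, 3.0]),
                             np.array([0, 0, 1]), np.array([0, 1, 1]))


class TestArtAnova:
    def test_stripped_effects_near_zero_noiseless(self, rng):
        data = balanced_dataset(rng, a_effect=4.0, b_effect=2.0, noise=0.0)
        res = art_anova(data, posthoc=False)
        for eff in res.effects.values():
            for f in eff.stripped_f.values():
                assert f < 1e-8

    def test_df_structure_matches_balanced_design(self, rng):
        # 3x3 with 3 replicates per cell: dfs (2, 18), (2, 18), (4, 18)
        data = balanced_dataset(rng)
        res = art_anova(data, posthoc=False)
        assert (res.effects["A"].df_num, res.effects["A"].df_den) == (2, 18)
        assert (res.effects["B"].df_num, res.effects["B"].df_den) == (2, 18)
        assert (res.effects["AB"].df_num, res.effects["AB"].df_den) == (4, 18)

    def test_strong_main_effect_detected(self, rng):
        detected = 0
        for k in range(20):
            data = balanced_dataset(np.random.default_rng(k), a_effect=6.0)
            res = art_anova(data, posthoc=False)
            if res.effects["A"].p < 0.001:
                detected += 1
        assert detected >= 19

    def test_single_factor_reduction_equals_oneway_on_ranks(self, rng):
        # one B level: the ART F for A must equal a plain one-way ANOVA on
        # midranks of the raw responses (independent scipy oracle)
        y = rng.standard_normal(15) + np.repeat([0.0, 1.0, 2.0], 5)
        a = np.repeat([0, 1, 2], 5)
        data = FactorialDataset(y, a, np.zeros(15, dtype=int))
        res = art_anova(data, posthoc=False)
        ranks = stats.rankdata(y)
        f_oracle, p_oracle = stats.f_oneway(*(ranks[a == i] for i in range(3)))
        assert res.effects["A"].f == pytest.approx(f_oracle, rel=1e-10)
        assert res.effects["A"].p == pytest.approx(p_oracle, rel=1e-10)
        assert "B" not in res.effects and "AB" not in res.effects

    def test_rank_anova_matches_statsmodels(self, rng):
        # full two-way ANOVA on aligned ranks vs the statsmodels OLS oracle
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        data = balanced_dataset(rng, a_effect=1.0, b_effect=0.5, ab_effect=0.3)
        res = art_anova(data, posthoc=False)
        for effect, term in (("A", "C(a)"), ("B", "C(b)"), ("AB", "C(a):C(b)")):
            aligned = art_align(data, effect)
            ranked = stats.rankdata(aligned)
            df = pd.DataFrame({"y": ranked, "a": data.a, "b": data.b})
            fit = ols("y ~ C(a) * C(b)", df).fit()
            table = sm.stats.anova_lm(fit, typ=2)
            assert res.effects[effect].f == pytest.approx(
                float(table.loc[term, "F"]), rel=1e-9)

    def test_unbalanced_rejected(self, rng):
        y = rng.standard_normal(10)
        a = np.array([0] * 6 + [1] * 4)
        b = np.array([0, 1] * 5)
        data = FactorialDataset(y, a, b)
        with pytest.raises(ValueError, match="balanced"):
            art_anova(data)

    def test_interaction_type_one_error_nominal(self):
        # fully null 3x3 design: interaction rejections at alpha = .05 should
        # sit inside [0.03, 0.07] over many seeds
        alpha, n_sims = 0.05, 600
        rejections = 0
        for k in range(n_sims):
            data = balanced_dataset(np.random.default_rng(10_000 + k))
            res = art_anova(data, posthoc=False)
            if res.effects["AB"].p < alpha:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07


class TestEffectSizes:
    def test_partial_eta_squared_arithmetic(self):
        assert partial_eta_squared(3.0, 9.0) == 0.25
        assert partial_eta_squared(0.0, 9.0) == 0.0
        assert partial_eta_squared(3.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            partial_eta_squared(0.0, 0.0)

    def test_cohens_d_hand_computation(self):
        # {1,2,3} vs {3,4,5}: pooled SD 1, |d| = 2
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)
        assert cohens_d([3, 4, 5], [1, 2, 3]) == pytest.approx(2.0)

    def test_cohens_d_identical_groups_zero(self):
        assert cohens_d([1, 2, 3, 4], [4, 3, 2, 1]) == 0.0

    def test_cohens_d_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1, 1, 1], [2, 2, 2])

    def test_magnitude_labels(self):
        assert classify_cohens_d(0.1) == "very small"
        assert classify_cohens_d(0.6) == "medium"
        assert classify_cohens_d(1.812) == "very large"
        assert classify_cohens_d(2.592) == "huge"


class TestPosthoc:
    def test_three_levels_three_contrasts(self, rng):
        data = balanced_dataset(rng, a_effect=2.0)
        contrasts = bonferroni_pairwise(data, "A")
        assert len(contrasts) == 3
        for c in contrasts:
            assert c.p_adjusted >= c.p_raw
            assert c.p_adjusted == min(1.0, 3 * c.p_raw)

    def test_familywise_error_controlled_under_null(self):
        alpha, n_sims = 0.05, 400
        any_reject = 0
        for k in range(n_sims):
            data = balanced_dataset(np.random.default_rng(50_000 + k))
            if any(c.p_adjusted < alpha for c in bonferroni_pairwise(data, "A")):
                any_reject += 1
        rate = any_reject / n_sims
        # Bonferroni is conservative; allow Monte-Carlo slack above alpha
        assert rate <= alpha + 2.5 * math.sqrt(alpha * (1 - alpha) / n_sims)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 5, 30).astype(float)  # heavy ties
        y = x + rng.normal(0, 1.5, 30)
        rho, p = spearman_rho(x, y)
        oracle = stats.spearmanr(x, y)
        assert rho == pytest.approx(oracle.statistic, rel=1e-12)
        assert p == pytest.approx(oracle.pvalue, rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])
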