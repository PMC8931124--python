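"""Contingency tests, effect sizes, rank tests, power, reconstruction.

Independent oracles here: Fisher p by direct factorial enumeration of
all tables with fixed margins; Mann-Whitney p by itertools enumeration
of group assignments; scipy / statsmodels reference routines as
cross-checks of the asymptotic variants.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cancelnudge import (
    ContingencyTable2x2,
    PowerSpec,
    cohen_d_from_samples,
    cohen_d_pooled,
    fisher_exact_2x2,
    mann_whitney,
    ols_moderation,
    pearson_chi2,
    reconstruct_counts,
    required_n,
    required_n_chi2_df1,
    required_n_two_sample_t,
    weighted_mean_age,
    wilson_ci,
)
from cancelnudge.stimuli import experiment4_choice_shares


# ---------------------------------------------------------------- oracles

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p from first principles: enumerate every table
    with the observed margins and sum the point probabilities that do
    not exceed the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d

    def point_prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(c1, r1)
    p_obs = point_prob(a)
    return sum(point_prob(x) for x in range(lo, hi + 1)
               if point_prob(x) <= p_obs * (1 + 1e-9))


def mw_oracle(x, y):
    """Permutation-exact two-sided Mann-Whitney p by enumerating every
    assignment of pooled observations to the first group."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n = len(x), len(pooled)
    ranks = sps.rankdata(pooled)
    mean_u = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    dev = abs(u_obs - mean_u)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        hits += abs(u - mean_u) >= dev - 1e-12
    return hits / total


# ---------------------------------------------------------------- chi2 / w

class TestPearsonChi2:
    def test_reconstructed_field_counts(self):
        res = pearson_chi2(ContingencyTable2x2(56, 16, 39, 36))
        assert round(res.statistic, 2) == 10.68
        assert round(res.w, 2) == 0.27

    def test_independence_gives_zero(self):
        assert pearson_chi2(ContingencyTable2x2(10, 10, 10, 10)).statistic == 0

    def test_perfect_association(self):
        # N(ad-bc)^2 / margins = 40*(400)^2/(20*20*20*20) by hand
        assert pearson_chi2(ContingencyTable2x2(20, 0, 0, 20)).statistic == 40

    def test_uncorrected_matches_scipy_without_yates(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert pearson_chi2(t).statistic == pytest.approx(ref.statistic)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2(ContingencyTable2x2(0, 0, 5, 5))


class TestFisherExact:
    def test_field_experiment_value(self):
        assert round(fisher_exact_2x2(ContingencyTable2x2(56, 16, 39, 36)),
                     3) == 0.002

    def test_balanced_tiny_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_for_all_small_tables(self):
        for a, b, c, d in itertools.product(range(11), repeat=4):
            n = a + b + c + d
            if not 0 < n <= 10:
                continue
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            got = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert got == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_matches_scipy_on_larger_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(1, 60, size=4))
            got = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert got == pytest.approx(ref, rel=1e-8)


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.z == 0.0 and res.p == pytest.approx(1.0)

    def test_complete_separation_u_zero(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]).u == 0.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 11 - n1))
            # integer draws force ties with high probability
            x = rng.integers(0, 6, n1).astype(float)
            y = rng.integers(0, 6, n2).astype(float)
            got = mann_whitney(x, y, method="exact")
            assert got.p == pytest.approx(mw_oracle(x, y), abs=1e-12)

    def test_asymptotic_matches_scipy_tie_correction(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.integers(0, 10, 25).astype(float)
            y = rng.integers(0, 10, 30).astype(float)
            got = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=False)
            assert got.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestCohenD:
    def test_retirement_survey_value(self):
        assert round(cohen_d_pooled(67.02, 2.57, 97, 66.05, 2.67, 97), 2) == 0.37

    def test_gain_experiment_value(self):
        # unequal 40/35 split backs out the printed effect size
        assert round(cohen_d_pooled(56, 41.92, 40, 84.57, 29.34, 35), 2) == -0.78

    def test_equal_means_zero(self):
        assert cohen_d_pooled(5, 1, 10, 5, 2, 10) == 0.0

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohen_d_pooled(5, 0, 10, 6, 0, 10)

    def test_sign_flips_under_group_relabel(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        assert cohen_d_from_samples(x, y) == pytest.approx(
            -cohen_d_from_samples(y, x))


class TestPower:
    def test_one_tailed_chi2_sizing(self):
        assert required_n_chi2_df1(0.27, alpha=0.05, power=0.80, tails=1) == 85

    def test_two_tailed_chi2_sizing(self):
        # noncentral chi-square iteration; the pilot effect size w=.23
        assert required_n_chi2_df1(0.23, alpha=0.05, power=0.80, tails=2) == 149

    def test_noncentral_t_sizing(self):
        assert required_n_two_sample_t(0.60) == 45
        assert required_n_two_sample_t(-0.60) == 45   # magnitude only
        assert required_n_two_sample_t(0.48) == 70    # 140 in total

    def test_matches_statsmodels_solver(self):
        from statsmodels.stats.power import tt_ind_solve_power
        for d in (0.3, 0.48, 0.6, 1.0):
            ref = math.ceil(tt_ind_solve_power(effect_size=d, alpha=0.05,
                                               power=0.80))
            assert required_n_two_sample_t(d) == ref

    def test_monotone_in_effect_size_and_power(self):
        ns = [required_n_two_sample_t(d) for d in (0.2, 0.4, 0.6, 0.8)]
        assert ns == sorted(ns, reverse=True)
        ns = [required_n_chi2_df1(0.3, power=p, tails=1)
              for p in (0.5, 0.8, 0.95)]
        assert ns == sorted(ns)

    def test_dispatch_and_validation(self):
        assert required_n(PowerSpec("chi2_df1", 0.27, 0.05, 1, 0.80)) == 85
        assert required_n(PowerSpec("two_sample_t", 0.6, 0.05, 2, 0.80)) == 45
        with pytest.raises(ValueError):
            PowerSpec("anova", 0.3)
        with pytest.raises(ValueError):
            PowerSpec("chi2_df1", -0.1)
        with pytest.raises(ValueError):
            PowerSpec("chi2_df1", 0.3, alpha_level=1.5)


class TestWeightedMeanAge:
    def test_published_columns(self):
        canc = weighted_mean_age(experiment4_choice_shares("cancellation"))
        base = weighted_mean_age(experiment4_choice_shares("baseline"))
        assert round(canc, 2) == 67.02
        # the narrative reports 66.05 (from unrounded data); the printed
        # integer percentage column itself averages to 66.06
        assert round(base, 2) == 66.06

    def test_point_mass(self):
        assert weighted_mean_age({67: 100.0}) == 67.0

    def test_validation(self):
        with pytest.raises(ValueError):
            weighted_mean_age({})
        with pytest.raises(ValueError):
            weighted_mean_age({62: 40.0, 70: 40.0})


class TestWilsonCI:
    def test_reproduces_published_intervals(self):
        lo, hi = wilson_ci(56, 72)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (66.9, 85.8)
        lo, hi = wilson_ci(39, 75)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (40.9, 62.9)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        for x, n in [(5, 20), (19, 20), (50, 103)]:
            ref = proportion_confint(x, n, method="wilson")
            got = wilson_ci(x, n)
            assert got == pytest.approx(ref, abs=1e-12)


class TestReconstructCounts:
    def test_field_experiment_percentages_alone_are_ambiguous(self):
        res = reconstruct_counts(77.8, 52.0, 147)
        assert not res.unique
        assert len(res.tables) == 2
        assert ContingencyTable2x2(56, 16, 39, 36) in res.tables

    def test_printed_cis_identify_the_table(self):
        res = reconstruct_counts(
            77.8, 52.0, 147,
            printed_cis=((66.9, 85.8), (40.9, 62.9)))
        assert res.unique
        assert res.table == ContingencyTable2x2(56, 16, 39, 36)

    def test_small_ambiguous_split(self):
        # N=8 admits 50/50 under three different group splits
        res = reconstruct_counts(50.0, 50.0, 8)
        assert not res.unique
        with pytest.raises(ValueError):
            _ = res.table
        # N=4 leaves only the balanced split, hence a unique table
        assert reconstruct_counts(50.0, 50.0, 4).unique

    def test_degenerate_percentages_non_unique(self):
        res = reconstruct_counts(100.0, 0.0, 10)
        assert not res.unique

    def test_inconsistent_percentages_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_counts(33.3, 77.8, 3)


class TestOlsModeration:
    def _table(self, n, seed, interaction=0.0):
        rng = np.random.default_rng(seed)
        cond = rng.integers(0, 2, n).astype(float)
        age = rng.uniform(20, 60, n)
        income = rng.integers(1, 11, n).astype(float)
        y = 65 + 1.2 * cond + interaction * cond * age + rng.normal(0, 1.5, n)
        return pd.DataFrame({"chosen_age": y, "cancellation": cond,
                             "age": age, "income": income})

    def test_matches_normal_equations_on_worked_table(self):
        df = self._table(8, seed=10)
        fit = ols_moderation(df)
        X = np.column_stack([
            np.ones(8), df.cancellation, df.age, df.cancellation * df.age,
            df.income, df.cancellation * df.income,
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ df.chosen_age.to_numpy())
        got = fit.params[["Intercept", "cancellation", "age",
                          "age:cancellation", "income",
                          "income:cancellation"]].to_numpy()
        assert np.allclose(got, beta, rtol=1e-8)

    def test_no_true_moderation_recovered(self):
        df = self._table(400, seed=11, interaction=0.0)
        fit = ols_moderation(df)
        for term in ("age:cancellation", "income:cancellation"):
            assert abs(fit.params[term]) < 3 * fit.bse[term]
        assert fit.params["cancellation"] > 0

    def test_constant_outcome_zero_slopes(self):
        df = self._table(50, seed=12)
        df["chosen_age"] = 66.0
        fit = ols_moderation(df)
        slopes = fit.params.drop("Intercept")
        assert np.allclose(slopes, 0.0, atol=1e-8)

    def test_missing_column_rejected(self):
        df = self._table(20, seed=13).drop(columns=["income"])
        with pytest.raises(ValueError):
            ols_moderation(df)
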