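"""Statistical battery: exact oracles, recovery simulations, report shapes."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glymphalps import (CohortSpec, ConfigurationError, RegressionError,
                        bonferroni_flags, mann_whitney,
                        monte_carlo_p_interval, ols_with_interaction,
                        run_confounder_adjustment, run_correlation_battery,
                        run_group_comparisons, run_posthoc_regressions,
                        simulate_cohort, spearman_ci)


def exact_mannwhitney_p(a, b):
    """Independent oracle: two-sided p by full enumeration of group
    assignments of the pooled (tie-free) sample."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    mu = n1 * (len(b)) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(2, 3), (3, 3), (4, 4), (5, 5)]:
            for _ in range(5):
                a = rng.normal(size=n1)
                b = rng.normal(1.0, size=n2)
                res = mann_whitney(a, b)
                assert res.method == "exact"
                assert res.p_value == pytest.approx(exact_mannwhitney_p(a, b),
                                                    abs=1e-12)

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2, 3], [1.0, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_swap_symmetry(self):
        a, b = [1.2, 3.4, 2.2, 9.0], [0.5, 4.4, 7.7]
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r2.u_statistic == pytest.approx(
            r1.n_a * r1.n_b - r1.u_statistic)

    def test_degenerate_constant_data(self):
        res = mann_whitney([5.0] * 4, [5.0] * 6)
        assert res.p_value == 1.0
        assert res.method == "degenerate"

    def test_approximate_close_to_exact_n6(self):
        """Normal approximation vs exact enumeration, all tie-free shapes
        with n1=n2=6 (exhaustive over rank assignments)."""
        ranks = np.arange(1, 13, dtype=float)
        worst = 0.0
        for comb in itertools.combinations(range(12), 6):
            a = ranks[list(comb)]
            b = np.delete(ranks, list(comb))
            exact = sps.mannwhitneyu(a, b, method="exact").pvalue
            approx = sps.mannwhitneyu(a, b, method="asymptotic",
                                      use_continuity=True).pvalue
            worst = max(worst, abs(min(approx, 1.0) - exact))
        assert worst < 0.03


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman_ci([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.rho == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_hand_computed_rank_formula(self):
        # ranks x=(1,2,3,4), y=(2,1,4,3): sum d^2 = 4
        # rho = 1 - 6*4 / (4*15) = 0.6
        res = spearman_ci([10, 20, 30, 40], [5, 1, 50, 40])
        assert res.rho == pytest.approx(1 - 6 * 4 / (4 * 15))

    def test_perfect_antitone_large_n(self):
        x = np.random.default_rng(1).normal(size=100)
        res = spearman_ci(x, -x)
        assert res.rho == pytest.approx(-1.0)
        assert res.ci_low == pytest.approx(-1.0)

    def test_fisher_ci_contains_rho(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = spearman_ci(x, y)
        assert res.ci_low < res.rho < res.ci_high

    def test_zero_variance_flagged(self):
        res = spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.undefined

    def test_pairwise_deletion(self):
        x = [1, 2, 3, 4, np.nan]
        y = [2, 4, 6, 8, 1]
        res = spearman_ci(x, y)
        assert res.n == 4
        assert res.rho == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ConfigurationError):
            spearman_ci([1, 2, 3], [3, 1, 2])


class TestBonferroni:
    def test_family_of_14(self):
        assert bonferroni_flags([0.001, 0.01, 0.04], m=14) == \
            [True, False, False]

    def test_identity_family(self):
        assert bonferroni_flags([0.04, 0.06], m=1) == [True, False]

    def test_all_one(self):
        assert bonferroni_flags([1.0] * 5, m=5) == [False] * 5

    def test_invalid_family_size(self):
        with pytest.raises(ConfigurationError):
            bonferroni_flags([0.01], m=0)


class TestMonteCarloP:
    @staticmethod
    def _mean_diff(a, b):
        return a.mean() - b.mean()

    def test_degenerate_statistic(self):
        p, (lo, hi) = monte_carlo_p_interval(lambda a, b: 0.0,
                                             [1, 2, 3], [4, 5, 6],
                                             n_permutations=200, seed=0)
        assert p == 1.0
        assert hi == 1.0

    def test_separated_groups_small_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)  # 5-sd shift
        p, _ = monte_carlo_p_interval(self._mean_diff, a, b,
                                      n_permutations=10000, seed=1)
        assert p <= 0.001

    def test_seeded_determinism(self):
        a, b = [1.0, 2, 3, 7], [2.0, 4, 8, 9]
        r1 = monte_carlo_p_interval(self._mean_diff, a, b, 500, seed=5)
        r2 = monte_carlo_p_interval(self._mean_diff, a, b, 500, seed=5)
        assert r1 == r2

    def test_interval_brackets_p(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 20)
        p, (lo, hi) = monte_carlo_p_interval(self._mean_diff, a, b, 2000,
                                             seed=6)
        assert lo <= p <= hi


class TestRegression:
    def test_perfect_fit_single_term(self):
        df = pd.DataFrame({"x": np.arange(10, dtype=float)})
        df["y"] = 2.0 * df["x"]
        df["group"] = "PD"
        tab = ols_with_interaction(df, dependent="y", terms=("x",),
                                   interaction=None)
        row = tab.coefficient("x")
        assert row["B"] == pytest.approx(2.0)
        assert row["Beta"] == pytest.approx(1.0)
        assert row["SE"] == pytest.approx(0.0, abs=1e-10)

    def test_t_equals_b_over_se(self):
        df = simulate_cohort(CohortSpec(seed=0))
        tab = ols_with_interaction(df)
        for row in tab.rows:
            if row["SE"] > 0:
                assert row["t"] == pytest.approx(row["B"] / row["SE"],
                                                 abs=1e-9)

    def test_single_group_interaction_singular(self):
        df = simulate_cohort(CohortSpec(seed=1))
        df = df[df.group == "PD"]
        with pytest.raises(RegressionError):
            ols_with_interaction(df)

    def test_interaction_recovery_monte_carlo(self):
        """Planted patient-only AHI slope of -0.004 is recovered by the
        interaction coefficient: negative sign in >= 95% of seeds, mean
        within +-30% of truth."""
        coefs = []
        for seed in range(200):
            df = simulate_cohort(CohortSpec(seed=seed))
            coefs.append(ols_with_interaction(df)
                         .coefficient("ahi_x_group")["B"])
        coefs = np.array(coefs)
        assert (coefs < 0).mean() >= 0.95
        assert abs(coefs.mean() - (-0.004)) < 0.3 * 0.004

    def test_posthoc_group_pattern(self):
        """AHI term significant in the patient subset but not in controls
        for the majority of seeds (the planted per-group pattern)."""
        pd_sig, ctrl_sig = 0, 0
        n_rep = 60
        for seed in range(n_rep):
            tabs = run_posthoc_regressions(simulate_cohort(CohortSpec(seed=seed)))
            pd_sig += tabs["PD"].coefficient("ahi")["p"] < 0.05
            ctrl_sig += tabs["control"].coefficient("ahi")["p"] < 0.05
        assert pd_sig > n_rep / 2
        assert ctrl_sig < n_rep / 2

    def test_insufficient_n_rejected(self):
        df = simulate_cohort(CohortSpec(seed=2)).head(6)
        with pytest.raises(RegressionError):
            run_posthoc_regressions(df[df.group == "PD"])


class TestConfounderAdjustment:
    def test_inert_flags_match_simple_regression(self):
        df = simulate_cohort(CohortSpec(seed=3))
        df.loc[:, ["rbd", "rls", "plms"]] = 0
        adj = run_confounder_adjustment(df)
        simple = run_confounder_adjustment(df, confounders=())
        assert set(adj.dropped_terms) == {"rbd", "rls", "plms"}
        assert adj.coefficient("ahi")["B"] == pytest.approx(
            simple.coefficient("ahi")["B"], abs=1e-9)

    def test_planted_confounding_attenuates(self):
        """If RBD both lowers ALPS and raises AHI, adjusting for RBD must
        attenuate the apparent AHI effect (Monte-Carlo over seeds)."""
        diffs = []
        for seed in range(40):
            spec = CohortSpec(beta_ahi_pd=0.0, beta_rbd=-0.15,
                              rbd_ahi_shift=20.0, rbd_prevalence=0.4,
                              seed=seed)
            df = simulate_cohort(spec)
            unadj = run_confounder_adjustment(df, confounders=())
            adj = run_confounder_adjustment(df, confounders=("rbd",))
            diffs.append(abs(unadj.coefficient("ahi")["B"])
                         - abs(adj.coefficient("ahi")["B"]))
        assert np.mean(diffs) > 0


class TestBatteries:
    def test_group_comparison_report_shape(self):
        df = simulate_cohort(CohortSpec(seed=4))
        results = run_group_comparisons(df)
        names = [r.variable for r in results]
        assert "alps" in names and "ahi" in names and "sex" in names
        sex = results[-1]
        assert sex.method == "exact-2x2"
        for r in results[:-1]:
            assert 0 <= r.p_value <= 1
            assert 0 <= r.u_statistic <= r.n_a * r.n_b

    def test_sex_exact_test_matches_hypergeometric_oracle(self):
        """The printed 17/37 vs 10/22 split: compare against a direct
        enumeration of the conditional 2x2 distribution."""
        tab = np.array([[17, 37], [10, 22]])
        _, p = sps.fisher_exact(tab)
        # oracle: sum hypergeometric pmf over tables as or less likely
        n1, n2 = tab.sum(axis=1)
        k = tab[:, 0].sum()
        probs = [sps.hypergeom.pmf(x, n1 + n2, k, n1)
                 for x in range(max(0, k - n2), min(k, n1) + 1)]
        obs = sps.hypergeom.pmf(tab[0, 0], n1 + n2, k, n1)
        oracle = sum(pr for pr in probs if pr <= obs + 1e-12)
        assert p == pytest.approx(oracle, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_extreme_shift_flagged(self):
        df = simulate_cohort(CohortSpec(seed=5))
        df.loc[df.group == "PD", "alps"] += 10 * df["alps"].std()
        results = run_group_comparisons(df)
        alps = next(r for r in results if r.variable == "alps")
        assert alps.bonferroni_significant

    def test_correlation_battery_shape_and_planted_sign(self):
        df = simulate_cohort(CohortSpec(seed=6))
        results = run_correlation_battery(df, m=14)
        pd_res = [r for r in results if r.group == "PD"]
        ctrl_res = [r for r in results if r.group == "control"]
        assert len(pd_res) == len(ctrl_res) == 14
        ahi = next(r for r in pd_res if r.variable == "ahi")
        assert ahi.rho < 0

    def test_constant_target_all_undefined(self):
        df = simulate_cohort(CohortSpec(seed=7))
        df["alps"] = 1.0
        results = run_correlation_battery(df, m=14)
        assert all(r.undefined for r in results)

    def test_single_group_no_split(self):
        df = simulate_cohort(CohortSpec(seed=8))
        df = df[df.group == "PD"]
        results = run_correlation_battery(df, per_group=False, m=14)
        assert len(results) == 14
        assert all(r.group is None for r in results)

    def test_null_cohort_familywise_error_controlled(self):
        """Fully null cohort: Bonferroni (m=14) familywise error within the
        binomial 99% band around <= 5% over 300 quick replicates."""
        hits = 0
        n_rep = 300
        for seed in range(n_rep):
            df = simulate_cohort(CohortSpec(beta_ahi_pd=0, beta_age=0,
                                            beta_sex=0, seed=20_000 + seed))
            res = run_correlation_battery(df, m=14)
            hits += any(r.bonferroni_significant for r in res
                        if r.group == "PD")
        # 99% binomial upper band around 0.05 at n=300
        assert hits / n_rep <= 0.05 + 2.58 * math.sqrt(0.05 * 0.95 / n_rep)
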