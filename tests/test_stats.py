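import itertools
import math

import numpy as np
import pytest
from scipy import stats as st

from svoconform.stats import (
    holm,
    jzs_bayes_factor,
    jzs_bayes_factor_from_t,
    kruskal_with_posthoc,
    norm_rating_battery,
    rank_sum,
    required_sample_size,
    robust_linreg,
    spearman_assoc,
    wilcoxon_signed,
)


class TestHolm:
    def test_known_adjustment(self):
        p = [0.01, 0.04, 0.03, 0.005]
        adj = holm(p)
        # step-down: sorted p x (m - rank), cumulative max, capped at 1
        assert adj[3] == pytest.approx(0.02)
        assert adj[0] == pytest.approx(0.03)
        assert np.all(adj >= p)

    def test_monotone_in_input(self):
        p = np.linspace(0.001, 0.5, 8)
        adj = holm(p)
        assert np.all(np.diff(adj) >= 0)


class TestWilcoxonSigned:
    def test_exact_matches_enumeration(self, rng):
        """For n <= 10 the exact p equals brute force over all 2^n sign
        assignments."""
        for _ in range(5):
            n = int(rng.integers(6, 11))
            v = rng.normal(0.4, 1.0, n)
            while len(np.unique(np.abs(v))) < n:
                v = rng.normal(0.4, 1.0, n)
            res = wilcoxon_signed(v, 0.0, "greater", seed=1)
            ranks = st.rankdata(np.abs(v))
            count = sum(
                sum(r for s, r in zip(signs, ranks) if s) >= res.statistic
                for signs in itertools.product([0, 1], repeat=n))
            assert res.p_value == pytest.approx(count / 2 ** n, abs=1e-12)

    def test_all_positive_one_tailed(self, rng):
        v = np.abs(rng.normal(2, 0.5, 8)) + 0.1
        res = wilcoxon_signed(v, 0.0, "greater", seed=1)
        assert res.p_value == pytest.approx(1 / 2 ** 8)
        assert res.effect_size == pytest.approx(1.0)
        assert res.extras["log_V"] == pytest.approx(math.log(36.0))

    def test_symmetric_pairs_two_tailed(self):
        v = np.array([-3.0, 3.0, -1.5, 1.5, -0.7, 0.7])
        res = wilcoxon_signed(v, 0.0, "two-sided", seed=0)
        assert res.p_value == pytest.approx(1.0)
        assert abs(res.effect_size) < 1e-12

    def test_tail_relation_on_symmetric_null(self, rng):
        v = rng.normal(0, 1, 30)
        two = wilcoxon_signed(v, 0.0, "two-sided", seed=0).p_value
        lo = wilcoxon_signed(v, 0.0, "less", seed=0).p_value
        hi = wilcoxon_signed(v, 0.0, "greater", seed=0).p_value
        assert two == pytest.approx(2 * min(lo, hi), rel=0.05)

    def test_ci_brackets_estimate(self, rng):
        v = rng.normal(0.5, 1.0, 40)
        res = wilcoxon_signed(v, 0.0, "two-sided", seed=3)
        assert res.ci_low <= res.effect_size <= res.ci_high

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            wilcoxon_signed([1.0, 2.0, 3.0])


class TestKruskal:
    def test_hand_ranked_statistic(self):
        groups = [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0],
                  [9.0, 10.0, 11.0, 12.0]]
        res, _ = kruskal_with_posthoc(groups, seed=0)
        # textbook formula, no ties: H = 12/(N(N+1)) * sum n_i Rbar_i^2 - 3(N+1)
        n = 12
        rbar = [2.5, 6.5, 10.5]
        h = 12.0 / (n * (n + 1)) * sum(4 * r ** 2 for r in rbar) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h)
        assert res.effect_size == pytest.approx(h / (n - 1))

    def test_rank_invariance_under_label_permutation(self, rng):
        vals = rng.normal(0, 1, 30)
        g = [vals[:10], vals[10:20], vals[20:]]
        res1, _ = kruskal_with_posthoc(g, seed=0)
        perm = [g[2], g[0], g[1]]
        res2, _ = kruskal_with_posthoc(perm, seed=0)
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_large_shift_detected(self, rng):
        g = [rng.normal(0, 1, 30), rng.normal(0, 1, 30),
             rng.normal(100, 1, 30)]
        res, posthoc = kruskal_with_posthoc(g, seed=0)
        assert res.p_value < 0.001
        shifted = posthoc[(posthoc.group_j == 2) | (posthoc.group_i == 2)]
        assert (shifted.p_corrected < 0.01).all()

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            kruskal_with_posthoc([[1.0, 2.0], [3.0, 4.0]])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_assoc(x, x ** 3).statistic == pytest.approx(1.0)
        assert spearman_assoc(x, -x).statistic == pytest.approx(-1.0)

    def test_ties_match_average_rank_computation(self, rng):
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 4, 30).astype(float)
        res = spearman_assoc(x, y, seed=0)
        manual = st.pearsonr(st.rankdata(x), st.rankdata(y)).statistic
        assert res.statistic == pytest.approx(manual)

    def test_ci_coverage(self, rng):
        """Bootstrap CI covers the population Spearman rho in >= 90% of
        simulations (bivariate normal, n = 60)."""
        r = 0.5
        true_rho = 6 / math.pi * math.asin(r / 2)
        cov = [[1, r], [r, 1]]
        hits = 0
        sims = 500
        for i in range(sims):
            xy = rng.multivariate_normal([0, 0], cov, size=60)
            res = spearman_assoc(xy[:, 0], xy[:, 1], seed=i)
            hits += res.ci_low <= true_rho <= res.ci_high
        assert hits / sims >= 0.90


class TestRobustRegression:
    def test_exact_linear_recovery(self, rng):
        x = rng.normal(0, 1, 50)
        X = np.column_stack([np.ones(50), x])
        y = 2.0 + 3.0 * x
        out = robust_linreg(y, X)
        assert out["coefficients"]["coef"].to_numpy() == pytest.approx(
            [2.0, 3.0], abs=1e-8)

    def test_outlier_resistance_vs_ols(self, rng):
        x = rng.normal(0, 1, 50)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, 50)
        y_c = y.copy()
        y_c[0] += 200.0  # one gross outlier
        X = np.column_stack([np.ones(50), x])
        robust_slope = robust_linreg(y_c, X)["coefficients"]["coef"].iloc[1]
        ols_slope = np.linalg.lstsq(X, y_c, rcond=None)[0][1]
        clean_slope = np.linalg.lstsq(X, y, rcond=None)[0][1]
        assert abs(robust_slope - clean_slope) < abs(ols_slope - clean_slope)

    def test_matches_ols_when_no_residual_exceeds_huber_bound(self, rng):
        x = rng.normal(0, 1, 200)
        # residuals clipped inside the Huber threshold: all weights stay 1
        noise = np.clip(rng.normal(0, 1, 200), -1, 1) * 0.05
        y = 1.0 + 0.5 * x + noise
        X = np.column_stack([np.ones(200), x])
        robust = robust_linreg(y, X)["coefficients"]["coef"].to_numpy()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert robust == pytest.approx(ols, abs=1e-6)

    def test_nested_deviance_test_detects_signal(self, rng):
        x = rng.normal(0, 1, 80)
        z = rng.normal(0, 1, 80)
        y = 1.0 + 2.0 * z + rng.normal(0, 1, 80)
        X_full = np.column_stack([np.ones(80), x, z])
        X_red = np.column_stack([np.ones(80), x])
        out = robust_linreg(y, X_full, X_red)
        assert out["deviance_test"]["df"] == 1
        assert out["deviance_test"]["p"] < 0.001

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(0, 1, 30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(ValueError):
            robust_linreg(rng.normal(0, 1, 30), X)


class TestJzsBayesFactor:
    def test_null_t_favours_null(self):
        assert jzs_bayes_factor_from_t(0.0, 30) < 1.0

    def test_matches_trapezoid_oracle(self, rng):
        for _ in range(20):
            t = float(rng.uniform(-4, 4))
            n = int(rng.integers(8, 80))
            r = float(rng.uniform(0.4, 2.0))
            bf = jzs_bayes_factor_from_t(t, n, None, r, "two-sided")
            delta = np.linspace(-80, 80, 200_001)
            num = np.trapezoid(
                st.nct.pdf(t, n - 1, delta * math.sqrt(n))
                * st.cauchy.pdf(delta, 0, r), delta)
            oracle = num / st.t.pdf(t, n - 1)
            assert abs(bf - oracle) / oracle < 1e-4

    def test_cross_check_against_pingouin(self):
        import pingouin as pg

        for t, n, r in [(2.3, 40, math.sqrt(2) / 2), (0.5, 15, 1.0),
                        (3.5, 25, 2.0)]:
            ours = jzs_bayes_factor_from_t(t, n, None, r)
            theirs = float(pg.bayesfactor_ttest(t, n, r=r))
            assert ours == pytest.approx(theirs, rel=1e-6)

    def test_monotone_in_t(self):
        ts = np.linspace(0, 5, 11)
        bfs = [jzs_bayes_factor_from_t(t, 40) for t in ts]
        assert np.all(np.diff(bfs) > 0)

    def test_directional_splits_two_sided(self):
        t, n = 1.7, 35
        two = jzs_bayes_factor_from_t(t, n, alternative="two-sided")
        gt = jzs_bayes_factor_from_t(t, n, alternative="greater")
        lt = jzs_bayes_factor_from_t(t, n, alternative="less")
        assert (gt + lt) / 2 == pytest.approx(two, rel=1e-6)
        assert gt > two > lt

    def test_two_sample_interface(self, rng):
        x = rng.normal(1.0, 1, 30)
        y = rng.normal(0.0, 1, 30)
        assert jzs_bayes_factor(x, y) > 1.0


class TestPowerAnalysis:
    def test_study_sample_size(self):
        assert required_sample_size(0.35, 0.05, 0.95, "one-sample", 1) == 90

    def test_floor_for_huge_effects(self):
        assert required_sample_size(50.0, 0.05, 0.95, "one-sample", 1) == 2
        assert required_sample_size(5.0, 0.05, 0.95, "one-sample", 1) <= 3

    def test_two_sample_matches_normal_approximation(self):
        n = required_sample_size(0.35, 0.05, 0.95, "two-sample", 2)
        za, zb = st.norm.ppf(0.975), st.norm.ppf(0.95)
        approx = 2 * ((za + zb) / 0.35) ** 2
        assert abs(n - approx) <= 2

    def test_achieved_power_brackets_target(self):
        from svoconform.stats import _achieved_power
        n = required_sample_size(0.35, 0.05, 0.95, "one-sample", 1)
        assert _achieved_power(n, 0.35, 0.05, "one-sample", 1) >= 0.95
        assert _achieved_power(n - 1, 0.35, 0.05, "one-sample", 1) < 0.95

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_sample_size(-1.0)
        with pytest.raises(ValueError):
            required_sample_size(0.3, alpha=1.2)


class TestRankSum:
    def test_separated_groups(self, rng):
        res = rank_sum(rng.normal(5, 1, 20), rng.normal(0, 1, 20),
                       alternative="greater", seed=0)
        assert res.p_value < 1e-6
        assert res.effect_size == pytest.approx(-1.0)


class TestNormRatingBattery:
    def test_identical_groups_all_null(self, rng):
        ratings = rng.integers(1, 5, size=(20, 6)).astype(float)
        table, summary = norm_rating_battery(
            {"a": ratings, "b": ratings.copy()}, seed=0)
        assert (table["p_corrected"] == 1.0).all()
        assert summary["n_significant_corrected"] == 0

    def test_zero_noise_construction_all_significant(self, design):
        from svoconform.synth import simulate_norm_ratings
        probes = design.norm_probes
        pro = np.stack([simulate_norm_ratings(+1, probes, 0.0, i)
                        for i in range(12)]).astype(float)
        anti = np.stack([simulate_norm_ratings(-1, probes, 0.0, i)
                         for i in range(12)]).astype(float)
        keep = [j for j in range(pro.shape[1])
                if len(set(pro[:, j]) | set(anti[:, j])) > 1]
        table, _ = norm_rating_battery(
            {"pro": pro[:, keep], "anti": anti[:, keep]}, seed=0)
        assert (table["p_raw"] < 0.05).all()

    def test_shuffled_labels_nominal_rate(self, rng):
        """Under random group labels the raw significant count stays within
        binomial 99% bounds at alpha = 0.05."""
        n_probes, n_sub, reps = 10, 25, 30
        count = total = 0
        for _ in range(reps):
            pool = rng.integers(1, 5, size=(2 * n_sub, n_probes)).astype(float)
            rng.shuffle(pool)
            table, _ = norm_rating_battery(
                {"a": pool[:n_sub], "b": pool[n_sub:]}, seed=0)
            count += int((table["p_raw"] < 0.05).sum())
            total += n_probes
        lo, hi = st.binom.interval(0.99, total, 0.05)
        assert lo <= count <= hi
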