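"""Inference layer vs brute-force and library oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from padrom import stats as ps


# ------------------------------------------------------------- test oracles


def brute_rm_anova(y):
    """Sums-of-squares decomposition by explicit loops (independent oracle)."""
    n, k = y.shape
    gm = y.sum() / y.size
    ss_cond = sum(n * (y[:, j].sum() / n - gm) ** 2 for j in range(k))
    ss_subj = sum(k * (y[i, :].sum() / k - gm) ** 2 for i in range(n))
    ss_tot = sum((y[i, j] - gm) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    eta = ss_cond / (ss_cond + ss_err)
    return ss_cond, ss_err, f, eta


def brute_wilcoxon_p(diffs):
    """Two-sided exact p by summing over every sign assignment (integer W)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for mask in range(2**n):
        bits = [(mask >> i) & 1 for i in range(n)]
        ws.append(sum(r for r, b in zip(ranks, bits) if b))
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs + 1e-9).mean(), (ws >= w_obs - 1e-9).mean())
    return min(1.0, p)


def brute_spearman_p(x, y):
    rho_obs = sps.spearmanr(x, y).statistic
    count = total = 0
    for perm in itertools.permutations(y):
        r = sps.spearmanr(x, perm).statistic
        count += abs(r) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


# ------------------------------------------------------------- RM-ANOVA


class TestRmAnova:
    def test_matches_brute_force(self, rng):
        for _ in range(10):
            y = rng.normal(50, 10, size=(9, 6))
            res = ps.rm_anova_gg(y)
            ss_cond, ss_err, f, eta = brute_rm_anova(y)
            assert res.ss_effect == pytest.approx(ss_cond, abs=1e-8)
            assert res.ss_error == pytest.approx(ss_err, abs=1e-8)
            assert res.f_stat == pytest.approx(f, abs=1e-8)
            assert res.partial_eta_sq == pytest.approx(eta, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(60, 8, size=(9, 1)) + rng.normal(0, 5, size=(9, 6))
        res = ps.rm_anova_gg(y)
        df = (
            pd.DataFrame(y, columns=list("abcdef"))
            .reset_index()
            .melt("index", var_name="cond")
        )
        aov = pg.rm_anova(
            data=df, dv="value", within="cond", subject="index", correction=True
        ).iloc[0]
        assert res.f_stat == pytest.approx(aov["F"], rel=1e-9)
        assert res.p_value == pytest.approx(aov["p_GG_corr"], rel=1e-9)
        assert res.gg_epsilon == pytest.approx(aov["eps"], rel=1e-6)

    def test_identical_columns_no_effect(self):
        col = np.arange(9.0)
        y = np.tile(col[:, None], (1, 6))
        res = ps.rm_anova_gg(y)
        assert res.f_stat == 0.0 and res.partial_eta_sq == 0.0 and res.p_value == 1.0

    def test_two_conditions_equal_squared_paired_t(self, rng):
        y = rng.normal(30, 5, size=(9, 2))
        res = ps.rm_anova_gg(y)
        t = sps.ttest_rel(y[:, 0], y[:, 1])
        assert res.f_stat == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_uncorrected == pytest.approx(t.pvalue, rel=1e-10)

    def test_epsilon_bounds_and_k2_degenerate(self, rng):
        y = rng.normal(size=(9, 2))
        assert ps.gg_epsilon(y) == 1.0  # k=2: epsilon range collapses to {1}
        for k in (3, 6):
            eps = ps.gg_epsilon(rng.normal(size=(9, k)))
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_eta_invariance_under_affine_units(self, rng):
        y = rng.normal(40, 6, size=(8, 5))
        base = ps.rm_anova_gg(y).partial_eta_sq
        assert ps.rm_anova_gg(y + 17.3).partial_eta_sq == pytest.approx(base, abs=1e-12)
        assert ps.rm_anova_gg(y * 57.2958).partial_eta_sq == pytest.approx(base, abs=1e-12)

    def test_missing_cells_rejected(self):
        y = np.ones((5, 3))
        y[2, 1] = np.nan
        with pytest.raises(ValueError):
            ps.rm_anova_gg(y)
        with pytest.raises(ValueError):
            ps.rm_anova_gg(np.ones((5, 1)))


class TestLsdPosthoc:
    def test_matches_paired_t_oracle(self, rng):
        y = rng.normal(30, 8, size=(9, 6))
        table = ps.lsd_posthoc(y)
        for i, j in itertools.combinations(range(6), 2):
            t = sps.ttest_rel(y[:, i], y[:, j])
            assert table.p.iloc[i, j] == pytest.approx(t.pvalue, rel=1e-12)
            assert table.p.iloc[j, i] == table.p.iloc[i, j]
            assert table.mean_diff.iloc[i, j] == pytest.approx(-table.mean_diff.iloc[j, i])

    def test_identical_pair_p_one(self, rng):
        y = rng.normal(size=(6, 3))
        y[:, 2] = y[:, 0]
        table = ps.lsd_posthoc(y)
        assert table.p.iloc[0, 2] == 1.0 and table.t.iloc[0, 2] == 0.0

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            ps.lsd_posthoc(np.ones((1, 3)))


class TestEffectBands:
    @pytest.mark.parametrize(
        "eta,band",
        [(0.005, "below_small"), (0.01, "small"), (0.05, "small"),
         (0.06, "medium"), (0.13, "medium"), (0.14, "large"), (0.9, "large")],
    )
    def test_eta_bands(self, eta, band):
        assert ps.classify_eta_sq(eta) == band

    def test_eta_out_of_range(self):
        with pytest.raises(ValueError):
            ps.classify_eta_sq(1.2)

    @pytest.mark.parametrize(
        "r,band",
        [(0.05, "negligible"), (0.1, "low"), (0.29, "low"), (0.35, "moderate"),
         (0.5, "high"), (0.975, "high"), (-0.8, "high")],
    )
    def test_correlation_bands(self, r, band):
        assert ps.classify_correlation(r) == band

    def test_correlation_out_of_range(self):
        with pytest.raises(ValueError):
            ps.classify_correlation(1.01)


class TestFriedman:
    def test_identical_columns_null(self):
        scores = np.tile(np.array([3, 4, 2, 5])[:, None], (1, 5))
        stat, p = ps.friedman_test(scores)
        assert stat == 0.0 and p == 1.0

    def test_matches_scipy_without_ties(self, rng):
        y = rng.permuted(np.tile(np.arange(30.0), (9, 1)), axis=1)[:, :5]
        stat, p = ps.friedman_test(y)
        ref = sps.friedmanchisquare(*(y[:, j] for j in range(5)))
        assert stat == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_monotone_rows_achieve_maximal_statistic(self):
        n, k = 3, 3
        monotone = np.tile(np.array([1.0, 2.0, 3.0]), (n, 1))
        stat_mono, _ = ps.friedman_test(monotone)
        best = max(
            ps.friedman_test(np.array(rows))[0]
            for rows in itertools.product(
                list(itertools.permutations([1.0, 2.0, 3.0])), repeat=n
            )
        )
        assert stat_mono == pytest.approx(best, abs=1e-12)

    def test_likert_matrix_matches_manual_ranks(self, rng):
        y = rng.integers(1, 6, size=(9, 5)).astype(float)
        stat, _ = ps.friedman_test(y)
        ranks = np.apply_along_axis(sps.rankdata, 1, y)
        rj = ranks.sum(axis=0)
        ssbn = (rj**2).sum()
        tie = sum(
            (c**3 - c) for row in y for c in np.unique(row, return_counts=True)[1]
        )
        corr = 1 - tie / (9 * (125 - 5))
        expected = (12.0 / (9 * 5 * 6) * ssbn - 3 * 9 * 6) / corr
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(1, 6, size=(9, 5)).astype(float)
        assert ps.friedman_test(y) == ps.friedman_test(np.exp(y))

    def test_missing_cells_rejected(self):
        y = np.ones((4, 3))
        y[0, 0] = np.nan
        with pytest.raises(ValueError):
            ps.friedman_test(y)


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            ps.wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_single_nonzero_difference(self):
        w, p = ps.wilcoxon_signed_rank([1.0, 2.0], [1.0, 5.0])
        assert p == 1.0

    def test_likert_n9_matches_enumeration(self, rng):
        for _ in range(10):
            a = rng.integers(1, 6, size=9).astype(float)
            b = rng.integers(1, 6, size=9).astype(float)
            if np.all(a == b):
                continue
            _, p = ps.wilcoxon_signed_rank(a, b)
            assert p == pytest.approx(brute_wilcoxon_p(a - b), abs=1e-12)

    def test_tie_free_matches_scipy_exact(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        _, p = ps.wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_large_sample_normal_approximation(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(0.5, 1.0, size=40)
        _, p = ps.wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, method="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_affine_invariance(self, rng):
        # signed ranks depend on the ordering of |differences|, which any
        # positive affine rescaling of the score scale preserves
        a = rng.integers(1, 6, size=9).astype(float)
        b = rng.integers(1, 6, size=9).astype(float)
        assert ps.wilcoxon_signed_rank(a, b) == ps.wilcoxon_signed_rank(3 * a + 2, 3 * b + 2)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        rho, p = ps.spearman_corr(x, x**3)
        assert rho == 1.0
        assert p == pytest.approx(2 / 120)  # two of 5! permutations are extreme
        rho_rev, _ = ps.spearman_corr(x, -x)
        assert rho_rev == -1.0

    def test_exact_p_matches_permutation_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            rho, p = ps.spearman_corr(x, y)
            assert rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)
            assert p == pytest.approx(brute_spearman_p(x, y), abs=1e-12)

    def test_symmetry_and_monotone_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert ps.spearman_corr(x, y) == ps.spearman_corr(y, x)
        rho1, _ = ps.spearman_corr(x, y)
        rho2, _ = ps.spearman_corr(np.exp(x), y**3 + 5)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_t_approximation_for_larger_n(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(0, 2, size=30)
        rho, p = ps.spearman_corr(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ps.spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestShapiro:
    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            ps.shapiro_wilk([2.0] * 10)

    def test_normal_samples_rarely_rejected(self):
        hits = 0
        for seed in range(50):
            x = np.random.default_rng(seed).normal(size=200)
            _, p = ps.shapiro_wilk(x)
            hits += p > 0.05
        assert hits >= 45

    def test_symmetric_small_sample_high_w(self):
        w, _ = ps.shapiro_wilk([1, 2, 3, 4, 3, 2, 1])
        assert w > 0.9
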