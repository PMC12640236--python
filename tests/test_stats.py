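import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mucoh.stats import (PairedTestResult, mediation_continuous,
                         normality_gate, paired_tests, rm_anova,
                         robust_regression, wilcoxon_signed_rank,
                         within_mediation)


def exact_wilcoxon_oracle(d):
    """Full 2^n enumeration of the signed-rank null (Pratt zeros)."""
    d = np.asarray(d, float)
    ranks = sps.rankdata(np.abs(d))
    nz = d != 0
    r = ranks[nz]
    obs = float(r[d[nz] > 0].sum())
    w_all = [float(np.dot(bits, r))
             for bits in itertools.product((0.0, 1.0), repeat=len(r))]
    w_all = np.asarray(w_all)
    p_le = np.mean(w_all <= obs + 1e-12)
    p_ge = np.mean(w_all >= obs - 1e-12)
    return obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestNormalityGate:
    def test_normal_sample_selects_t_most_of_the_time(self):
        picks = [normality_gate(np.random.default_rng(i).normal(size=31))
                 for i in range(100)]
        assert picks.count("t") >= 85   # ~95% expected at alpha=0.05

    def test_skewed_sample_selects_wilcoxon(self):
        picks = [normality_gate(np.random.default_rng(i).exponential(size=31))
                 for i in range(50)]
        assert picks.count("wilcoxon") >= 0.8 * 50

    def test_tiny_symmetric_sample_runs(self):
        assert normality_gate(np.array([-1.0, 0.0, 1.0])) in ("t", "wilcoxon")

    def test_constant_differences_warn_and_fall_back(self):
        with pytest.warns(UserWarning, match="constant"):
            assert normality_gate(np.zeros(10)) == "wilcoxon"


class TestPairedTests:
    @pytest.mark.parametrize("seed", range(6))
    def test_exact_wilcoxon_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 13)
        d = np.round(rng.normal(0.4, 1.0, size=n), 1)  # induces ties/zeros
        w, _, p = wilcoxon_signed_rank(d)
        w_o, p_o = exact_wilcoxon_oracle(d)
        assert w == pytest.approx(w_o)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_identical_conditions_wilcoxon_p_one(self):
        a = np.arange(10.0)
        res = paired_tests(a, a, method="wilcoxon")
        assert res.p == 1.0

    def test_identical_conditions_t_rejected(self):
        a = np.arange(10.0)
        with pytest.raises(ValueError, match="zero-variance"):
            paired_tests(a, a, method="t")

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.8, 1, 20)
        b = rng.normal(0, 1, 20)
        res = paired_tests(a, b, n_comparisons=3, method="t")
        assert res.p_corrected == pytest.approx(min(1.0, res.p * 3))
        assert res.p_corrected >= res.p

    def test_cohens_d_definition(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1, 1, 25)
        b = rng.normal(0, 1, 25)
        res = paired_tests(a, b, method="t")
        d = a - b
        assert res.effect_size == pytest.approx(d.mean() / d.std(ddof=1))

    def test_wilcoxon_effect_size_r(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1, 1, 30)
        b = rng.normal(0, 1, 30)
        res = paired_tests(a, b, method="wilcoxon")
        assert res.effect_size == pytest.approx(res.statistic / np.sqrt(30))

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1.0, 40)
        _, z, p = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestRmAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        vals = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0],
                         [0.0, 1.0, 2.0], [1.0, 3.0, 4.0]])
        res = rm_anova(vals)
        gm = vals.mean()
        ss_eff = 4 * ((vals.mean(0) - gm) ** 2).sum()
        ss_subj = 3 * ((vals.mean(1) - gm) ** 2).sum()
        ss_err = ((vals - gm) ** 2).sum() - ss_eff - ss_subj
        f_hand = (ss_eff / 2) / (ss_err / 6)
        assert res.statistic == pytest.approx(f_hand, abs=1e-9)
        assert res.effect_size == pytest.approx(ss_eff / (ss_eff + ss_err),
                                                abs=1e-9)

    def test_identical_columns_f_zero(self):
        col = np.random.default_rng(0).normal(size=6)
        vals = np.column_stack([col, col, col])
        res = rm_anova(vals)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_two_levels_matches_uncorrected_f(self):
        """With 2 levels sphericity holds trivially (epsilon = 1): the p
        value equals the uncorrected F p."""
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(12, 2)) + np.array([0.0, 0.8])
        res = rm_anova(vals)
        p_unc = sps.f.sf(res.statistic, *res.df)
        assert res.p == pytest.approx(p_unc, rel=1e-9)

    def test_gg_correction_does_not_anticonservative(self):
        """When sphericity is violated and the effect is real, the GG-
        corrected p is at least the uncorrected p (epsilon <= 1)."""
        rng = np.random.default_rng(2)
        n = 14
        base = rng.normal(size=(n, 1))
        vals = np.hstack([base, base + 0.2 * rng.normal(size=(n, 1)),
                          4.0 + 3 * rng.normal(size=(n, 1)),
                          0.5 + 5 * rng.normal(size=(n, 1))])
        res = rm_anova(vals)
        p_unc = sps.f.sf(res.statistic, *res.df)
        assert res.p >= p_unc - 1e-12

    def test_missing_cells_rejected(self):
        vals = np.ones((5, 3))
        vals[0, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova(vals)


class TestRobustRegression:
    def test_consistency_on_clean_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        y = 0.5 * x + 0.05 * rng.normal(size=100)
        res = robust_regression(x, y, standardize=False)
        assert abs(res.beta - 0.5) < 0.05

    def test_resists_gross_outliers_better_than_ols(self):
        import statsmodels.api as sm

        dev_r, dev_o = [], []
        for i in range(60):
            rng = np.random.default_rng(i)
            n = 50
            x = rng.normal(size=n)
            y = 0.5 * x + 0.1 * rng.normal(size=n)
            idx = rng.choice(n, 5, replace=False)
            y[idx] += rng.choice([-1.0, 1.0], 5) * 5.0
            b_r = robust_regression(x, y, standardize=False).beta
            b_o = sm.OLS(y, sm.add_constant(x)).fit().params[1]
            dev_r.append(abs(b_r - 0.5))
            dev_o.append(abs(b_o - 0.5))
        assert np.median(dev_r) < np.median(dev_o)

    def test_null_rejection_rate_calibrated(self):
        hits = 0
        n_rep = 400
        for i in range(n_rep):
            rng = np.random.default_rng(i)
            res = robust_regression(rng.normal(size=29), rng.normal(size=29))
            hits += res.p < 0.05
        rate = hits / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 3 * se

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            robust_regression(np.ones(10), np.random.default_rng(0).normal(size=10))


class TestWithinMediation:
    def test_indirect_is_exact_product_of_paths(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(20, 2))
        y = rng.normal(size=(20, 2))
        res = within_mediation(m, y, seed=1)
        assert res.indirect == pytest.approx(res.a_path * res.b_path)

    def test_ci_reproducible_with_seed(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(20, 2))
        y = rng.normal(size=(20, 2))
        r1 = within_mediation(m, y, seed=7)
        r2 = within_mediation(m, y, seed=7)
        assert r1.ci == r2.ci

    def test_null_b_path_ci_covers_zero(self):
        """Mediator unrelated to outcome: CI covers 0 in ~95% of replicates."""
        cover = 0
        n_rep = 150
        for i in range(n_rep):
            rng = np.random.default_rng(i)
            n = 31
            m = np.column_stack([rng.normal(0, 0.3, n),
                                 rng.normal(0.5, 0.3, n)])   # real a path
            y = rng.normal(size=(n, 2))                      # b = 0
            res = within_mediation(m, y, n_mc=2000, seed=i)
            cover += not res.significant
        assert cover / n_rep >= 0.90

    def test_parameter_recovery(self):
        """Planted a=0.5, b=0.5 recovers indirect ~0.25 on average."""
        est = []
        n_rep = 200
        for i in range(n_rep):
            rng = np.random.default_rng(i)
            n = 31
            m0 = rng.normal(0.0, 0.3, n)
            md = rng.normal(0.5, 0.3, n)
            m = np.column_stack([m0, m0 + md])
            yd = 0.5 * md + rng.normal(0, 0.5, n)
            y = np.column_stack([np.zeros(n), yd])
            est.append(within_mediation(m, y, n_mc=500, seed=i).indirect)
        se = np.std(est, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(est) - 0.25) <= 3 * se

    def test_shapes_validated(self):
        with pytest.raises(ValueError):
            within_mediation(np.zeros((10, 3)), np.zeros((10, 3)))
        with pytest.raises(ValueError):
            within_mediation(np.zeros((4, 2)), np.zeros((4, 2)))


class TestMediationContinuous:
    def test_full_mediation_structure_recovered(self):
        rng = np.random.default_rng(3)
        n = 200
        x = rng.normal(size=n)
        m = 0.7 * x + 0.5 * rng.normal(size=n)
        y = 0.7 * m + 0.5 * rng.normal(size=n)
        res = mediation_continuous(x, m, y, seed=0)
        assert res.significant
        assert res.indirect > 0.2
        assert res.total_p < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mediation_continuous(np.ones(10), np.arange(10.0), np.arange(10.0))
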