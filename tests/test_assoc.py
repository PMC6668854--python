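"""Score tests, polygenic fit, genomic control, permutation p, simpleM."""

import numpy as np
import pytest
from scipy import stats

from hipgwas.assoc import (
    empirical_genomewide_p,
    fit_polygenic,
    genomic_control,
    meff_from_correlation,
    mm_score_test,
    significance_thresholds,
    simpleM_meff,
    trend_score_test,
    trend_scan,
)
from hipgwas.io_formats import MISSING


def _counts_to_vectors(case_counts, control_counts):
    g = np.concatenate(
        [np.repeat([0, 1, 2], case_counts), np.repeat([0, 1, 2], control_counts)]
    ).astype(float)
    y = np.concatenate(
        [np.ones(sum(case_counts)), np.zeros(sum(control_counts))]
    )
    return g, y


def _ca_oracle(case_counts, control_counts):
    """Textbook Cochran-Armitage trend formula with scores (0, 1, 2)."""
    t = np.array([0.0, 1.0, 2.0])
    a = np.array(case_counts, float)
    nvec = a + np.array(control_counts, float)
    N, R = nvec.sum(), a.sum()
    return (
        N
        * (N * (t @ a) - R * (t @ nvec)) ** 2
        / (R * (N - R) * (N * (t**2 @ nvec) - (t @ nvec) ** 2))
    )


class TestTrendTest:
    def test_identical_distributions_give_zero(self):
        g, y = _counts_to_vectors([10, 10, 10], [10, 10, 10])
        stat, p = trend_score_test(g, y)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_formula(self):
        g, y = _counts_to_vectors([5, 10, 25], [25, 10, 5])
        stat, _p = trend_score_test(g, y)
        assert stat == pytest.approx(_ca_oracle([5, 10, 25], [25, 10, 5]), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_oracle_and_n_r2(self, seed):
        rng = np.random.default_rng(seed)
        cc = rng.integers(1, 30, 3)
        ct = rng.integers(1, 30, 3)
        g, y = _counts_to_vectors(cc, ct)
        stat, _ = trend_score_test(g, y)
        assert stat == pytest.approx(_ca_oracle(cc, ct), rel=1e-9)
        assert stat == pytest.approx(len(g) * np.corrcoef(g, y)[0, 1] ** 2, rel=1e-9)

    def test_homozygote_only_data_relates_to_allelic_chi_square(self):
        """With genotypes in {0,2} the allelic 2x2 chi-square equals twice the
        trend statistic (every animal contributes two identical alleles)."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            cc = rng.integers(2, 30, 2)
            ct = rng.integers(2, 30, 2)
            g = np.concatenate([np.repeat([0, 2], cc), np.repeat([0, 2], ct)]).astype(float)
            y = np.concatenate([np.ones(cc.sum()), np.zeros(ct.sum())])
            stat, _ = trend_score_test(g, y)
            allelic = np.array(
                [[2 * cc[1], 2 * cc[0]], [2 * ct[1], 2 * ct[0]]]
            )
            chi2 = stats.chi2_contingency(allelic, correction=False)[0]
            assert chi2 == pytest.approx(2 * stat, rel=1e-9)

    def test_monomorphic_flagged_zero(self):
        stat, p = trend_score_test(np.zeros(20), np.repeat([0, 1], 10))
        assert stat == 0.0 and p == 1.0

    def test_missing_genotypes_dropped(self):
        g = np.array([0, 1, 2, MISSING, 2, 0], dtype=float)
        y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        stat, _ = trend_score_test(g, y)
        stat2, _ = trend_score_test(g[[0, 1, 2, 4, 5]], y[[0, 1, 2, 4, 5]])
        assert stat == pytest.approx(stat2)

    def test_single_phenotype_class_raises(self):
        with pytest.raises(ValueError):
            trend_score_test(np.array([0, 1, 2]), np.ones(3))

    def test_scan_agrees_with_single_snp(self):
        rng = np.random.default_rng(4)
        G = rng.integers(0, 3, size=(80, 10)).astype(float)
        y = rng.integers(0, 2, 80).astype(float)
        scan = trend_scan(G, y)
        for j in range(10):
            stat, _ = trend_score_test(G[:, j], y)
            assert scan[j] == pytest.approx(stat, rel=1e-9)


class TestPolygenicFit:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        n = 120
        x = rng.normal(size=(n, 2))
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_polygenic(y, x, np.eye(n))
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        ols_resid = y - X @ beta_ols
        assert np.allclose(fit.environmental_residuals, (1 - fit.h2) * ols_resid, atol=1e-6)
        assert abs(fit.environmental_residuals.mean()) < 1e-6

    def test_h2_recovery(self):
        """True h2 = 0.4 at n = 1000 is recovered within a tolerant band."""
        rng = np.random.default_rng(1)
        estimates = []
        for _ in range(6):
            n, m = 1000, 800
            p = rng.uniform(0.1, 0.9, m)
            G = rng.binomial(1, p, (n, m)) + rng.binomial(1, p, (n, m))
            Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
            K = Z @ Z.T / m
            u = Z @ rng.normal(0, 1, m) / np.sqrt(m)  # polygenic component, var 1
            g = u * np.sqrt(0.4)
            e = rng.normal(0, np.sqrt(0.6), n)
            y = g + e
            fit = fit_polygenic(y, None, K)
            estimates.append(fit.h2)
        assert 0.25 <= np.mean(estimates) <= 0.55

    def test_constant_phenotype_raises(self):
        with pytest.raises(ValueError):
            fit_polygenic(np.ones(10), None, np.eye(10))


class TestMmScore:
    def test_equals_trend_with_identity_kinship(self):
        rng = np.random.default_rng(2)
        n = 100
        G = rng.integers(0, 3, size=(n, 20)).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        fit = fit_polygenic(y, None, np.eye(n))
        t_mm = mm_score_test(G, fit)
        for j in range(20):
            t_tr, _ = trend_score_test(G[:, j], y)
            assert abs(t_mm[j] - t_tr) < 1e-8

    def test_null_distribution_is_chi_square_1df(self):
        rng = np.random.default_rng(3)
        n, m = 300, 2000
        G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        fit = fit_polygenic(y, None, np.eye(n))
        t = mm_score_test(G, fit)
        ks = stats.kstest(t, lambda x: stats.chi2.cdf(x, df=1))
        assert ks.pvalue > 0.01

    def test_orthogonal_genotype_gives_zero(self):
        n = 50
        y = np.repeat([0.0, 1.0], 25)
        fit = fit_polygenic(y, None, np.eye(n))
        g = np.ones(n)  # constant => residualized to 0
        assert mm_score_test(g[:, None], fit)[0] == pytest.approx(0.0, abs=1e-10)


class TestGenomicControl:
    def test_median_at_reference_gives_unit_lambda(self):
        t = np.full(101, stats.chi2.ppf(0.5, 1))
        lam, corrected, _p = genomic_control(t)
        assert lam == pytest.approx(1.0, rel=1e-12)
        assert np.allclose(corrected, t)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        t = stats.chi2.rvs(1, size=500, random_state=rng)
        lam1, c1, _ = genomic_control(t)
        lam2, c2, _ = genomic_control(2 * t)
        assert lam2 == pytest.approx(2 * lam1, rel=1e-12)
        assert np.allclose(c1, c2)

    def test_null_sample_lambda_near_one(self):
        t = stats.chi2.rvs(1, size=10_000, random_state=np.random.default_rng(5))
        lam, _c, _p = genomic_control(t)
        assert 0.95 <= lam <= 1.05

    def test_reverse_gc_inflates_deflated_statistics(self):
        t = stats.chi2.rvs(1, size=2000, random_state=np.random.default_rng(6)) * 0.7
        lam, corrected, _ = genomic_control(t)
        assert lam < 1
        assert corrected.mean() > t.mean()

    def test_all_zero_statistics_error(self):
        with pytest.raises(ValueError):
            genomic_control(np.zeros(10))


class TestEmpiricalP:
    def test_extreme_observed_gets_smallest_p(self):
        rng = np.random.default_rng(7)
        n = 60
        G = rng.integers(0, 3, size=(n, 5)).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        G[:, 0] = y * 2  # perfectly associated
        p, _maxes = empirical_genomewide_p(G, y, n_perm=99, seed=1)
        assert p[0] == pytest.approx(1 / 100)

    def test_exhaustive_matches_brute_force(self):
        import itertools

        rng = np.random.default_rng(8)
        G = rng.integers(0, 3, size=(8, 2)).astype(float)
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        p, maxes = empirical_genomewide_p(G, e, n_perm=1, exhaustive=True)
        Gc = G - G.mean(0)
        ss = (Gc * Gc).sum(0)
        s2 = ((e - e.mean()) ** 2).sum() / 8

        def statf(v):
            vc = v - v.mean()
            return (Gc.T @ vc) ** 2 / (ss * s2)

        mx = []
        for c in itertools.combinations(range(8), 4):
            v = np.zeros(8)
            v[list(c)] = 1
            mx.append(statf(v).max())
        mx = np.array(mx)
        expected = [(mx >= o - 1e-12).mean() for o in statf(e)]
        assert np.allclose(p, expected)

    def test_null_p_close_to_uniform(self):
        rng = np.random.default_rng(9)
        n, m = 100, 200
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        p, _ = empirical_genomewide_p(G, y, n_perm=199, seed=2)
        # under the null the minimum genome-wide p should rarely be extreme
        assert p.min() > 1 / 200
        assert 0.2 < np.median(p)

    def test_monotone_in_observed_statistic(self):
        rng = np.random.default_rng(10)
        n = 80
        G = rng.integers(0, 3, size=(n, 10)).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        p, maxes = empirical_genomewide_p(G, y, n_perm=99, seed=3)
        t = trend_scan(G, y)
        order = np.argsort(t)
        assert np.all(np.diff(p[order]) <= 1e-12)


class TestSimpleM:
    def test_identity_correlation(self):
        assert meff_from_correlation(np.eye(200), 0.995) == 199

    def test_duplicated_pairs(self):
        rng = np.random.default_rng(11)
        base = rng.binomial(2, 0.5, size=(500, 50)).astype(float)
        G = np.repeat(base, 2, axis=1)  # 100 SNPs as 50 duplicated pairs
        est = simpleM_meff(G, window=100)
        assert est.m_eff == 50

    def test_meff_bounded_by_m(self):
        rng = np.random.default_rng(12)
        G = rng.binomial(2, 0.4, size=(100, 60)).astype(float)
        est = simpleM_meff(G, window=25)
        assert 1 <= est.m_eff <= 60

    def test_tiny_window_contributes_snp_count(self):
        rng = np.random.default_rng(13)
        G = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        est = simpleM_meff(G, window=1)
        assert est.m_eff == 3


class TestThresholds:
    def test_printed_bonferroni_values(self):
        bonf, eff = significance_thresholds(0.05, 92315, 24159)
        assert bonf == pytest.approx(5.42e-7, rel=5e-3)
        assert eff == pytest.approx(2.07e-6, rel=5e-3)

    def test_single_test(self):
        bonf, eff = significance_thresholds(0.05, 1, 1)
        assert bonf == 0.05 and eff == 0.05


class TestTypeIError:
    def test_trend_test_holds_nominal_level(self):
        rng = np.random.default_rng(14)
        n, m = 200, 10_000
        G = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        t = trend_scan(G, y)
        rejection = np.mean(t > stats.chi2.ppf(0.95, 1))
        assert 0.04 <= rejection <= 0.06
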