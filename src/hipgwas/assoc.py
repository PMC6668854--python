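"""Genome-wide association statistics.

Two score tests drive the scan:

* :func:`trend_score_test` — the Cochran-Armitage trend test (scores 0/1/2),
  generalized to covariates as the logistic score test of adding the genotype
  term to a null model.  Without covariates the statistic is exactly
  N * corr(g, y)^2.
* :func:`mm_score_test` — a mixed-model score test that accounts for
  relatedness: T = (g' V^-1 r)^2 / (g' V^-1 g) with V = sigma_g^2 K +
  sigma_e^2 I from :func:`fit_polygenic` and r the fixed-effect GLS
  residuals.  With K = I and h2 = 0 this collapses to the trend test.

Genomic control rescales the whole statistic vector by the inflation factor
lambda = median(T) / median(chi^2_1); deflation (lambda < 1) is corrected the
same way ("reverse genomic control"), inflating the statistics back up.
Experiment-wise significance comes from permuting the environmental residuals
(which, unlike the mixed-model statistics, are exchangeable) and recording the
per-permutation maximum statistic; the effective number of independent tests
is estimated from block-wise eigenvalue spectra of the SNP correlation matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


# ---------------------------------------------------------------------------
# Single-SNP trend / score test
# ---------------------------------------------------------------------------


def trend_score_test(
    g: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Cochran-Armitage trend statistic; logistic score test with covariates.

    Missing genotypes are dropped.  A SNP monomorphic among complete cases
    returns statistic 0 (flagged by a p of 1).  Returns ``(statistic, p)``.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (g != MISSING) & np.isfinite(g) & np.isfinite(y)
    g, y = g[ok], y[ok]
    if covariates is not None:
        x = np.column_stack([np.ones(ok.sum()), np.asarray(covariates)[ok]])
    else:
        x = np.ones((ok.sum(), 1))
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has fewer than 2 classes among complete cases")
    if np.ptp(g) == 0:
        return 0.0, 1.0

    # null logistic fit (closed form for intercept-only)
    if x.shape[1] == 1:
        p_hat = np.full(g.size, y.mean())
    else:
        import statsmodels.api as sm

        p_hat = sm.GLM(y, x, family=sm.families.Binomial()).fit().fittedvalues
    w = p_hat * (1 - p_hat)
    u = float(g @ (y - p_hat))
    xtw = x.T * w
    beta_g = np.linalg.solve(xtw @ x, xtw @ g)
    g_res = g - x @ beta_g
    v = float((g_res * w) @ g_res)
    if v <= 0:
        return 0.0, 1.0
    statistic = u * u / v
    return statistic, float(stats.chi2.sf(statistic, df=1))


def trend_scan(G: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
    """Vectorized trend statistics for an n x m genotype matrix.

    Uses the linear-score form on OLS residuals with the ML variance, which
    coincides with the Cochran-Armitage statistic without covariates.
    Missing genotypes are mean-imputed per SNP.
    """
    G = np.asarray(G, dtype=float)
    G = np.where(G == MISSING, np.nan, G)
    col_mean = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(np.nan_to_num(col_mean), inds[1])
    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(x)
    r = y - q @ (q.T @ y)
    Gt = G - q @ (q.T @ G)
    sigma2 = float(r @ r) / n
    num = (Gt.T @ r) ** 2
    den = (Gt * Gt).sum(axis=0) * sigma2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    return t


# ---------------------------------------------------------------------------
# Polygenic (mixed-model) fit
# ---------------------------------------------------------------------------


@dataclass
class PolygenicFit:
    h2: float
    beta: np.ndarray
    sigma2_total: float
    environmental_residuals: np.ndarray
    fixed_effect_residuals: np.ndarray
    #: eigendecomposition of K and design, cached for the score scan
    eigvals: np.ndarray
    eigvecs: np.ndarray
    X: np.ndarray


def fit_polygenic(
    y: np.ndarray, covariates: np.ndarray | None, kinship: np.ndarray
) -> PolygenicFit:
    """Maximum-likelihood variance components for y = Xb + g + e, cov(g) = s_g^2 K.

    A binary phenotype is treated as quantitative 0/1.  The likelihood is
    profiled over h2 = s_g^2 / (s_g^2 + s_e^2) on the eigenbasis of K.
    Environmental residuals e_hat = s_e^2 V^-1 (y - Xb) have mean ~ 0 and are
    exchangeable under the null, making them suitable for permutation.
    Non-PSD kinship is repaired by shifting the spectrum with a warning.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    n = y.size
    X = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    K = np.asarray(kinship, dtype=float)
    vals, vecs = np.linalg.eigh((K + K.T) / 2)
    if vals.min() < -1e-8:
        log.warning("kinship not PSD (min eig %.3g); shifting spectrum", vals.min())
        vals = vals - vals.min()
    vals = np.clip(vals, 0.0, None)

    yt = vecs.T @ y
    Xt = vecs.T @ X

    def negloglik(h2: float) -> float:
        d = h2 * vals + (1 - h2)
        dw = 1.0 / d
        XtDX = (Xt.T * dw) @ Xt
        beta = np.linalg.solve(XtDX, (Xt.T * dw) @ yt)
        res = yt - Xt @ beta
        sigma2 = float((res * res * dw).sum()) / n
        return 0.5 * (n * np.log(2 * np.pi * sigma2) + np.log(d).sum() + n)

    grid = np.linspace(0.0, 0.999, 25)
    h0 = grid[np.argmin([negloglik(h) for h in grid])]
    lo, hi = max(0.0, h0 - 0.05), min(0.999, h0 + 0.05)
    res = optimize.minimize_scalar(negloglik, bounds=(lo, hi), method="bounded")
    h2 = float(res.x)

    d = h2 * vals + (1 - h2)
    dw = 1.0 / d
    XtDX = (Xt.T * dw) @ Xt
    beta = np.linalg.solve(XtDX, (Xt.T * dw) @ yt)
    resid_t = yt - Xt @ beta
    sigma2 = float((resid_t * resid_t * dw).sum()) / n
    r = y - X @ beta
    e_hat = vecs @ ((1 - h2) * dw * resid_t)
    return PolygenicFit(
        h2=h2,
        beta=beta,
        sigma2_total=sigma2,
        environmental_residuals=e_hat,
        fixed_effect_residuals=r,
        eigvals=vals,
        eigvecs=vecs,
        X=X,
    )


def mm_score_test(G: np.ndarray, fit: PolygenicFit) -> np.ndarray:
    """Mixed-model score statistics T = (g' V^-1 r)^2 / (g~' V^-1 g~) per SNP.

    ``g~`` is the genotype residualized against the fixed effects in the
    V^-1 metric; missing genotypes are mean-imputed per SNP.  Reduces to the
    trend statistic when K = I and h2 = 0.
    """
    G = np.asarray(G, dtype=float)
    G = np.where(G == MISSING, np.nan, G)
    col_mean = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(np.nan_to_num(col_mean), inds[1])

    d = fit.h2 * fit.eigvals + (1 - fit.h2)
    d = np.maximum(d, 1e-12)
    dw = 1.0 / (d * fit.sigma2_total)
    U = fit.eigvecs
    Gt = U.T @ G
    Xt = U.T @ fit.X
    rt = U.T @ fit.fixed_effect_residuals

    WG = Gt * dw[:, None]
    num = (rt @ WG) ** 2  # r' V^-1 g; r _|_ X in the V metric
    XtWX = (Xt.T * dw) @ Xt
    B = Xt.T @ WG  # p x m
    C = np.linalg.solve(XtWX, B)
    den = (Gt * WG).sum(axis=0) - (B * C).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 1e-12, num / den, 0.0)
    return t


# ---------------------------------------------------------------------------
# Genomic control and empirical significance
# ---------------------------------------------------------------------------


def genomic_control(statistics: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """lambda = median(T) / 0.4549; statistics divided by lambda unconditionally.

    Deflation (lambda < 1) is corrected the same way — dividing by a lambda
    below one inflates the statistics ("reverse genomic control").  Returns
    ``(lambda, corrected statistics, corrected p)``.
    """
    t = np.asarray(statistics, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no finite statistics")
    lam = float(np.median(t) / CHI2_MEDIAN_1DF)
    if lam <= 0:
        raise ValueError("lambda undefined (all statistics zero)")
    corrected = np.asarray(statistics, dtype=float) / lam
    p = stats.chi2.sf(corrected, df=1)
    return lam, corrected, p


def empirical_genomewide_p(
    G: np.ndarray,
    residuals: np.ndarray,
    n_perm: int,
    seed: int = 0,
    exhaustive: bool = False,
    alpha: float | None = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-based experiment-wise (genome-wide) p-values.

    Permutes the residual/phenotype vector, recomputes every SNP's score
    statistic, and records the maximum per permutation;
    p_emp = (1 + #{max >= observed}) / (n_perm + 1).  With ``exhaustive``
    all distinct permutations of a binary vector are enumerated and the exact
    p = #{max >= observed} / n_all (the identity permutation included).
    Returns ``(p_empirical per SNP, max distribution)``.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    G = np.asarray(G, dtype=float)
    G = np.where(G == MISSING, np.nan, G)
    col_mean = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(np.nan_to_num(col_mean), inds[1])
    e = np.asarray(residuals, dtype=float)
    n = e.size
    Gc = G - G.mean(axis=0)
    ss = (Gc * Gc).sum(axis=0)
    sigma2 = float(((e - e.mean()) ** 2).sum()) / n

    def stats_for(vec_matrix: np.ndarray) -> np.ndarray:
        vc = vec_matrix - vec_matrix.mean(axis=0)
        num = (Gc.T @ vc) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ss[:, None] > 0, num / (ss[:, None] * sigma2), 0.0)

    observed = stats_for(e[:, None])[:, 0]

    if exhaustive:
        uniq = np.unique(e)
        if uniq.size != 2:
            raise ValueError("exhaustive enumeration requires a binary vector")
        k = int((e == uniq.max()).sum())
        combos = list(itertools.combinations(range(n), k))
        perms = np.full((n, len(combos)), uniq.min())
        for c, idx in enumerate(combos):
            perms[list(idx), c] = uniq.max()
        maxes = stats_for(perms).max(axis=0)
        p_emp = np.array([(maxes >= obs - 1e-12).mean() for obs in observed])
        return p_emp, maxes

    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = rng.permutation(e)
    maxes = stats_for(perms).max(axis=0)
    if alpha is not None and 1.0 / (n_perm + 1) > alpha:
        log.warning("n_perm=%d gives p resolution coarser than alpha=%g", n_perm, alpha)
    p_emp = np.array([(1 + (maxes >= obs - 1e-12).sum()) / (n_perm + 1) for obs in observed])
    return p_emp, maxes


# ---------------------------------------------------------------------------
# Effective number of tests (eigenvalue method) and thresholds
# ---------------------------------------------------------------------------


@dataclass
class MeffEstimate:
    m_eff: int
    m_total: int
    window: int
    variance_fraction: float


def meff_from_correlation(corr: np.ndarray, variance_fraction: float = 0.995) -> int:
    """Smallest k with (sum of top-k eigenvalues) / (sum of all) >= C."""
    vals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    vals = np.clip(vals, 0, None)
    total = vals.sum()
    if total <= 0:
        return corr.shape[0]
    frac = np.cumsum(vals) / total
    return int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)


def simpleM_meff(
    gm: GenotypeMatrix | np.ndarray,
    window: int = 1000,
    variance_fraction: float = 0.995,
    chrom: np.ndarray | None = None,
) -> MeffEstimate:
    """Effective number of independent tests from block-wise SNP correlation.

    Per chromosome, SNPs are taken in windows of ``window``; each window
    contributes the smallest number of eigenvalues of its composite genotype
    correlation matrix explaining ``variance_fraction`` of the variance.
    Windows with < 2 SNPs contribute their SNP count.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(gm, GenotypeMatrix):
        G = gm.dosage(impute=True)
        chrom = gm.snps["chrom"].to_numpy()
    else:
        G = np.asarray(gm, dtype=float)
        if chrom is None:
            chrom = np.zeros(G.shape[1])
    m = G.shape[1]
    total = 0
    for c in pd.unique(pd.Series(chrom)):
        idx = np.flatnonzero(np.asarray(chrom) == c)
        for s in range(0, idx.size, window):
            block = idx[s : s + window]
            if block.size < 2:
                total += block.size
                continue
            sub = G[:, block]
            sd = sub.std(axis=0)
            keep = sd > 0
            total += int((~keep).sum())  # monomorphic columns count as 1 each
            if keep.sum() < 2:
                total += int(keep.sum())
                continue
            corr = np.corrcoef(sub[:, keep], rowvar=False)
            total += meff_from_correlation(corr, variance_fraction)
    total = min(total, m)
    return MeffEstimate(m_eff=total, m_total=m, window=window, variance_fraction=variance_fraction)


def significance_thresholds(alpha: float, m_total: int, m_eff: int | None = None) -> tuple[float, float | None]:
    """Bonferroni threshold alpha/m and the effective-test threshold alpha/m_eff."""
    if m_total < 1:
        raise ValueError("m_total must be >= 1")
    bonf = alpha / m_total
    eff = alpha / m_eff if m_eff else None
    return bonf, eff


# ---------------------------------------------------------------------------
# Whole-scan convenience wrapper
# ---------------------------------------------------------------------------


def association_scan(
    gm: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    kinship: np.ndarray | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the mixed-model (or plain trend) scan with GC and optional permutations.

    Returns a per-SNP table: statistic, lambda-corrected p, and (if n_perm>0)
    the empirical genome-wide p computed on environmental residuals.
    """
    ok = np.isfinite(y)
    G = gm.calls[ok].astype(float)
    G[G == MISSING] = np.nan
    yv = np.asarray(y, dtype=float)[ok]
    cov = None if covariates is None else np.asarray(covariates)[ok]
    if kinship is not None:
        fit = fit_polygenic(yv, cov, kinship[np.ix_(ok, ok)])
        statistic = mm_score_test(np.nan_to_num(G, nan=MISSING), fit)
        resid = fit.environmental_residuals
    else:
        statistic = trend_scan(np.nan_to_num(G, nan=MISSING), yv, cov)
        x = np.ones((yv.size, 1)) if cov is None else np.column_stack([np.ones(yv.size), cov])
        q, _ = np.linalg.qr(x)
        resid = yv - q @ (q.T @ yv)
    lam, corrected, p_gc = genomic_control(statistic)
    out = gm.snps[["snp_id", "chrom", "pos"]].copy()
    out["stat"] = statistic
    out["lambda"] = lam
    out["stat_gc"] = corrected
    out["p_gc"] = p_gc
    out["n_used"] = int(ok.sum())
    if n_perm > 0:
        p_emp, _maxes = empirical_genomewide_p(
            np.nan_to_num(G, nan=MISSING), resid, n_perm=n_perm, seed=seed
        )
        out["p_empirical"] = p_emp
    return out
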