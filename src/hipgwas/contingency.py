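"""Contingency-table analyses: combined two-SNP genotypes, odds ratios with
Woolf confidence intervals, frequency tables, and Spearman correlation with a
Fisher-z interval.

The combined genotype of two tag SNPs collapses the joint state into three
common categories: homozygous non-risk at both ("GA"), heterozygous at both
("RR", IUPAC ambiguity code), homozygous risk at both ("AG"); every mixed
hom/het combination is "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING

COMBINED_LEVELS = ("GA", "RR", "AG", "other")


def combine_two_snp_genotypes(
    g1: np.ndarray, g2: np.ndarray, risk_is_allele_b: tuple[bool, bool] = (True, True)
) -> np.ndarray:
    """Per-sample combined genotype of two SNPs (object array, None if missing).

    ``risk_is_allele_b`` says, per SNP, whether the counted allele is the risk
    allele; genotypes are reoriented to risk-allele counts before combining.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    out = np.empty(g1.shape, dtype=object)
    for i, (a, b) in enumerate(zip(g1, g2)):
        if a == MISSING or b == MISSING:
            out[i] = None
            continue
        ra = a if risk_is_allele_b[0] else 2 - a
        rb = b if risk_is_allele_b[1] else 2 - b
        if ra == 0 and rb == 0:
            out[i] = "GA"
        elif ra == 1 and rb == 1:
            out[i] = "RR"
        elif ra == 2 and rb == 2:
            out[i] = "AG"
        else:
            out[i] = "other"
    return out


@dataclass
class OrResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    haldane_corrected: bool = False
    undefined: bool = False


def odds_ratio_2x2(a: float, b: float, c: float, d: float, alpha: float = 0.05) -> OrResult:
    """OR = ad/bc with the Woolf (log-normal) confidence interval.

    A single zero cell triggers the Haldane-Anscombe +0.5 correction on all
    cells (flagged).  Two zero cells in one margin leave the OR undefined.
    The p-value is the Pearson chi-square (no continuity correction) on the
    uncorrected table.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("negative cell count")
    table = cells.reshape(2, 2)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return OrResult(float("nan"), float("nan"), float("nan"), float("nan"), undefined=True)
    corrected = False
    work = cells
    if (cells == 0).any():
        work = cells + 0.5
        corrected = True
    a_, b_, c_, d_ = work
    orr = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.exp(np.log(orr) - z * se), np.exp(np.log(orr) + z * se)
    chi2, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
    return OrResult(float(orr), float(lo), float(hi), float(p), haldane_corrected=corrected)


def genotypic_or(
    case_counts: tuple[float, float, float], control_counts: tuple[float, float, float]
) -> tuple[OrResult, OrResult]:
    """Odds ratios for genotypes Aa and AA relative to aa (shared reference).

    Counts are (n_aa, n_Aa, n_AA) per group.  Returns (OR_Aa, OR_AA), each a
    2x2 OR with its Woolf interval.
    """
    aa_case, het_case, hom_case = case_counts
    aa_ctrl, het_ctrl, hom_ctrl = control_counts
    or_het = odds_ratio_2x2(het_case, aa_case, het_ctrl, aa_ctrl)
    or_hom = odds_ratio_2x2(hom_case, aa_case, hom_ctrl, aa_ctrl)
    return or_het, or_hom


def frequency_table(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Counts and within-group proportions; per-group fractions sum to 1."""
    counts = pd.crosstab(values, groups)
    fractions = counts / counts.sum(axis=0)
    out = pd.concat({"count": counts, "fraction": fractions}, axis=1)
    return out


@dataclass
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int
    p: float


def spearman_fisher_ci(rho: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z interval tanh(atanh(rho) +- z / sqrt(n - 3))."""
    if n < 4:
        raise ValueError("need n >= 4")
    z = stats.norm.ppf(1 - alpha / 2)
    half = z / np.sqrt(n - 3)
    return float(np.tanh(np.arctanh(rho) - half)), float(np.tanh(np.arctanh(rho) + half))


def spearman_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> SpearmanResult:
    """Midrank Spearman rho with a Fisher-z confidence interval.

    Ties are handled by midranks; a constant vector leaves rho undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need n >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rho undefined")
    rho, p = stats.spearmanr(x, y)
    lo, hi = spearman_fisher_ci(float(rho), x.size, alpha)
    return SpearmanResult(rho=float(rho), ci_low=lo, ci_high=hi, n=int(x.size), p=float(p))


def comparison_threshold(n_loci: int = 4, n_tests_per_locus: int = 2, alpha: float = 0.05) -> float:
    """Multiple-testing cut-off alpha / (independent loci x phenotypic tests)."""
    if n_loci < 1 or n_tests_per_locus < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_loci * n_tests_per_locus)
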