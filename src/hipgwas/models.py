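"""Nested logistic risk models and ROC/AUC discrimination testing.

The full model regresses case status on two deletion indicators (one deleted
allele; both alleles deleted) plus an indicator for the protective combined
SNP genotype; the reduced model drops the deletion terms.  The models are
compared twice: by the deviance difference against a chi-square with the
difference in degrees of freedom, and by the DeLong test for paired AUCs
(one-sided: does the full model discriminate better?).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class GlmFit:
    params: pd.Series
    bse: pd.Series
    residual_deviance: float
    df_residual: int
    fitted: np.ndarray
    converged: bool
    separation_flag: bool

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """exp(coef) with Wald confidence intervals."""
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": np.exp(self.params - z * self.bse),
                "ci_high": np.exp(self.params + z * self.bse),
            }
        )


def fit_logistic(outcome: np.ndarray, design: pd.DataFrame | np.ndarray) -> GlmFit:
    """Logistic GLM by IRLS; residual deviance = -2 log-likelihood.

    Complete separation is detected from runaway coefficients and flagged
    (the fit is still returned, with a warning).
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be 0/1")
    X = pd.DataFrame(design).copy()
    if "const" not in X.columns:
        X.insert(0, "const", 1.0)
    model = sm.GLM(y, X.astype(float), family=sm.families.Binomial())
    res = model.fit(maxiter=50, tol=1e-10)
    separation = bool(np.any(np.abs(res.params.to_numpy()) > 15))
    if separation:
        log.warning("possible complete separation: coefficient(s) diverging")
    return GlmFit(
        params=res.params,
        bse=res.bse,
        residual_deviance=float(res.deviance),
        df_residual=int(res.df_resid),
        fitted=np.asarray(res.fittedvalues),
        converged=bool(res.converged),
        separation_flag=separation,
    )


def deletion_design(
    deletion_alleles: np.ndarray, combined_genotype: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full and reduced design matrices for the deletion risk model.

    Full: indicator(one deleted allele), indicator(two deleted alleles),
    indicator(combined genotype == GA).  Reduced: the GA indicator only.
    """
    d = np.asarray(deletion_alleles)
    full = pd.DataFrame(
        {
            "deletion_one": (d == 1).astype(float),
            "deletion_both": (d == 2).astype(float),
            "ga_genotype": (np.asarray(combined_genotype) == "GA").astype(float),
        }
    )
    reduced = full[["ga_genotype"]].copy()
    return full, reduced


@dataclass
class DevianceComparison:
    delta_deviance: float
    df: int
    p: float


def deviance_compare(full: GlmFit, reduced: GlmFit) -> DevianceComparison:
    """Chi-square test of the deviance drop from reduced to nested full model."""
    df = reduced.df_residual - full.df_residual
    if df < 0:
        raise ValueError("reduced model must be nested in the full model")
    delta = reduced.residual_deviance - full.residual_deviance
    if df == 0:
        return DevianceComparison(delta_deviance=float(delta), df=0, p=1.0)
    return DevianceComparison(
        delta_deviance=float(delta), df=int(df), p=float(stats.chi2.sf(max(delta, 0.0), df=df))
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic / (n1 n0); ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass
class RocComparison:
    auc_full: float
    auc_reduced: float
    z: float
    p_one_sided: float
    variance: float
    undefined: bool = False


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values for positives (V10) and negatives (V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    return v10, v01


def delong_compare(
    scores_full: np.ndarray, scores_reduced: np.ndarray, labels: np.ndarray
) -> RocComparison:
    """Paired DeLong comparison of two AUCs on the same samples.

    Z = (AUC_full - AUC_reduced) / sd with the placement-value covariance;
    one-sided p from the upper normal tail.  Identical score vectors give
    zero variance and an undefined Z (flagged).
    """
    y = np.asarray(labels, dtype=int)
    sf = np.asarray(scores_full, dtype=float)
    sr = np.asarray(scores_reduced, dtype=float)
    v10f, v01f = _placements(sf, y)
    v10r, v01r = _placements(sr, y)
    auc_f = float(v10f.mean())
    auc_r = float(v10r.mean())
    n1, n0 = v10f.size, v01f.size
    s10 = np.cov(np.vstack([v10f, v10r]))
    s01 = np.cov(np.vstack([v01f, v01r]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n0
    if var <= 0:
        return RocComparison(auc_f, auc_r, float("nan"), float("nan"), float(var), undefined=True)
    z = (auc_f - auc_r) / np.sqrt(var)
    return RocComparison(auc_f, auc_r, float(z), float(stats.norm.sf(z)), float(var))


def compare_risk_models(
    outcome: np.ndarray, deletion_alleles: np.ndarray, combined_genotype: np.ndarray
) -> dict:
    """Fit full/reduced deletion models and run both comparisons.

    Returns a dict with the two fits, the deviance test and the DeLong test,
    mirroring a model-comparison report row (residual df/deviance, delta
    deviance with p, AUCs, Z and one-sided p).
    """
    full_X, reduced_X = deletion_design(deletion_alleles, combined_genotype)
    full = fit_logistic(outcome, full_X)
    reduced = fit_logistic(outcome, reduced_X)
    dev = deviance_compare(full, reduced)
    roc = delong_compare(full.fitted, reduced.fitted, outcome)
    return {
        "full": full,
        "reduced": reduced,
        "deviance": dev,
        "roc": roc,
    }
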