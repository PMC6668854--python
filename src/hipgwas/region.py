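"""Target-region association and the segregating-variant screen.

The regional test is a Cochran-Mantel-Haenszel (CMH) chi-square on allelic
2 x 2 tables stratified by genotyping batch:

    M^2 = (sum_k (a_k - E[a_k]))^2 / sum_k Var(a_k)

with one degree of freedom and no continuity correction.  The default
per-stratum variance is r1 r2 c1 c2 / n^3, which makes the single-stratum
statistic identical to the Pearson chi-square; ``variance="hypergeometric"``
gives the classical r1 r2 c1 c2 / (n^2 (n-1)) form.  Strata with a zero
margin carry no information and are dropped.

Family-wise significance over a region comes from permuting case/control
labels *within* strata (preserving the batch structure that the CMH
conditions on) and recording the maximum M^2 across SNPs per permutation.

The segregation screen retains annotated variants whose case/control carrier
count difference is large (|delta| >= 22 by default) and whose functional
class is not intergenic, intronic or synonymous; negative delta marks
control-enriched (candidate protective) variants.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_EXCLUDED_CLASSES = frozenset({"intergenic", "intronic", "synonymous"})


# ---------------------------------------------------------------------------
# CMH statistic
# ---------------------------------------------------------------------------


@dataclass
class CmhResult:
    m2: float
    p_raw: float
    n_strata_used: int

    def p_bonferroni(self, n_tests: int) -> float:
        return min(1.0, n_tests * self.p_raw)


def cmh_m2(tables: list[np.ndarray], variance: str = "pearson") -> CmhResult:
    """CMH chi-square for a list of per-stratum 2x2 tables [[a, b], [c, d]].

    Rows are case/control, columns counted/other allele.  Zero-margin strata
    are dropped; if all strata drop the statistic is undefined (NaN, flagged
    by n_strata_used == 0).
    """
    if variance not in ("pearson", "hypergeometric"):
        raise ValueError("variance must be 'pearson' or 'hypergeometric'")
    num = 0.0
    den = 0.0
    used = 0
    for t in tables:
        t = np.asarray(t, dtype=float)
        r1, r2 = t.sum(axis=1)
        c1, c2 = t.sum(axis=0)
        n = t.sum()
        if min(r1, r2, c1, c2) <= 0:
            continue
        a = t[0, 0]
        num += a - r1 * c1 / n
        if variance == "pearson":
            den += r1 * r2 * c1 * c2 / n**3
        else:
            den += r1 * r2 * c1 * c2 / (n * n * (n - 1))
        used += 1
    if used == 0 or den <= 0:
        return CmhResult(m2=float("nan"), p_raw=float("nan"), n_strata_used=0)
    m2 = num * num / den
    return CmhResult(m2=float(m2), p_raw=float(stats.chi2.sf(m2, df=1)), n_strata_used=used)


def allele_tables(
    g: np.ndarray, y: np.ndarray, strata: np.ndarray
) -> list[np.ndarray]:
    """Per-stratum allelic 2x2 tables (rows case/control, cols counted/other)."""
    g = np.asarray(g)
    ok = g != MISSING
    tables = []
    for s in pd.unique(pd.Series(strata)):
        m = ok & (np.asarray(strata) == s)
        gc = g[m & (y == 1)].astype(float)
        gn = g[m & (y == 0)].astype(float)
        tables.append(
            np.array(
                [
                    [gc.sum(), 2 * gc.size - gc.sum()],
                    [gn.sum(), 2 * gn.size - gn.sum()],
                ]
            )
        )
    return tables


def cmh_scan(
    gm: GenotypeMatrix, y: np.ndarray, strata: np.ndarray, variance: str = "pearson"
) -> pd.DataFrame:
    """Per-SNP CMH over a region; Bonferroni over the SNPs actually tested."""
    rows = []
    for j in range(gm.n_snps):
        res = cmh_m2(allele_tables(gm.calls[:, j], y, strata), variance=variance)
        rows.append((gm.snps.loc[j, "snp_id"], gm.snps.loc[j, "pos"], res.m2, res.p_raw, res.n_strata_used))
    out = pd.DataFrame(rows, columns=["snp_id", "pos", "m2", "p_raw", "n_strata"])
    tested = out["m2"].notna().sum()
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * tested)
    return out


# ---------------------------------------------------------------------------
# Max-M^2 permutation null
# ---------------------------------------------------------------------------


@dataclass
class NullMaxDist:
    n_perm: int
    max_values: np.ndarray
    exhaustive: bool = False

    @property
    def mean(self) -> float:
        return float(np.mean(self.max_values))

    @property
    def q2_5(self) -> float:
        return float(np.percentile(self.max_values, 2.5))

    @property
    def q97_5(self) -> float:
        return float(np.percentile(self.max_values, 97.5))


def _m2_batch(
    Gval: np.ndarray,
    Gobs: np.ndarray,
    case_mat: np.ndarray,
    strata_masks: list[np.ndarray],
    variance: str,
) -> np.ndarray:
    """M^2 for every SNP (rows) under every case-label column of case_mat.

    Gval: n x m alt-allele counts with missing as 0; Gobs: n x m 0/1
    observed mask; case_mat: n x B 0/1 case indicators.
    """
    m = Gval.shape[1]
    B = case_mat.shape[1]
    num = np.zeros((m, B))
    den = np.zeros((m, B))
    for mask in strata_masks:
        Gv = Gval[mask]
        Go = Gobs[mask]
        C = case_mat[mask]
        a = Gv.T @ C  # m x B: alt alleles among cases
        n1 = 2 * (Go.T @ C)  # alleles among cases
        tot_alt = Gv.sum(axis=0)[:, None]
        tot_all = 2 * Go.sum(axis=0)[:, None]
        n2 = tot_all - n1
        c1 = tot_alt
        c2 = tot_all - tot_alt
        with np.errstate(invalid="ignore", divide="ignore"):
            e = n1 * c1 / tot_all
            if variance == "pearson":
                v = n1 * n2 * c1 * c2 / tot_all**3
            else:
                v = n1 * n2 * c1 * c2 / (tot_all * tot_all * (tot_all - 1))
        informative = (
            (n1 > 0) & (n2 > 0) & np.broadcast_to((c1 > 0) & (c2 > 0), v.shape)
        )
        num += np.where(informative, a - e, 0.0)
        den += np.where(informative, v, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m2 = np.where(den > 0, num * num / den, np.nan)
    return m2


def max_m2_permutation(
    gm: GenotypeMatrix,
    y: np.ndarray,
    strata: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    variance: str = "pearson",
    exhaustive_limit: int = 100_000,
) -> tuple[NullMaxDist, pd.DataFrame]:
    """Permutation null of the maximum M^2 over a region, labels permuted within strata.

    Returns the null max distribution (mean and 2.5/97.5 percentiles) and a
    per-SNP frame with observed M^2 and the family-wise p
    (1 + #{max >= observed}) / (n_perm + 1); when the number of distinct
    within-strata permutations is below ``exhaustive_limit`` they are
    enumerated instead and the p is exact.
    """
    y = np.asarray(y, dtype=int)
    strata = np.asarray(strata)
    levels = pd.unique(pd.Series(strata))
    strata_masks = [np.asarray(strata) == s for s in levels]
    Gval = np.where(gm.calls == MISSING, 0, gm.calls).astype(float)
    Gobs = (gm.calls != MISSING).astype(float)

    observed = _m2_batch(Gval, Gobs, y[:, None].astype(float), strata_masks, variance)[:, 0]

    from math import comb

    n_distinct = 1
    for mask in strata_masks:
        n_distinct *= comb(int(mask.sum()), int(y[mask].sum()))
        if n_distinct > exhaustive_limit:
            break

    if n_distinct <= exhaustive_limit:
        per_stratum = []
        for mask in strata_masks:
            idx = np.flatnonzero(mask)
            k = int(y[idx].sum())
            per_stratum.append([set(c) for c in itertools.combinations(idx.tolist(), k)])
        cols = []
        for assignment in itertools.product(*per_stratum):
            v = np.zeros(y.size)
            for chosen in assignment:
                for i in chosen:
                    v[i] = 1.0
            cols.append(v)
        case_mat = np.column_stack(cols)
        m2 = _m2_batch(Gval, Gobs, case_mat, strata_masks, variance)
        maxes = np.nanmax(m2, axis=0)
        p_fwer = np.array([np.mean(maxes >= obs - 1e-12) if np.isfinite(obs) else np.nan for obs in observed])
        dist = NullMaxDist(n_perm=case_mat.shape[1], max_values=maxes, exhaustive=True)
    else:
        rng = np.random.default_rng(seed)
        batch = 200  # permutations per block keeps memory bounded
        maxes = np.empty(n_perm)
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            case_mat = np.empty((y.size, b))
            for col in range(b):
                v = y.astype(float).copy()
                for mask in strata_masks:
                    idx = np.flatnonzero(mask)
                    v[idx] = v[rng.permutation(idx)]
                case_mat[:, col] = v
            m2 = _m2_batch(Gval, Gobs, case_mat, strata_masks, variance)
            maxes[done : done + b] = np.nanmax(m2, axis=0)
            done += b
        p_fwer = np.array(
            [
                (1 + np.sum(maxes >= obs - 1e-12)) / (n_perm + 1) if np.isfinite(obs) else np.nan
                for obs in observed
            ]
        )
        dist = NullMaxDist(n_perm=n_perm, max_values=maxes, exhaustive=False)

    out = gm.snps[["snp_id", "chrom", "pos"]].copy()
    out["m2"] = observed
    out["p_fwer"] = p_fwer
    return dist, out


# ---------------------------------------------------------------------------
# Segregation screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    retained: pd.DataFrame
    min_abs_diff: int
    excluded_classes: frozenset


def segregation_screen(
    variants: pd.DataFrame,
    min_abs_diff: int = 22,
    excluded_classes: frozenset = DEFAULT_EXCLUDED_CLASSES,
) -> ScreenResult:
    """Retain variants with |case carriers - control carriers| >= threshold.

    A carrier is any sample with at least one alternate allele.  Variants in
    the excluded functional classes are dropped regardless of delta; negative
    delta (control-enriched, candidate protective) is preserved in the output.
    Output row order is position-sorted, independent of input order.
    """
    df = variants.copy()
    df["delta"] = df["case_carriers"] - df["control_carriers"]
    keep = (~df["effect_class"].isin(excluded_classes)) & (df["delta"].abs() >= min_abs_diff)
    retained = (
        df.loc[keep]
        .sort_values(["chrom", "pos", "alt"], kind="mergesort")
        .reset_index(drop=True)
    )
    return ScreenResult(
        retained=retained, min_abs_diff=min_abs_diff, excluded_classes=frozenset(excluded_classes)
    )


def gene_effect_rollup(variants: pd.DataFrame, screen: ScreenResult) -> pd.DataFrame:
    """Signed carrier-difference totals per (gene, effect class).

    Genes with at least one retained (segregating) variant are rolled up over
    *all* their variants outside the screen's excluded classes; positive cells
    are case-enriched, negative control-enriched.
    """
    genes = set(screen.retained["gene"])
    df = variants.copy()
    df["delta"] = df["case_carriers"] - df["control_carriers"]
    df = df.loc[
        df["gene"].isin(genes) & ~df["effect_class"].isin(screen.excluded_classes)
    ]
    table = (
        df.pivot_table(index="gene", columns="effect_class", values="delta", aggfunc="sum", fill_value=0)
        .sort_index()
    )
    return table
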