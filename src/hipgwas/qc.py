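"""Genotype quality control and batch merging with strand reconciliation.

Filters are applied in a fixed, documented order (the counts depend on it):
per-SNP call rate, per-sample call rate, minor allele frequency, then a
Hardy-Weinberg test computed on controls only — cases may legitimately
deviate from HWE at trait-associated SNPs.  Only autosomal SNPs are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import COMPLEMENT, MISSING, GenotypeMatrix, PhenotypeClass, classify_phenotype

log = logging.getLogger(__name__)

N_AUTOSOMES = 38  # dog karyotype: 38 autosome pairs + X/Y


@dataclass
class QcThresholds:
    maf_min: float = 0.05
    sample_call_min: float = 0.90
    snp_call_min: float = 0.95
    hwe_p_min: float = 1e-5
    n_autosomes: int = N_AUTOSOMES
    exclude_samples: tuple = ()  # explicit id exclusions (e.g. outlier genotypes)

    def __post_init__(self) -> None:
        for name in ("maf_min", "sample_call_min", "snp_call_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class QcReport:
    n_snps_in: int = 0
    n_samples_in: int = 0
    snps_removed_by_rule: dict = field(default_factory=dict)
    samples_removed: list = field(default_factory=list)
    n_snps_out: int = 0
    n_samples_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("snps_in", self.n_snps_in), ("samples_in", self.n_samples_in)]
        rows += [(f"snps_removed_{rule}", len(ids)) for rule, ids in self.snps_removed_by_rule.items()]
        rows += [
            ("samples_removed", len(self.samples_removed)),
            ("snps_out", self.n_snps_out),
            ("samples_out", self.n_samples_out),
        ]
        return pd.DataFrame(rows, columns=["item", "count"])


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float, bool]:
    """Pearson 1-df chi-square test against Hardy-Weinberg expectations.

    Expected genotype counts derive from the sample allele frequency.  A
    monomorphic SNP cannot deviate: (0, 1) is returned with a flag.
    Returns ``(statistic, p, monomorphic)``.
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("empty genotype counts")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0, True
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    statistic = float(((obs - exp) ** 2 / exp).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1)), False


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value (sum of heterozygote-count probabilities <= observed)."""
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("empty genotype counts")
    rare = min(2 * n_aa + n_ab, n_ab + 2 * n_bb)  # rarer allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    def logprob(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_r + 1)
            - gammaln(hom_c + 1)
            - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
        )

    lp = np.array([logprob(h) for h in hets])
    pr = np.exp(lp - lp.max())
    pr /= pr.sum()
    obs = pr[hets == n_ab][0] if n_ab in hets else 0.0
    return float(min(1.0, pr[pr <= obs * (1 + 1e-12)].sum()))


def _hwe_p_vector(gm: GenotypeMatrix, sample_mask: np.ndarray, exact: bool = False) -> np.ndarray:
    calls = gm.calls[sample_mask]
    p = np.ones(gm.n_snps)
    for j in range(gm.n_snps):
        col = calls[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        counts = [(col == 0).sum(), (col == 1).sum(), (col == 2).sum()]
        if exact:
            p[j] = hwe_exact_test(*counts)
        else:
            _stat, pj, _mono = hwe_test(*counts)
            p[j] = pj
    return p


def _is_autosome(chrom: pd.Series, n_autosomes: int) -> np.ndarray:
    def ok(c):
        try:
            return 1 <= int(c) <= n_autosomes
        except (TypeError, ValueError):
            return False

    return chrom.map(ok).to_numpy()


def apply_qc(
    gm: GenotypeMatrix,
    cohort: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    exact_hwe: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the QC filter cascade; the report itemizes removals per rule.

    Order: autosome restriction -> per-SNP call rate -> per-sample call rate
    -> MAF -> HWE on controls.  The HWE step is skipped with a warning when
    the cohort contains no controls.
    """
    thr = thresholds or QcThresholds()
    report = QcReport(n_snps_in=gm.n_snps, n_samples_in=gm.n_samples)

    keep_snp = np.ones(gm.n_snps, dtype=bool)
    removed: dict[str, list] = {}

    auto = _is_autosome(gm.snps["chrom"], thr.n_autosomes)
    removed["non_autosomal"] = list(gm.snps.loc[~auto, "snp_id"])
    keep_snp &= auto

    cr_snp = gm.call_rate_snps()
    rule = keep_snp & (cr_snp < thr.snp_call_min)
    removed["snp_call_rate"] = list(gm.snps.loc[rule, "snp_id"])
    keep_snp &= ~rule

    # per-sample call rate computed over SNPs surviving so far
    sub = gm.calls[:, keep_snp]
    cr_sample = 1.0 - (sub == MISSING).mean(axis=1) if sub.shape[1] else np.ones(gm.n_samples)
    keep_sample = cr_sample >= thr.sample_call_min
    excl = np.isin(np.array(gm.samples), list(thr.exclude_samples))
    keep_sample &= ~excl
    report.samples_removed = [s for s, k in zip(gm.samples, keep_sample) if not k]

    trimmed = gm.subset(np.flatnonzero(keep_sample), np.arange(gm.n_snps))

    maf = trimmed.maf()
    rule = keep_snp & (np.nan_to_num(maf) < thr.maf_min)
    removed["maf"] = list(gm.snps.loc[rule, "snp_id"])
    keep_snp &= ~rule

    # HWE on controls only
    pheno = np.array(
        [
            classify_phenotype(l, r)
            for l, r in zip(
                cohort.set_index("dog_id").loc[trimmed.samples, "hip_left"],
                cohort.set_index("dog_id").loc[trimmed.samples, "hip_right"],
            )
        ]
    )
    is_control = np.array([c is PhenotypeClass.CONTROL for c in pheno])
    if is_control.sum() == 0:
        log.warning("no controls in cohort; HWE filter skipped")
        removed["hwe_controls"] = []
    else:
        hwe_p = _hwe_p_vector(trimmed, is_control, exact=exact_hwe)
        rule = keep_snp & (hwe_p < thr.hwe_p_min)
        removed["hwe_controls"] = list(gm.snps.loc[rule, "snp_id"])
        keep_snp &= ~rule

    out = trimmed.subset(None, np.flatnonzero(keep_snp))
    report.snps_removed_by_rule = removed
    report.n_snps_out = out.n_snps
    report.n_samples_out = out.n_samples
    return out, report


# ---------------------------------------------------------------------------
# Batch merging with strand reconciliation
# ---------------------------------------------------------------------------


def _is_ambiguous(a: str, b: str) -> bool:
    """A/T and C/G SNPs cannot be strand-reconciled from allele labels."""
    return {a, b} in ({"A", "T"}, {"C", "G"})


def merge_batches(batches: list[GenotypeMatrix]) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Merge disjoint-sample batches on shared SNP ids, reconciling strands.

    For SNPs whose allele pairs are reverse complements across batches the
    later batch is complemented before merging.  Strand-ambiguous (A/T, C/G)
    SNPs with discordant allele labels and SNPs whose allele sets cannot be
    reconciled by complementing are dropped.  Returns the merged matrix and a
    log frame of per-SNP actions.
    """
    if not batches:
        raise ValueError("no batches to merge")
    base = batches[0]
    shared = set(base.snps["snp_id"])
    for b in batches[1:]:
        shared &= set(b.snps["snp_id"])
    order = [s for s in base.snps["snp_id"] if s in shared]

    all_samples = [s for b in batches for s in b.samples]
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("sample ids overlap across batches")

    actions: list[tuple[str, str]] = []
    keep: list[str] = []
    aligned_calls: list[list[np.ndarray]] = []
    idx_of = [{sid: j for j, sid in enumerate(b.snps["snp_id"])} for b in batches]

    for sid in order:
        j0 = idx_of[0][sid]
        ref_a, ref_b = base.snps.loc[j0, ["allele_a", "allele_b"]]
        cols = [base.calls[:, j0]]
        ok = True
        action = "kept"
        for bi, b in enumerate(batches[1:], start=1):
            j = idx_of[bi][sid]
            a, bb = b.snps.loc[j, ["allele_a", "allele_b"]]
            col = b.calls[:, j]
            ref_set = {ref_a, ref_b} - {"0"}
            this_set = {a, bb} - {"0"}
            if _is_ambiguous(ref_a, ref_b) or _is_ambiguous(a, bb):
                if this_set == ref_set and (a, bb) == (ref_a, ref_b):
                    action = "ambiguous_kept"
                else:
                    ok, action = False, "ambiguous_dropped"
                    break
            elif this_set <= ref_set or not this_set:
                if a == ref_b and bb == ref_a:  # swapped labels: recode
                    col = np.where(col == MISSING, MISSING, 2 - col).astype(np.int8)
                    action = "swapped"
            else:
                comp = {COMPLEMENT[x] for x in this_set}
                if comp <= ref_set:
                    ca, cb = COMPLEMENT[a], COMPLEMENT[bb]
                    if ca == ref_b and cb == ref_a:
                        col = np.where(col == MISSING, MISSING, 2 - col).astype(np.int8)
                        action = "flipped_swapped"
                    else:
                        action = "flipped"
                else:
                    ok, action = False, "irreconcilable_dropped"
                    break
            cols.append(col)
        actions.append((sid, action))
        if ok:
            keep.append(sid)
            aligned_calls.append(cols)

    log_df = pd.DataFrame(actions, columns=["snp_id", "action"])
    snp_rows = base.snps.set_index("snp_id").loc[keep].reset_index()
    calls = np.concatenate(
        [np.stack([cols[bi] for cols in aligned_calls], axis=1) for bi in range(len(batches))],
        axis=0,
    ) if keep else np.empty((len(all_samples), 0), dtype=np.int8)
    merged = GenotypeMatrix(samples=all_samples, snps=snp_rows, calls=calls.astype(np.int8))
    dropped = log_df["action"].str.endswith("dropped").sum()
    if dropped:
        log.info("merge_batches dropped %d unreconcilable SNPs", dropped)
    return merged, log_df
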