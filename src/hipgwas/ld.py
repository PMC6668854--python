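"""Linkage disequilibrium from unphased genotypes and greedy clumping.

r^2 between two SNPs is estimated by maximum likelihood: haplotype
frequencies under Hardy-Weinberg are obtained with an EM algorithm from the
3 x 3 genotype table (the double heterozygote is the only ambiguous cell),
then r^2 = D^2 / (p_A p_a p_B p_b).  Clumping greedily groups associated SNPs
into loci: the most significant unassigned SNP passing the p threshold
becomes an index, capturing every unassigned SNP on the same chromosome
within the distance cut-off whose r^2 with it reaches the r^2 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class LdPair:
    r2: float
    haplotype_freqs: np.ndarray  # (p_AB, p_Ab, p_aB, p_ab); A/B = allele_b of each SNP
    d: float
    converged: bool
    method: str  # "em" or "composite"


def _complete_pairs(gi: np.ndarray, gj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    ok = (gi != MISSING) & (gj != MISSING)
    return gi[ok].astype(int), gj[ok].astype(int)


def haplotype_em(
    gi: np.ndarray, gj: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[np.ndarray, bool]:
    """EM haplotype frequencies (AB, Ab, aB, ab) from two unphased SNPs.

    'A'/'B' denote the counted alleles of the two SNPs.  Converged when the
    largest frequency change drops below ``tol``.
    """
    gi, gj = _complete_pairs(gi, gj)
    n = gi.size
    if n == 0:
        raise ValueError("no complete genotype pairs")
    table = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            table[a, b] = np.sum((gi == a) & (gj == b))

    pA = gi.mean() / 2
    pB = gj.mean() / 2
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    dh = table[1, 1]  # double heterozygotes: AB/ab vs Ab/aB unresolved
    converged = False
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        frac = cis / (cis + trans) if cis + trans > 0 else 0.5
        # expected haplotype counts (2n total)
        c = np.zeros(4)
        c[0] = 2 * table[2, 2] + table[2, 1] + table[1, 2] + dh * frac
        c[1] = 2 * table[2, 0] + table[2, 1] + table[1, 0] + dh * (1 - frac)
        c[2] = 2 * table[0, 2] + table[0, 1] + table[1, 2] + dh * (1 - frac)
        c[3] = 2 * table[0, 0] + table[0, 1] + table[1, 0] + dh * frac
        newf = c / (2 * n)
        delta = np.abs(newf - f).max()
        f = newf
        if delta < tol:
            converged = True
            break
    return f, converged


def r2_em(gi: np.ndarray, gj: np.ndarray) -> LdPair:
    """EM-based r^2; falls back to composite genotype correlation on failure."""
    f, converged = haplotype_em(gi, gj)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    denom = pA * (1 - pA) * pB * (1 - pB)
    d = f[0] - pA * pB
    if converged and denom > 0:
        return LdPair(r2=float(d * d / denom), haplotype_freqs=f, d=float(d), converged=True, method="em")
    ci, cj = _complete_pairs(gi, gj)
    if np.ptp(ci) == 0 or np.ptp(cj) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(ci, cj)[0, 1] ** 2)
    return LdPair(r2=r2, haplotype_freqs=f, d=float(d), converged=False, method="composite")


def ld_matrix(gm: GenotypeMatrix, snp_ids: list[str]) -> pd.DataFrame:
    """Pairwise EM r^2 for a set of SNPs (long-format frame)."""
    idx = [gm.snp_index(s) for s in snp_ids]
    rows = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            pair = r2_em(gm.calls[:, idx[a]], gm.calls[:, idx[b]])
            rows.append((snp_ids[a], snp_ids[b], pair.r2, pair.method))
    return pd.DataFrame(rows, columns=["snp_i", "snp_j", "r2", "method"])


@dataclass
class ClumpSet:
    clumps: list  # list of (index_snp, [member snp_ids])
    p_threshold: float
    r2_threshold: float
    max_distance: float

    @property
    def n_clumps(self) -> int:
        return len(self.clumps)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i, index, ",".join(members), len(members) + 1)
            for i, (index, members) in enumerate(self.clumps)
        ]
        return pd.DataFrame(rows, columns=["clump", "index_snp", "members", "size"])


def clump_markers(
    assoc: pd.DataFrame,
    gm: GenotypeMatrix,
    p_threshold: float = 5e-5,
    r2_threshold: float = 0.70,
    max_distance: float = 7.5e6,
    p_column: str = "p_gc",
) -> ClumpSet:
    """Greedy clumping of association results into independently associated loci.

    ``assoc`` needs columns snp_id, chrom, pos and a p-value column.  Ties in
    p are broken by genomic position (smaller coordinate first).
    """
    df = assoc.loc[assoc[p_column] <= p_threshold, ["snp_id", "chrom", "pos", p_column]]
    df = df.sort_values([p_column, "pos"], kind="mergesort").reset_index(drop=True)
    unassigned = dict(zip(df["snp_id"], zip(df["chrom"], df["pos"])))
    clumps: list[tuple[str, list[str]]] = []
    for snp in df["snp_id"]:
        if snp not in unassigned:
            continue
        chrom, pos = unassigned.pop(snp)
        members = []
        ji = gm.snp_index(snp)
        for other, (oc, op) in list(unassigned.items()):
            if oc != chrom or abs(op - pos) > max_distance:
                continue
            pair = r2_em(gm.calls[:, ji], gm.calls[:, gm.snp_index(other)])
            if pair.r2 >= r2_threshold:
                members.append(other)
                del unassigned[other]
        clumps.append((snp, members))
    return ClumpSet(
        clumps=clumps,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        max_distance=max_distance,
    )
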