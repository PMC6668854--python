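"""Synthetic cohort generator.

Emulates the statistical structure of a stratified purebred-dog case-control
cohort so that every downstream stage (QC, structure correction, association
scanning, clumping, regional tests, fragment analyses) can be exercised and
validated without external data:

* population structure: per-cluster allele frequencies drift from a common
  ancestral frequency under the Balding-Nichols model at a configurable Fst;
* linkage disequilibrium: SNPs come in blocks sharing an ancestral
  frequency; along a block each haplotype copies its previous allele state
  with high probability and otherwise draws afresh, so adjacent SNPs reach
  r of about the copying probability; diplotypes pair two independent
  haplotypes (Hardy-Weinberg within cluster);
* phenotype: binary disease liability from a logistic model whose per-locus
  log-odds equal log(allelic OR) per risk allele plus a cluster intercept
  (the intercepts create the stratification confounding that genomic control
  and cluster covariates must absorb);
* hip scores: controls become A/A, mild cases C/C, the rest moderate-to-severe
  pairs, so phenotype classification maps back deterministically; a fraction
  of dogs receives a borderline B score and drops out of all analyses;
* genotyping artefacts: round-robin batch assignment and independent missing
  calls.

Default parameter values mirror the study conditions this generator stands in
for: 525 dogs, 4 subpopulation clusters, Fst 0.05, a protective locus with
allelic OR 0.4 and a risk locus with OR 2.3 on the same chromosome more than
7.5 Mb apart, case fraction ~0.47 with ~32% of cases mild, and a deletion
locus rank-correlated with its tag SNP at Spearman rho 0.65.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import MISSING, GenotypeMatrix, write_ped_map, write_cohort

MODERATE_SEVERE_PAIRS = [("C", "D"), ("D", "C"), ("D", "D"), ("D", "E"), ("E", "D"), ("E", "E")]
STRICT_PAIRS = [("D", "D"), ("D", "E"), ("E", "D"), ("E", "E")]


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_dogs: int = 525
    n_snps: int = 2000
    n_chromosomes: int = 5
    n_clusters: int = 4
    fst: float = 0.05
    ld_block_len: int = 10
    #: (snp_index, allelic odds ratio, ancestral MAF); the two defaults sit on
    #: the same chromosome > 7.5 Mb apart (a protective and a risk locus).
    causal_loci: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(500, 0.4, 0.3), (700, 2.3, 0.2)]
    )
    batch_count: int = 3
    missing_rate: float = 0.01
    b_score_rate: float = 0.05
    #: fraction of dogs that are cases before B-score dropout (247/526 in the
    #: emulated cohort) and the mild / strict split among cases.
    case_fraction: float = 247 / 526
    mild_fraction: float = 79 / 247
    strict_fraction: float = 132 / 168
    #: spread of cluster intercepts on the log-odds scale (confounding strength)
    cluster_intercept_spread: float = 1.0
    #: probability a haplotype copies the previous allele state within a
    #: block (adjacent-SNP allelic correlation; controls within-block LD).
    #: 0.98 puts within-block r^2 at ~0.70-0.96, the moderate-to-high range
    #: seen within real associated loci on these arrays.
    ld_rho: float = 0.98
    snp_spacing: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for idx, orr, maf in self.causal_loci:
            if not (0 <= idx < self.n_snps):
                raise ValueError(f"causal snp_index {idx} out of range")
            if orr <= 0:
                raise ValueError("allelic_odds_ratio must be > 0")
            if not (0 < maf <= 0.5):
                raise ValueError("ancestral MAF must be in (0, 0.5]")


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for downstream validation."""

    cluster_of_dog: np.ndarray
    #: block index -> per-cluster allele frequencies of the block's SNPs
    haplotype_frequencies: dict
    realized_or: dict
    disease: np.ndarray
    #: causal snp_index -> True when allele_b in the stored matrix is the
    #: non-risk allele (minor-allele orientation flipped the risk allele)
    causal_flipped: dict = field(default_factory=dict)
    deletion_tag_rho: float | None = None
    seed: int = 0


def _balding_nichols_freqs(rng, ancestral: np.ndarray, fst: float, k: int) -> np.ndarray:
    """Per-cluster allele frequencies drifted from ancestral ones at given Fst."""
    if fst == 0:
        return np.tile(ancestral, (k, 1))
    a = ancestral * (1 - fst) / fst
    b = (1 - ancestral) * (1 - fst) / fst
    return rng.beta(a, b, size=(k, ancestral.size))


def _allelic_or(g: np.ndarray, y: np.ndarray) -> float:
    """Direct 2x2 allele-count odds ratio (risk allele = allele_b)."""
    ok = g != MISSING
    g, y = g[ok].astype(float), y[ok]
    a = g[y == 1].sum()  # risk alleles in cases
    b = 2 * (y == 1).sum() - a
    c = g[y == 0].sum()
    d = 2 * (y == 0).sum() - c
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Draw a full synthetic cohort; fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m, k = config.n_dogs, config.n_snps, config.n_clusters

    # ancestral frequencies are shared within an LD block (small jitter) so
    # that block members can reach the high r^2 the copying process targets
    n_blocks = int(np.ceil(m / config.ld_block_len))
    block_of = np.arange(m) // config.ld_block_len
    block_anc = rng.uniform(0.15, 0.85, size=n_blocks)
    for idx, _orr, maf in config.causal_loci:
        block_anc[block_of[idx]] = maf
    ancestral = np.clip(block_anc[block_of] + rng.normal(0, 0.02, size=m), 0.05, 0.95)
    for idx, _orr, maf in config.causal_loci:
        ancestral[idx] = maf
    cluster_freqs = _balding_nichols_freqs(rng, ancestral, config.fst, k)
    for idx, _orr, _maf in config.causal_loci:
        col = cluster_freqs[:, idx]
        if np.all((col <= 0) | (col >= 1)) or col.max() <= 0 or col.min() >= 1:
            raise ValueError(f"causal locus {idx} monomorphic in every cluster after drift")

    cluster = rng.integers(0, k, size=n)

    # haplotype copying along blocks: exact HWE within cluster (two
    # independent haplotypes per dog), adjacent-SNP allelic r ~ ld_rho
    calls = np.empty((n, m), dtype=np.int8)
    blocks = [
        np.arange(s, min(s + config.ld_block_len, m)) for s in range(0, m, config.ld_block_len)
    ]
    rho = config.ld_rho
    for c in range(k):
        members = np.flatnonzero(cluster == c)
        if members.size == 0:
            continue
        freqs = cluster_freqs[c]
        hap_sum = np.zeros((members.size, m), dtype=np.int8)
        for _copy in range(2):
            hap = np.empty((members.size, m), dtype=np.int8)
            for block in blocks:
                hap[:, block[0]] = rng.random(members.size) < freqs[block[0]]
                for t in range(1, block.size):
                    copy = rng.random(members.size) < rho
                    fresh = rng.random(members.size) < freqs[block[t]]
                    hap[:, block[t]] = np.where(copy, hap[:, block[t - 1]], fresh)
            hap_sum += hap
        calls[members] = hap_sum

    # logistic liability with per-cluster intercepts
    logit = np.zeros(n)
    for idx, orr, _maf in config.causal_loci:
        logit += np.log(orr) * calls[:, idx]
    if k > 1:
        intercepts = np.linspace(
            -config.cluster_intercept_spread / 2, config.cluster_intercept_spread / 2, k
        )
        logit += intercepts[cluster]

    def prevalence(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(logit + b0)))))

    b0 = optimize.brentq(lambda b: prevalence(b) - config.case_fraction, -20, 20)
    p_disease = 1.0 / (1.0 + np.exp(-(logit + b0)))
    disease = (rng.random(n) < p_disease).astype(int)

    # hip-score pairs that classify back to the intended class
    left = np.empty(n, dtype="U1")
    right = np.empty(n, dtype="U1")
    for i in range(n):
        if disease[i] == 0:
            left[i], right[i] = "A", "A"
        elif rng.random() < config.mild_fraction:
            left[i], right[i] = "C", "C"
        elif rng.random() < config.strict_fraction:
            left[i], right[i] = STRICT_PAIRS[rng.integers(len(STRICT_PAIRS))]
        else:
            pair = MODERATE_SEVERE_PAIRS[rng.integers(2)]  # C/D or D/C
            left[i], right[i] = pair
    b_dogs = rng.random(n) < config.b_score_rate
    for i in np.flatnonzero(b_dogs):
        if rng.random() < 0.5:
            left[i] = "B"
        else:
            right[i] = "B"

    realized = {idx: _allelic_or(calls[:, idx], disease) for idx, _o, _m in config.causal_loci}

    # orient allele_b as the minor allele (matching the PED reader convention)
    freq_b = calls.astype(float).mean(axis=0) / 2
    flip = freq_b > 0.5
    calls[:, flip] = 2 - calls[:, flip]

    # missingness, applied last so realized ORs above describe the clean data
    if config.missing_rate > 0:
        calls[rng.random((n, m)) < config.missing_rate] = MISSING

    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chrom = (np.arange(m) // per_chrom + 1).astype(str)
    pos = (np.arange(m) % per_chrom + 1) * config.snp_spacing
    ref = np.where(flip, "G", "A")
    alt = np.where(flip, "A", "G")
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "allele_a": ref,
            "allele_b": alt,
        }
    )
    samples = [f"dog{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(samples=samples, snps=snps, calls=calls)

    cohort = pd.DataFrame(
        {
            "dog_id": samples,
            "sex": rng.choice(["1", "2"], size=n),
            "batch": (np.arange(n) % config.batch_count + 1).astype(str),
            "hip_left": left,
            "hip_right": right,
        }
    )
    truth = SimTruth(
        cluster_of_dog=cluster,
        haplotype_frequencies={
            bi: cluster_freqs[:, block] for bi, block in enumerate(blocks)
        },
        realized_or=realized,
        disease=disease,
        causal_flipped={idx: bool(flip[idx]) for idx, _o, _m in config.causal_loci},
        seed=config.seed,
    )
    return gm, cohort, truth


# ---------------------------------------------------------------------------
# Deletion locus correlated with a tag SNP
# ---------------------------------------------------------------------------


def _discrete_spearman(p_joint: np.ndarray) -> float:
    """Population Spearman correlation of two discrete ordinal variables.

    Computed as the Pearson correlation of mid-distribution values
    F(x-) + P(x)/2, which is what the sample midrank coefficient converges to.
    """
    px = p_joint.sum(axis=1)
    py = p_joint.sum(axis=0)
    ux = np.concatenate([[0], np.cumsum(px)])[:-1] + px / 2
    uy = np.concatenate([[0], np.cumsum(py)])[:-1] + py / 2
    mx = ux @ px
    my = uy @ py
    cov = ((ux[:, None] - mx) * (uy[None, :] - my) * p_joint).sum()
    vx = ((ux - mx) ** 2 * px).sum()
    vy = ((uy - my) ** 2 * py).sum()
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def _copula_cells(rho: float, xcuts: np.ndarray, ycuts: np.ndarray) -> np.ndarray:
    """Joint cell probabilities of a discretized bivariate normal."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    bvn = stats.multivariate_normal(mean=[0, 0], cov=cov, allow_singular=True)
    xq = np.concatenate([[-np.inf], stats.norm.ppf(xcuts), [np.inf]])
    yq = np.concatenate([[-np.inf], stats.norm.ppf(ycuts), [np.inf]])
    cdf = np.empty((xq.size, yq.size))
    for i, xv in enumerate(xq):
        for j, yv in enumerate(yq):
            if np.isinf(xv) and xv < 0 or np.isinf(yv) and yv < 0:
                cdf[i, j] = 0.0
            elif np.isinf(xv) and np.isinf(yv):
                cdf[i, j] = 1.0
            elif np.isinf(xv):
                cdf[i, j] = stats.norm.cdf(yv)
            elif np.isinf(yv):
                cdf[i, j] = stats.norm.cdf(xv)
            else:
                cdf[i, j] = bvn.cdf([xv, yv])
    cells = np.diff(np.diff(cdf, axis=0), axis=1)
    return np.clip(cells, 0, None)


def simulate_deletion_locus(
    tag_genotypes: np.ndarray,
    target_rho: float,
    seed: int,
    freqs: tuple[float, float, float] = (0.43, 0.44, 0.13),
) -> np.ndarray:
    """Draw 0/1/2 deletion genotypes rank-correlated with tag SNP genotypes.

    A Gaussian copula couples the tag genotype (through its empirical
    distribution) to a latent normal that is discretized at ``freqs``
    (defaulting to the emulated no-deletion / one-allele / two-allele
    frequencies).  The latent correlation is calibrated so the population
    Spearman coefficient of the two discrete variables equals ``target_rho``;
    the sample coefficient then converges to it as n grows.
    """
    if not np.isfinite(target_rho) or abs(target_rho) > 1:
        raise ValueError("target_rho must be finite and within [-1, 1]")
    tag = np.asarray(tag_genotypes)
    if not np.isin(tag[tag != MISSING], [0, 1, 2]).all():
        raise ValueError("tag genotypes must be coded 0/1/2")
    rng = np.random.default_rng(seed)
    n = tag.size

    if abs(target_rho) == 1.0:
        out = tag.copy().astype(np.int8)
        if target_rho < 0:
            out[tag != MISSING] = 2 - out[tag != MISSING]
        out[tag == MISSING] = rng.choice(3, size=(tag == MISSING).sum(), p=freqs)
        return out

    obs = tag != MISSING
    levels, counts = np.unique(tag[obs], return_counts=True)
    px = counts / counts.sum()
    xcuts = np.cumsum(px)[:-1]
    ycuts = np.cumsum(np.asarray(freqs))[:-1]

    def achieved(rho_z: float) -> float:
        return _discrete_spearman(_copula_cells(rho_z, xcuts, ycuts))

    lo, hi = -0.999999, 0.999999
    if not (achieved(lo) <= target_rho <= achieved(hi)):
        raise ValueError(
            f"target_rho {target_rho} unattainable for these margins "
            f"(range [{achieved(lo):.3f}, {achieved(hi):.3f}])"
        )
    rho_z = optimize.brentq(lambda r: achieved(r) - target_rho, lo, hi, xtol=1e-6)

    # conditional draw: z1 truncated to the tag's category, z2 = rho z1 + noise
    level_of = {g: i for i, g in enumerate(levels)}
    edges = np.concatenate([[0.0], np.cumsum(px)])
    z1 = np.empty(n)
    cat = np.array([level_of.get(g, -1) for g in tag])
    u = rng.random(n)
    for i in range(n):
        c = cat[i] if cat[i] >= 0 else rng.integers(len(levels))
        z1[i] = stats.norm.ppf(edges[c] + u[i] * (edges[c + 1] - edges[c]))
    z2 = rho_z * z1 + np.sqrt(1 - rho_z**2) * rng.standard_normal(n)
    ycum = np.concatenate([[0.0], np.cumsum(np.asarray(freqs))])
    ycum[-1] = 1.0
    return np.digitize(stats.norm.cdf(z2), ycum[1:-1]).astype(np.int8)


VARIANT_EFFECT_WEIGHTS = {
    "intergenic": 0.40,
    "intronic": 0.38,
    "synonymous": 0.05,
    "nonsynonymous": 0.04,
    "upstream": 0.04,
    "downstream": 0.04,
    "UTR3": 0.02,
    "splicing": 0.01,
    "exonic_splicing": 0.01,
    "ncRNA_exonic": 0.01,
}


def make_variant_table(
    n_variants: int = 3000,
    n_cases: int = 24,
    n_controls: int = 24,
    segregating_rate: float = 0.02,
    region: tuple[int, int] = (30_620_001, 37_620_000),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic annotated variant table for the segregation screen.

    Emulates a targeted-resequencing variant catalogue from a case-control
    design in which the sequenced dogs were picked by opposing homozygous tag
    genotypes: most variants carry a shared population frequency in both
    groups, while a small fraction (``segregating_rate``) rides the selected
    haplotypes and so appears in nearly all of one group and almost none of
    the other (risk- or protective-oriented with equal probability).
    """
    rng = np.random.default_rng(seed)
    effects = np.array(list(VARIANT_EFFECT_WEIGHTS))
    weights = np.array(list(VARIANT_EFFECT_WEIGHTS.values()))
    weights = weights / weights.sum()
    eff = rng.choice(effects, size=n_variants, p=weights)
    pos = np.sort(rng.integers(region[0], region[1], size=n_variants))
    genes = np.array([f"GENE{g:03d}" for g in pos // 200_000])
    base = rng.uniform(0.0, 1.0, size=n_variants)
    seg = rng.random(n_variants) < segregating_rate
    protective = rng.random(n_variants) < 0.5
    p_case = np.where(seg, np.where(protective, 0.01, 0.97), base)
    p_ctrl = np.where(seg, np.where(protective, 0.97, 0.01), base)
    nts = np.array(["A", "C", "G", "T"])
    ref = rng.choice(nts, size=n_variants)
    alt = nts[(np.searchsorted(nts, ref) + rng.integers(1, 4, n_variants)) % 4]
    return pd.DataFrame(
        {
            "chrom": "9",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene": genes,
            "effect_class": eff,
            "case_carriers": rng.binomial(n_cases, p_case),
            "control_carriers": rng.binomial(n_controls, p_ctrl),
        }
    )


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------


def make_fragment_table(
    gm: GenotypeMatrix,
    cohort: pd.DataFrame,
    tag_snp: str,
    second_snp: str,
    target_rho: float = 0.65,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-dog deletion + two-SNP genotype table tied to a tag SNP."""
    j1 = gm.snp_index(tag_snp)
    j2 = gm.snp_index(second_snp)
    deletion = simulate_deletion_locus(gm.calls[:, j1], target_rho, seed)
    return pd.DataFrame(
        {
            "dog_id": gm.samples,
            "deletion_alleles": deletion,
            "snp1_genotype": gm.calls[:, j1],
            "snp2_genotype": gm.calls[:, j2],
        }
    )


def write_fixtures(
    gm: GenotypeMatrix,
    cohort: pd.DataFrame,
    out_dir,
    fragment: pd.DataFrame | None = None,
    overwrite: bool = False,
) -> dict:
    """Write PED/MAP + cohort TSV (+ fragment TSV); returns a file manifest."""
    from pathlib import Path

    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = {"genotypes.ped", "genotypes.map", "cohort.tsv"}
    if fragment is not None:
        targets.add("fragment.tsv")
    existing = [t for t in targets if (out / t).exists()]
    if existing and not overwrite:
        raise FileExistsError(f"refusing to overwrite {existing} (pass overwrite=True)")
    write_ped_map(gm, out / "genotypes.ped", out / "genotypes.map", cohort=cohort)
    write_cohort(cohort, out / "cohort.tsv")
    if fragment is not None:
        fragment.to_csv(out / "fragment.tsv", sep="\t", index=False)
    return {name: (out / name).stat().st_size for name in sorted(targets)}
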