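"""Readers, writers and phenotype classification for the pipeline's text formats.

Genotypes travel as PED/MAP text (one dog per PED line: six metadata columns
followed by two allele columns per SNP; the MAP file carries chromosome, SNP id
and 1-based base-pair position).  Internally genotypes are an integer matrix
counting copies of ``allele_b`` (0/1/2) with a dedicated missing sentinel.
Coordinates are 1-based inclusive throughout; array indexing is 0-based and the
conversion is confined to this module.

Hip phenotypes are pairs of categorical FCI grades (A normal .. E severe), one
per hip.  A dog is a control when both hips score A, a mild case at C/C, a
moderate-to-severe case when both hips are dysplastic and at least one is D or
worse, and excluded when any hip scores B (borderline) or when only one hip is
dysplastic (ambiguous).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-9)
"""Sentinel for a missing genotype call (never used arithmetically)."""

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}

#: Closed vocabulary of functional-effect classes for annotated variants.
EFFECT_CLASSES = frozenset(
    {
        "downstream",
        "nonsynonymous",
        "exonic_splicing",
        "ncRNA_exonic",
        "ncRNA_intronic",
        "splicing",
        "upstream",
        "UTR3",
        "UTR5",
        "intergenic",
        "intronic",
        "synonymous",
        "stopgain",
        "stoploss",
        "frameshift",
    }
)

HIP_GRADES = ("A", "B", "C", "D", "E")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype calls with an attached SNP map.

    ``calls[i, j]`` counts copies of ``allele_b`` of SNP ``j`` carried by
    sample ``i``; ``MISSING`` marks a failed call.  ``snps`` is a DataFrame
    with columns ``snp_id, chrom, pos, allele_a, allele_b`` (pos 1-based).
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        valid = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not valid.all():
            raise ValueError("genotype codes must be 0/1/2 or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def call_rate_samples(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask().mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_snps)
        return 1.0 - self.missing_mask().mean(axis=0)

    def allele_b_freq(self) -> np.ndarray:
        """Frequency of allele_b per SNP among non-missing calls (NaN if none)."""
        obs = ~self.missing_mask()
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs, self.calls, 0).sum(axis=0) / np.where(n > 0, 2 * n, np.nan)

    def maf(self) -> np.ndarray:
        f = self.allele_b_freq()
        return np.minimum(f, 1.0 - f)

    def dosage(self, impute: bool = False) -> np.ndarray:
        """Calls as float with missing as NaN, optionally mean-imputed per SNP."""
        g = self.calls.astype(float)
        g[self.missing_mask()] = np.nan
        if impute:
            col_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(g))
            g[idx] = col_mean[idx[1]]
        return g

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in sample_idx],
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
            calls=self.calls[np.ix_(sample_idx, snp_idx)],
        )

    def snp_index(self, snp_id: str) -> int:
        loc = np.flatnonzero((self.snps["snp_id"] == snp_id).to_numpy())
        if loc.size == 0:
            raise KeyError(snp_id)
        return int(loc[0])


def _minor_allele_pair(a1: np.ndarray, a2: np.ndarray) -> tuple[str, str]:
    """Return (allele_a, allele_b) with allele_b the minor allele.

    Ties are broken lexicographically (the later letter becomes allele_b) so
    that the orientation is deterministic and write/read round-trips.
    """
    alleles, counts = np.unique(np.concatenate([a1, a2]), return_counts=True)
    tally = {al: int(c) for al, c in zip(alleles, counts) if al != "0"}
    if not tally:
        return "0", "0"
    if len(tally) == 1:
        (only,) = tally
        return only, "0"
    (a, ca), (b, cb) = sorted(tally.items())
    if ca == cb:
        return a, b  # lexicographically later letter is allele_b
    return (a, b) if ca > cb else (b, a)


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a PED/MAP pair into a :class:`GenotypeMatrix`.

    "0 0" allele pairs become missing.  ``allele_b`` (the counted allele) is
    the minor allele in the file, with deterministic lexicographic
    tie-breaking.  Sample order is preserved.
    """
    snp_map = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str, "pos": np.int64},
    )
    m = len(snp_map)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns, got {len(parts)}"
                )
            samples.append(parts[1])
            alleles = np.array(parts[6:], dtype="U1")
            bad = set(alleles) - VALID_ALLELES - {"0"}
            if bad:
                raise FormatError(f"{ped_path}:{lineno}: invalid allele symbol(s) {sorted(bad)}")
            rows.append(alleles)
    if rows:
        allele_arr = np.stack(rows)  # (n, 2m)
        a1, a2 = allele_arr[:, 0::2], allele_arr[:, 1::2]
    else:
        a1 = a2 = np.empty((0, m), dtype="U1")

    allele_a = np.empty(m, dtype="U1")
    allele_b = np.empty(m, dtype="U1")
    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    for j in range(m):
        aa, ab = _minor_allele_pair(a1[:, j], a2[:, j])
        allele_a[j], allele_b[j] = aa, ab
        obs = (a1[:, j] != "0") & (a2[:, j] != "0")
        calls[obs, j] = (a1[obs, j] == ab).astype(np.int8) + (a2[obs, j] == ab).astype(np.int8)

    snps = pd.DataFrame(
        {
            "snp_id": snp_map["snp_id"],
            "chrom": snp_map["chrom"],
            "pos": snp_map["pos"],
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path, cohort: pd.DataFrame | None = None) -> None:
    """Write PED/MAP; inverse of :func:`read_ped_map`.

    Missing calls are written as "0 0".  If a cohort table is given its sex
    and derived case/control status populate PED columns 5-6.
    """
    snps = gm.snps
    with open(map_path, "w") as fh:
        for row in snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")
    meta = {}
    if cohort is not None:
        cohort = cohort.set_index("dog_id")
        for dog in gm.samples:
            if dog in cohort.index:
                rec = cohort.loc[dog]
                cls = classify_phenotype(rec["hip_left"], rec["hip_right"])
                pheno = {PhenotypeClass.CONTROL: "1"}.get(cls, "2" if cls.is_case else "0")
                meta[dog] = (str(rec.get("sex", 0)), pheno)
    a = snps["allele_a"].to_numpy()
    b = snps["allele_b"].to_numpy()
    code_pairs = np.empty((3, len(snps)), dtype=object)
    code_pairs[0] = [f"{x} {x}" for x in a]
    code_pairs[1] = [f"{x} {y}" for x, y in zip(a, b)]
    code_pairs[2] = [f"{y} {y}" for y in b]
    with open(ped_path, "w") as fh:
        for i, dog in enumerate(gm.samples):
            sex, pheno = meta.get(dog, ("0", "0"))
            fields = [dog, dog, "0", "0", sex, pheno]
            row = gm.calls[i]
            fields.extend(
                "0 0" if g == MISSING else code_pairs[g][j] for j, g in enumerate(row)
            )
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Phenotype classification
# ---------------------------------------------------------------------------


class PhenotypeClass(enum.Enum):
    CONTROL = "control"
    MILD = "mild"
    MODERATE_SEVERE = "moderate_severe"
    EXCLUDED_B = "excluded_B"
    EXCLUDED_AMBIGUOUS = "excluded_ambiguous"

    @property
    def is_case(self) -> bool:
        return self in (PhenotypeClass.MILD, PhenotypeClass.MODERATE_SEVERE)


def classify_phenotype(left: str, right: str) -> PhenotypeClass:
    """Deterministically classify a hip-score pair.

    A/A -> control; any B -> excluded (confounded borderline phenotype);
    C/C -> mild case; both hips dysplastic with at least one D or worse ->
    moderate-to-severe case; one normal and one dysplastic hip -> excluded
    as ambiguous.
    """
    for g in (left, right):
        if g not in HIP_GRADES:
            raise ValueError(f"unknown hip grade {g!r}")
    if "B" in (left, right):
        return PhenotypeClass.EXCLUDED_B
    if left == "A" and right == "A":
        return PhenotypeClass.CONTROL
    if "A" in (left, right):
        return PhenotypeClass.EXCLUDED_AMBIGUOUS
    if left == "C" and right == "C":
        return PhenotypeClass.MILD
    return PhenotypeClass.MODERATE_SEVERE


def is_strict_case(left: str, right: str) -> bool:
    """True when both hips score D or worse (the stringent case definition)."""
    return classify_phenotype(left, right) is PhenotypeClass.MODERATE_SEVERE and (
        left in ("D", "E") and right in ("D", "E")
    )


CASE_DEFINITIONS = ("strict", "moderate_severe", "relaxed")


def case_control_status(left: str, right: str, definition: str = "relaxed") -> float:
    """1.0 for a case under the given definition, 0.0 for a control, NaN otherwise.

    Definitions are nested: strict (both hips D or worse) c moderate_severe
    (C/D, D/C or worse) c relaxed (C/C or worse).
    """
    if definition not in CASE_DEFINITIONS:
        raise ValueError(f"unknown case definition {definition!r}")
    cls = classify_phenotype(left, right)
    if cls is PhenotypeClass.CONTROL:
        return 0.0
    if definition == "relaxed" and cls.is_case:
        return 1.0
    if definition == "moderate_severe" and cls is PhenotypeClass.MODERATE_SEVERE:
        return 1.0
    if definition == "strict" and is_strict_case(left, right):
        return 1.0
    return float("nan")


def add_phenotype_classes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the cohort with a ``phenotype`` column of class names."""
    out = cohort.copy()
    out["phenotype"] = [
        classify_phenotype(l, r).value for l, r in zip(out["hip_left"], out["hip_right"])
    ]
    return out


# ---------------------------------------------------------------------------
# Tabular readers/writers
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["dog_id", "sex", "batch", "hip_left", "hip_right"]


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"dog_id": str, "sex": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    if df["dog_id"].duplicated().any():
        raise FormatError("duplicate dog_id in cohort table")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect_class",
    "case_carriers",
    "control_carriers",
]


def read_variant_table(path, n_cases: int | None = None, n_controls: int | None = None) -> pd.DataFrame:
    """Read an annotated variant table (segregation-screen input).

    Validates the functional-effect vocabulary and, when group sizes are
    given, that carrier counts do not exceed them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str, "effect_class": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table missing columns {missing}")
    bad = df.loc[~df["effect_class"].isin(EFFECT_CLASSES)]
    if len(bad):
        rows = ", ".join(f"row {i}: {e!r}" for i, e in bad["effect_class"].head(5).items())
        raise FormatError(f"unknown effect class ({rows})")
    for col, limit in (("case_carriers", n_cases), ("control_carriers", n_controls)):
        if (df[col] < 0).any():
            raise FormatError(f"negative {col}")
        if limit is not None and (df[col] > limit).any():
            raise FormatError(f"{col} exceeds group size {limit}")
    return df


FRAGMENT_COLUMNS = ["dog_id", "deletion_alleles", "snp1_genotype", "snp2_genotype"]


def read_fragment_table(path) -> pd.DataFrame:
    """Read per-dog deletion (0/1/2 deleted alleles) + tag-SNP genotypes."""
    df = pd.read_csv(path, sep="\t", dtype={"dog_id": str})
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"fragment table missing columns {missing}")
    if df["dog_id"].duplicated().any():
        raise FormatError("duplicate dog_id in fragment table")
    if not df["deletion_alleles"].isin([0, 1, 2]).all():
        raise FormatError("deletion_alleles must be 0, 1 or 2")
    return df
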