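"""Population structure: genomic relationships, classical MDS, and
BIC-selected Gaussian-mixture clustering used as an association covariate.

The genomic relationship matrix (GRM) averages allele-frequency-standardized
genotype products over SNPs.  Classical multidimensional scaling of the
GRM-induced distance d_ij = sqrt(k_ii + k_jj - 2 k_ij) gives the familiar
cluster plot; a Gaussian mixture fitted on the leading MDS axes with the
number of components selected by BIC supplies a data-driven subpopulation
label per dog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .io_formats import GenotypeMatrix

log = logging.getLogger(__name__)


def compute_grm(gm: GenotypeMatrix) -> np.ndarray:
    """Average over SNPs of (g_i - 2p)(g_j - 2p) / (2p(1-p)).

    Missing calls are mean-imputed per SNP for this computation only (they
    then contribute zero to the standardized product).  Monomorphic and
    all-missing SNPs are excluded.
    """
    if gm.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    g = gm.dosage(impute=True)
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    g = g[:, poly]
    p = p[poly]
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (z @ z.T) / z.shape[1]


def mds_coordinates(kinship: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling of d_ij = sqrt(k_ii + k_jj - 2 k_ij).

    The double-centered squared-distance matrix equals the centered kinship,
    so coordinates are eigenvectors of J K J scaled by sqrt(eigenvalue).
    Coordinates are column-centered; dimensions beyond the rank are zero.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    k = np.asarray(kinship, dtype=float)
    n = k.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ k @ j  # == -1/2 J D^2 J for the kinship-induced distance
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    dims = min(dims, n)
    coords = vecs[:, :dims] * np.sqrt(vals[:dims])
    return coords - coords.mean(axis=0)


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    bic_by_k: dict


def assign_clusters(
    kinship: np.ndarray,
    k_max: int = 8,
    n_axes: int = 2,
    seed: int = 0,
) -> ClusterAssignment:
    """Gaussian-mixture clustering on the top MDS axes, k chosen by BIC.

    Mirrors model-based clustering with BIC model selection; the number of
    components spans 1..k_max (lowered with a warning when n < k_max).
    Deterministic given ``seed``.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n = kinship.shape[0]
    if n < k_max:
        log.warning("k_max %d > n %d; lowering", k_max, n)
        k_max = n
    coords = mds_coordinates(kinship, dims=n_axes)
    # degenerate axes (zero variance) upset the mixture fit; jitter-free drop
    keep = coords.std(axis=0) > 1e-12
    x = coords[:, keep] if keep.any() else coords[:, :1]

    bic_by_k: dict[int, float] = {}
    best = None
    for k in range(1, k_max + 1):
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=3,
            random_state=seed,
            reg_covar=1e-9,
        ).fit(x)
        bic = gmm.bic(x)
        bic_by_k[k] = float(bic)
        if best is None or bic < best[0]:
            best = (bic, k, gmm)
    _, k, gmm = best
    return ClusterAssignment(labels=gmm.predict(x), k=k, bic_by_k=bic_by_k)


def cluster_covariates(labels: np.ndarray) -> np.ndarray:
    """Dummy-encode cluster labels (first level as reference)."""
    levels = np.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) if len(levels) > 1 else np.empty((len(labels), 0))
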