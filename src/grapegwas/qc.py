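"""Genotype quality control and population-structure diagnostics.

Filtering mirrors standard GBS post-processing: samples below a 50% call
rate are removed first, then SNPs with minor-allele frequency strictly
below 5% (recomputed on the retained samples).  Downstream structure tools:
mean-dosage imputation, PCA on centered unscaled dosages, the VanRaden
genomic relationship matrix, K-means/agglomerative cluster comparison, and
LD decay (composite dosage r-squared versus physical distance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import adjusted_rand_score

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "qc_filter",
    "impute_mean",
    "run_pca",
    "vanraden_kinship",
    "cluster_accessions",
    "ld_decay",
    "PCAResult",
    "ClusterResult",
]


def qc_filter(
    G: GenotypeMatrix, maf_min: float = 0.05, call_rate_min: float = 0.5
) -> GenotypeMatrix:
    """Remove low-call-rate samples, then SNPs with MAF < ``maf_min``.

    Both thresholds are strict (``<``), so a SNP at exactly 5% MAF or a
    sample at exactly 50% call rate is retained.  MAF is computed from
    non-missing dosages of the retained samples; SNPs with no calls at all
    are removed.  The removal funnel is logged and recorded in ``meta``.
    """
    keep_acc = G.sample_call_rate() >= call_rate_min
    if not keep_acc.any():
        raise ValueError("all samples removed by call-rate filter")
    G1 = G.subset(accessions=keep_acc)
    maf = G1.maf()
    keep_snp = ~np.isnan(maf) & (maf >= maf_min)
    if not keep_snp.any():
        raise ValueError("all SNPs removed by MAF filter")
    out = G1.subset(snps=keep_snp)
    report = {
        "samples_in": G.n_accessions,
        "samples_removed": int((~keep_acc).sum()),
        "snps_in": G.n_snps,
        "snps_removed": int((~keep_snp).sum()),
        "maf_min": maf_min,
        "call_rate_min": call_rate_min,
    }
    logger.info(
        "qc_filter: removed %d/%d samples (call rate < %g) and %d/%d SNPs (MAF < %g)",
        report["samples_removed"], report["samples_in"], call_rate_min,
        report["snps_removed"], report["snps_in"], maf_min,
    )
    out.meta["qc"] = report
    return out


def impute_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the SNP's rounded mean dosage."""
    dos = G.dosages.copy()
    missing = np.isnan(dos)
    if missing.all(axis=0).any():
        raise ValueError("cannot impute a SNP with no observed calls")
    if missing.any():
        fill = np.clip(np.round(np.nanmean(dos, axis=0)), 0, 2)
        r, c = np.where(missing)
        dos[r, c] = fill[c]
    out = G.subset()
    out.dosages = dos
    out.meta["imputed"] = int(missing.sum())
    return out


@dataclass
class PCAResult:
    """Principal components of the centered (unscaled) dosage matrix."""

    scores: np.ndarray  # accessions x components
    explained_fraction: np.ndarray  # proportion of total variance, 0..1
    loadings: np.ndarray  # SNPs x components


def run_pca(G: GenotypeMatrix, n_components: int = 6) -> PCAResult:
    """PCA of column-centered dosages; deterministic sign convention.

    The variance explained by each component is its eigenvalue divided by
    the total variance of all columns.  The sign of each component is fixed
    by forcing its largest-magnitude SNP loading positive.  When
    ``n_components`` exceeds the matrix rank the result is truncated with a
    warning.
    """
    X = np.asarray(G.dosages, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("run_pca requires a complete (imputed) matrix")
    X = X - X.mean(axis=0)
    n, p = X.shape
    # eigendecompose the small Gram matrix (n << p in GBS panels)
    gram = X @ X.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    tol = evals[0] * max(n, p) * np.finfo(float).eps if evals.size else 0.0
    rank = int((evals > tol).sum())
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds matrix rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    k = n_components
    sing = np.sqrt(evals[:k])
    scores = evecs[:, :k] * sing
    with np.errstate(divide="ignore", invalid="ignore"):
        loadings = X.T @ evecs[:, :k] / np.where(sing > 0, sing, 1.0)
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    total = evals.sum()
    frac = evals[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(scores=scores, explained_fraction=frac, loadings=loadings)


def vanraden_kinship(G: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix K = ZZ'/(2 sum p(1-p)).

    Z is the dosage matrix centered by twice the observed allele frequency.
    Monomorphic SNPs contribute nothing; an all-monomorphic matrix is an
    error.
    """
    X = np.asarray(G.dosages, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("vanraden_kinship requires a complete matrix")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic SNPs")
    Z = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return Z @ Z.T / denom


@dataclass
class ClusterResult:
    kmeans_labels: np.ndarray
    hclust_labels: np.ndarray
    agreement_ari: float  # adjusted Rand index between the two methods
    k: int
    seed: int


def cluster_accessions(pca: PCAResult, K: int = 9, seed: int = 0, n_init: int = 10) -> ClusterResult:
    """K-means and average-linkage agglomerative clustering on PC scores."""
    n = pca.scores.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of accessions {n}")
    km = KMeans(n_clusters=K, random_state=seed, n_init=n_init).fit(pca.scores)
    logger.info("cluster_accessions: K-means with K=%d, %d restarts, seed=%d", K, n_init, seed)
    if K == 1:
        hc_labels = np.zeros(n, dtype=int)
    else:
        hc = AgglomerativeClustering(n_clusters=K, linkage="average").fit(pca.scores)
        hc_labels = hc.labels_
    ari = float(adjusted_rand_score(km.labels_, hc_labels)) if K > 1 else 1.0
    return ClusterResult(
        kmeans_labels=km.labels_, hclust_labels=hc_labels,
        agreement_ari=ari, k=K, seed=seed,
    )


def ld_decay(
    G: GenotypeMatrix,
    max_dist: int = 500_000,
    r2_threshold: float = 0.2,
    bin_width: int = 5_000,
) -> pd.DataFrame:
    """Mean pairwise dosage r-squared in physical-distance bins.

    All intra-chromosome SNP pairs within ``max_dist`` bp contribute.  The
    returned frame has columns ``bin_start, bin_end, mid, mean_r2, n_pairs``
    and carries the estimated decay distance (midpoint of the first
    populated bin whose mean r2 drops below ``r2_threshold``) in
    ``attrs['crossing_distance']`` (NaN if never crossed).
    """
    X = np.asarray(G.dosages, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("ld_decay requires a complete matrix")
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    usable = False
    for chrom in np.unique(G.chroms):
        idx = np.flatnonzero(G.chroms == chrom)
        if idx.size < 2:
            continue
        sub = X[:, idx]
        sd = sub.std(axis=0)
        keep = sd > 0
        if keep.sum() < 2:
            continue
        usable = True
        sub = sub[:, keep]
        pos = G.positions[idx][keep]
        r = np.corrcoef(sub, rowvar=False)
        iu, ju = np.triu_indices(pos.size, k=1)
        dist = pos[ju] - pos[iu]
        within = dist <= max_dist
        r2 = r[iu[within], ju[within]] ** 2
        b = np.minimum((dist[within] - 1) // bin_width, n_bins - 1).astype(np.int64)
        sums += np.bincount(b, weights=r2, minlength=n_bins)
        counts += np.bincount(b, minlength=n_bins)
    if not usable:
        raise ValueError("need at least two polymorphic SNPs on some chromosome")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    starts = np.arange(n_bins) * bin_width + 1
    table = pd.DataFrame(
        {
            "bin_start": starts,
            "bin_end": starts + bin_width - 1,
            "mid": starts + bin_width // 2 - 1,
            "mean_r2": means,
            "n_pairs": counts,
        }
    )
    crossing = np.nan
    populated = table[table["n_pairs"] > 0]
    below = populated[populated["mean_r2"] < r2_threshold]
    if not below.empty:
        crossing = float(below["mid"].iloc[0])
    table.attrs["crossing_distance"] = crossing
    table.attrs["r2_threshold"] = r2_threshold
    return table
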