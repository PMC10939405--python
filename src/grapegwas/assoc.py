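"""PC-corrected single-marker association scan.

A deliberately transparent stand-in for multi-locus GWAS model-search
methods (BLINK and relatives): for each SNP, the trait BLUE is regressed on
an intercept, the first ``n_pcs`` principal-component scores and the SNP
dosage; the two-sided t-test p-value of the dosage coefficient is reported
as a LOD score (-log10 p) together with Bonferroni and Benjamini-Hochberg
FDR threshold flags.  By the Frisch-Waugh-Lovell theorem the per-SNP fit is
computed on PC-residualized phenotype and dosages, which makes the scan a
pair of matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix
from .qc import PCAResult

logger = logging.getLogger(__name__)

__all__ = ["scan_trait", "thresholds", "qq_data", "ThresholdSet"]

_P_FLOOR = np.finfo(float).tiny  # underflow guard; LOD capped at ~307.65


@dataclass
class ThresholdSet:
    """Significance thresholds on the LOD scale for one scan."""

    n_tests: int
    alpha: float
    bonferroni_lod: float
    fdr_lod: float  # LOD of the last BH-rejected test; inf if none rejected
    reject_fdr: np.ndarray = None
    reject_bonferroni: np.ndarray = None


def thresholds(pvalues, n_tests: int | None = None, alpha: float = 0.05) -> ThresholdSet:
    """Bonferroni and Benjamini-Hochberg cutoffs expressed as LOD scores."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if n_tests is None:
        n_tests = p.size
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    bonf_lod = -np.log10(alpha / n_tests)
    reject_bh, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")[:4]
    reject_bonf = p < alpha / n_tests
    if reject_bh.any():
        fdr_lod = float(-np.log10(p[reject_bh].max()))
    else:
        fdr_lod = np.inf
    return ThresholdSet(
        n_tests=int(n_tests),
        alpha=alpha,
        bonferroni_lod=float(bonf_lod),
        fdr_lod=fdr_lod,
        reject_fdr=reject_bh,
        reject_bonferroni=reject_bonf,
    )


def scan_trait(
    G: GenotypeMatrix,
    blues: pd.Series,
    trait: str,
    pca: PCAResult,
    n_pcs: int = 6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-marker OLS scan of one trait over all SNPs.

    Parameters
    ----------
    G
        Complete (imputed) genotype matrix.
    blues
        Accession-indexed adjusted phenotype values; accessions are matched
        to ``G.accession_ids`` by intersection.
    pca
        PCA computed on the same matrix ``G`` (rows aligned with it).
    n_pcs
        Number of PC covariates (default six, the usual structure
        correction for a multi-family panel).

    Returns a per-SNP frame with columns ``snp, chrom, pos, trait, p, lod,
    above_fdr, above_bonferroni, degenerate`` and the fitted
    :class:`ThresholdSet` in ``attrs['thresholds']``.
    """
    X = np.asarray(G.dosages, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("scan requires a complete (imputed) matrix")
    mask = np.isin(G.accession_ids, blues.index.to_numpy())
    if not mask.any():
        raise ValueError("no accessions shared between genotypes and BLUEs")
    idx = np.flatnonzero(mask)
    y = blues.loc[G.accession_ids[idx]].to_numpy(dtype=float)
    X = X[idx]
    n = idx.size
    if n_pcs >= n - 2:
        raise ValueError(f"n_pcs={n_pcs} too large for {n} accessions")

    C = np.hstack([np.ones((n, 1)), pca.scores[idx, :n_pcs]])
    Q, _ = np.linalg.qr(C)
    yr = y - Q @ (Q.T @ y)
    Xr = X - Q @ (Q.T @ (X))

    degenerate = np.nanstd(X, axis=0) == 0
    gg = np.einsum("ij,ij->j", Xr, Xr)
    gy = yr @ Xr
    dof = n - C.shape[1] - 1
    ok = (gg > n * np.finfo(float).eps) & ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, gy / np.where(gg > 0, gg, 1.0), 0.0)
        rss = yr @ yr - beta**2 * gg
        rss = np.clip(rss, 0.0, None)
        se2 = rss / dof / np.where(gg > 0, gg, 1.0)
        tstat = np.where(se2 > 0, beta / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(ok, p, 1.0)
    n_floored = int((p < _P_FLOOR).sum())
    if n_floored:
        logger.info("%s: %d p-values floored at %.3g", trait, n_floored, _P_FLOOR)
    p = np.clip(p, _P_FLOOR, 1.0)

    th = thresholds(p, n_tests=p.size, alpha=alpha)
    out = pd.DataFrame(
        {
            "snp": G.snp_ids,
            "chrom": G.chroms,
            "pos": G.positions,
            "trait": trait,
            "p": p,
            "lod": -np.log10(p),
            "above_fdr": th.reject_fdr,
            "above_bonferroni": th.reject_bonferroni,
            "degenerate": degenerate | ~ok,
        }
    )
    out.attrs["thresholds"] = th
    return out


def qq_data(pvalues) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p for a QQ plot.

    Observed p-values are sorted ascending and paired with uniform
    quantiles (i - 0.5)/n, both on the -log10 scale.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.sort(p))
    return expected, observed
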