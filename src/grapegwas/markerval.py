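"""Bootstrapped rank-genotype profiles for marker suitability.

To judge whether a significant SNP is usable for marker-assisted selection,
accessions are repeatedly resampled with replacement (R bootstrap
populations of size S), sorted by phenotype (rank 1 = highest value), and
the dosage observed at each rank is averaged over replicates.  A marker
that tracks the trait yields a monotone mean-dosage-versus-rank profile;
the Spearman correlation rho between rank index and profile summarizes the
trend.  Because the 0/2 homozygote labelling is arbitrary, suitability is
read from |rho|; the signed rho is kept for null experiments, whose mean is
expected to be zero under no association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["rank_genotype_profile", "null_experiment", "RankProfile", "NullSummary"]


@dataclass
class RankProfile:
    """Mean genotypic value per phenotypic rank, averaged over bootstraps."""

    profile: np.ndarray  # length S, dosage units
    R: int
    S: int
    population_mean_dosage: float  # full-panel mean dosage of the SNP
    rho: float  # Spearman correlation of rank 1..S vs profile
    abs_rho: float
    degenerate: bool = False  # constant phenotype or constant profile


def rank_genotype_profile(
    phenotype,
    genotype,
    R: int = 200,
    S: int = 250,
    seed: int = 0,
) -> RankProfile:
    """Bootstrap rank-vs-genotype profile for one SNP and one trait.

    Parameters
    ----------
    phenotype, genotype
        Aligned per-accession trait values and dosages; no missing values.
    R, S
        Number of bootstrap populations and their size.  Sampling is with
        replacement, so S may exceed the panel size (a warning is logged).
    seed
        RNG seed; the procedure is fully reproducible from it.

    Within a bootstrap sample, accessions are ordered by descending
    phenotype; ties (including bootstrap duplicates) are broken by the
    accession's position in the input, which keeps the procedure
    deterministic.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(genotype, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("phenotype and genotype must be aligned 1-D vectors")
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("missing values not allowed; impute first")
    if S < 2:
        raise ValueError("S must be >= 2")
    if R < 1:
        raise ValueError("R must be >= 1")
    n = y.size
    if S > n:
        logger.warning("sample size S=%d exceeds panel size %d (replacement sampling)", S, n)

    rng = np.random.default_rng(seed)
    total = np.zeros(S)
    const_pheno = np.ptp(y) == 0
    for _ in range(R):
        idx = rng.integers(0, n, size=S)
        # descending phenotype, stable on accession index for ties
        order = np.lexsort((idx, -y[idx]))
        total += x[idx[order]]
    profile = total / R

    degenerate = const_pheno or np.ptp(profile) == 0
    if degenerate:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(np.arange(1, S + 1), profile).statistic)
        if np.isnan(rho):
            rho, degenerate = 0.0, True
    return RankProfile(
        profile=profile,
        R=R,
        S=S,
        population_mean_dosage=float(x.mean()),
        rho=rho,
        abs_rho=abs(rho),
        degenerate=degenerate,
    )


@dataclass
class NullSummary:
    """Signed-rho distribution over randomly drawn SNPs."""

    rhos: np.ndarray
    mean: float
    sd: float
    n_snps: int
    degenerate: bool = False  # single-SNP convention: sd reported as 0


def null_experiment(
    phenotype,
    G: GenotypeMatrix,
    n_snps: int = 10,
    R: int = 200,
    S: int = 250,
    seed: int = 0,
) -> NullSummary:
    """Profile statistic for randomly selected SNPs (the reference null).

    Draws ``n_snps`` markers uniformly without replacement and reports the
    signed Spearman rho of each profile, with mean and standard deviation.
    """
    if G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    if n_snps > G.n_snps:
        raise ValueError(f"n_snps={n_snps} exceeds available SNPs {G.n_snps}")
    rng = np.random.default_rng(seed)
    picks = rng.choice(G.n_snps, size=n_snps, replace=False)
    rhos = np.array(
        [
            rank_genotype_profile(
                phenotype, G.dosages[:, j], R=R, S=S, seed=int(rng.integers(2**31))
            ).rho
            for j in picks
        ]
    )
    degenerate = n_snps == 1
    sd = 0.0 if degenerate else float(rhos.std(ddof=1))
    if degenerate:
        logger.warning("null_experiment with a single SNP: sd reported as 0 by convention")
    return NullSummary(
        rhos=rhos, mean=float(rhos.mean()), sd=sd, n_snps=n_snps, degenerate=degenerate
    )
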