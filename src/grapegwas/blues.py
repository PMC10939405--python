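"""Season- and covariate-adjusted genetic values (BLUEs).

For each trait, phenotypic records are fitted with the fixed-effects model

    y = season + covariates + accession + error,   error ~ N(0, sigma^2)

by ordinary least squares.  Season effects use sum-to-zero coding, so the
reported per-accession BLUE is the expected value of that accession in an
average season at covariate value zero; contrasts between accessions are
invariant to this choice.  Trait-specific covariates follow the breeder's
map: berry and harvest traits are corrected for soluble solids and seed dry
weight, post-harvest traits for soluble solids, seed traits for nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "default_covariate_map",
    "fit_blues",
    "fit_all_blues",
    "weight_loss",
    "BlueResult",
    "BlueTable",
]


def default_covariate_map() -> dict[str, list[str]]:
    """Trait -> ordered covariate names used for adjustment."""
    covmap: dict[str, list[str]] = {}
    for t in ("B_height", "B_width", "B_shape", "B_weight", "H_cluster", "H_rachis"):
        covmap[t] = ["soluble_solids", "S_dry"]
    for t in ("P_cluster", "P_cluster_loss", "P_rachis", "P_rachis_loss"):
        covmap[t] = ["soluble_solids"]
    for t in ("S_number", "S_fresh", "S_dry"):
        covmap[t] = []
    return covmap


@dataclass
class BlueResult:
    """Per-trait fit: accession BLUEs plus diagnostics."""

    trait: str
    values: pd.Series  # accession -> adjusted genetic value
    sigma2: float  # residual variance estimate
    n_records: int
    n_dropped: int  # records dropped for missing covariates
    season_effects: pd.Series
    covariate_slopes: pd.Series
    residuals: np.ndarray = field(repr=False, default=None)


@dataclass
class BlueTable:
    """Accession x trait matrix of BLUEs with per-trait diagnostics."""

    values: pd.DataFrame  # index accession, columns traits
    fits: dict[str, BlueResult]


def fit_blues(
    pheno: pd.DataFrame,
    trait: str,
    covmap: dict[str, list[str]] | None = None,
    use_covariates: bool = True,
) -> BlueResult:
    """OLS fit of the season + covariate + accession model for one trait.

    Parameters
    ----------
    pheno
        Long-format phenotype table (columns ``accession, season, trait,
        value`` plus any covariate columns).
    trait
        Trait to fit; must be present in ``pheno['trait']``.
    covmap
        Trait -> covariates; defaults to :func:`default_covariate_map`.
    use_covariates
        If False, covariates are omitted (the "uncorrected BLUEs" variant).
    """
    if covmap is None:
        covmap = default_covariate_map()
    sub = pheno.loc[(pheno["trait"] == trait) & pheno["value"].notna()].copy()
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from phenotype table")

    covariates = list(covmap.get(trait, [])) if use_covariates else []
    for c in covariates:
        if c not in sub.columns:
            raise ValueError(f"covariate {c!r} not found in phenotype table")
    n_before = len(sub)
    if covariates:
        sub = sub.dropna(subset=covariates)
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.info("%s: dropped %d records with missing covariates", trait, n_dropped)

    accessions = pd.Index(sorted(sub["accession"].unique()))
    seasons = sorted(sub["season"].unique())
    if len(accessions) < 2:
        raise ValueError("need records for at least two accessions")

    n = len(sub)
    acc_codes = accessions.get_indexer(sub["accession"])
    X_acc = np.zeros((n, len(accessions)))
    X_acc[np.arange(n), acc_codes] = 1.0

    # sum-to-zero season coding: last season's effect = -sum of the others
    season_cols = []
    for s in seasons[:-1]:
        col = np.where(sub["season"] == s, 1.0, 0.0)
        col[sub["season"] == seasons[-1]] = -1.0
        season_cols.append(col)
    X_season = np.column_stack(season_cols) if season_cols else np.empty((n, 0))
    X_cov = sub[covariates].to_numpy(dtype=float) if covariates else np.empty((n, 0))

    X = np.hstack([X_acc, X_season, X_cov])
    colnames = (
        [f"accession[{a}]" for a in accessions]
        + [f"season[{s}]" for s in seasons[:-1]]
        + covariates
    )

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns the pivoted QR leaves out of the basis
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(colnames[j] for j in piv[rank:])
        raise ValueError(f"design matrix rank-deficient; confounded columns: {bad}")

    y = sub["value"].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0

    k = len(accessions)
    season_eff = pd.Series(beta[k : k + len(seasons) - 1], index=seasons[:-1])
    if seasons[:-1]:
        season_eff[seasons[-1]] = -season_eff.sum()
    slopes = pd.Series(beta[k + len(seasons) - 1 :], index=covariates)
    return BlueResult(
        trait=trait,
        values=pd.Series(beta[:k], index=accessions, name=trait),
        sigma2=sigma2,
        n_records=n,
        n_dropped=n_dropped,
        season_effects=season_eff,
        covariate_slopes=slopes,
        residuals=resid,
    )


def fit_all_blues(
    pheno: pd.DataFrame,
    covmap: dict[str, list[str]] | None = None,
    use_covariates: bool = True,
    traits: list[str] | None = None,
) -> BlueTable:
    """Fit every trait present in the table; returns the accession x trait matrix."""
    if traits is None:
        traits = sorted(pheno["trait"].unique())
    fits = {
        t: fit_blues(pheno, t, covmap=covmap, use_covariates=use_covariates)
        for t in traits
    }
    values = pd.DataFrame({t: r.values for t, r in fits.items()})
    return BlueTable(values=values, fits=fits)


def weight_loss(harvest: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Percent weight loss: (harvest - post) / harvest * 100 (synthetic-data helper)."""
    harvest = np.asarray(harvest, dtype=float)
    post = np.asarray(post, dtype=float)
    return (harvest - post) / harvest * 100.0
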