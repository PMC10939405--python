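"""Shared in-memory containers for the pipeline.

Genotypes live in a :class:`GenotypeMatrix` (accessions x SNPs alt-allele
dosage matrix, entries 0/1/2 with NaN for missing calls).  Phenotypes are a
long-format :class:`pandas.DataFrame` with one row per
(accession, season, trait) and covariate columns alongside; gene models and
GO annotations are plain DataFrames documented in :mod:`grapegwas.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "PHENO_COLUMNS"]

#: required columns of a long-format phenotype table
PHENO_COLUMNS = ("accession", "season", "trait", "value")


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix with marker coordinates.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_accessions, n_snps)``; entries in
        ``{0, 1, 2}`` or NaN for missing calls.
    snp_ids, chroms, positions
        Per-SNP identifier, chromosome name and 1-based bp position.
        Positions must be strictly increasing within each chromosome.
    accession_ids
        Per-accession identifiers.
    group_labels
        Optional family / panel label per accession (e.g. ``jardin`` for the
        diversity panel, ``F1_*`` for crosses).
    meta
        Free-form provenance (QC funnel counts, simulation parameters...).
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    accession_ids: np.ndarray
    group_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D accessions x SNPs array")
        self.snp_ids = np.asarray(self.snp_ids)
        self.chroms = np.asarray(self.chroms)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.accession_ids = np.asarray(self.accession_ids)
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if self.group_labels.shape[0] != self.n_accessions:
                raise ValueError("group_labels length mismatch")
        n_acc, n_snp = self.dosages.shape
        for name, arr in (
            ("snp_ids", self.snp_ids),
            ("chroms", self.chroms),
            ("positions", self.positions),
        ):
            if arr.shape[0] != n_snp:
                raise ValueError(f"{name} length {arr.shape[0]} != n_snps {n_snp}")
        if self.accession_ids.shape[0] != n_acc:
            raise ValueError("accession_ids length mismatch")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")
        for chrom in np.unique(self.chroms):
            pos = self.positions[self.chroms == chrom]
            if pos.size > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic shape/summary helpers -------------------------------------

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP (NaN if no calls)."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per accession."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def subset(
        self,
        accessions: np.ndarray | None = None,
        snps: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given accession / SNP indices or masks."""
        acc = np.arange(self.n_accessions) if accessions is None else np.asarray(accessions)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if acc.dtype == bool:
            acc = np.flatnonzero(acc)
        if snp.dtype == bool:
            snp = np.flatnonzero(snp)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(acc, snp)].copy(),
            snp_ids=self.snp_ids[snp].copy(),
            chroms=self.chroms[snp].copy(),
            positions=self.positions[snp].copy(),
            accession_ids=self.accession_ids[acc].copy(),
            group_labels=None if self.group_labels is None else self.group_labels[acc].copy(),
            meta=dict(self.meta),
        )
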