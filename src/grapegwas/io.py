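"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF (unphased diploid GT), gene models as GFF3
(1-based inclusive, feature type ``gene``), phenotypes as CSV, GO
annotations as TSV and all stage outputs as TSV with a ``#`` header comment
declaring the coordinate convention.  BED exports are 0-based half-open;
everything else is 1-based.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_gff3",
    "write_gff3",
    "read_phenotypes",
    "write_phenotypes",
    "read_go_table",
    "write_go_table",
    "write_bed_windows",
    "read_published_associations",
]


# ---------------------------------------------------------------------------
# VCF

_GT_TO_DOSAGE = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}  # cyvcf2 gt_types codes


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Multiallelic records are dropped (counted in ``meta['multiallelic_dropped']``);
    missing and half-called genotypes become NaN dosages.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    dosage_cols, snp_ids, chroms, positions = [], [], [], []
    n_multi = 0
    for v in vcf:
        if v.ALT is None or len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage_cols.append([_GT_TO_DOSAGE[int(g)] for g in gt])
        snp_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        positions.append(v.POS)
    vcf.close()
    if not dosage_cols:
        raise ValueError(f"no biallelic records found in {path}")
    return GenotypeMatrix(
        dosages=np.array(dosage_cols, dtype=np.float32).T,
        snp_ids=np.array(snp_ids),
        chroms=np.array(chroms),
        positions=np.array(positions, dtype=np.int64),
        accession_ids=samples,
        meta={"multiallelic_dropped": n_multi, "source": str(path)},
    )


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write dosages as an unphased diploid VCF (REF=A, ALT=T placeholders)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=grapegwas\n")
        for chrom in dict.fromkeys(G.chroms.tolist()):
            length = int(G.positions[G.chroms == chrom].max())
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, G.accession_ids))
            + "\n"
        )
        for j in range(G.n_snps):
            calls = [
                "./." if np.isnan(d) else gt_map[float(d)] for d in G.dosages[:, j]
            ]
            fh.write(
                f"{G.chroms[j]}\t{G.positions[j]}\t{G.snp_ids[j]}\tA\tT\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path) -> pd.DataFrame:
    """Gene rows of a GFF3 file as a 1-based inclusive interval table.

    Only feature type ``gene`` is kept; the gene id comes from the ID
    attribute and records without one are skipped with a warning.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    columns = ["gene_id", "chrom", "start", "end", "strand"]
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:
        return pd.DataFrame(columns=columns)
    rows = []
    for f in db.features_of_type("gene"):
        ids = f.attributes.get("ID")
        if not ids:
            warnings.warn(
                f"gene record at {f.seqid}:{f.start}-{f.end} lacks an ID attribute; skipped",
                stacklevel=2,
            )
            continue
        rows.append((ids[0], f.seqid, int(f.start), int(f.end), f.strand or "."))
    return pd.DataFrame(rows, columns=columns)


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write a gene interval table as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\tgrapegwas\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# tabular formats

def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, dtype={"accession": str, "season": str, "trait": str})
    required = {"accession", "season", "trait", "value"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    return pheno


def write_go_table(go: pd.DataFrame, path) -> None:
    go.to_csv(path, sep="\t", index=False)


def read_go_table(path) -> pd.DataFrame:
    go = pd.read_csv(path, sep="\t")
    required = {"gene_id", "go_id", "category"}
    missing = required - set(go.columns)
    if missing:
        raise ValueError(f"GO TSV missing columns: {sorted(missing)}")
    bad = set(go["category"]) - {"CC", "MF", "BP"}
    if bad:
        raise ValueError(f"invalid GO categories: {sorted(bad)}")
    return go


def write_bed_windows(hits, path) -> None:
    """Hit windows as BED (0-based half-open conversion from 1-based bins)."""
    with open(path, "w") as fh:
        fh.write("# BED: 0-based half-open candidate windows\n")
        for h in hits:
            fh.write(f"{h.chrom}\t{h.window_start - 1}\t{h.window_end}\t{h.snp_id}\n")


# ---------------------------------------------------------------------------
# published results table

def read_published_associations() -> pd.DataFrame:
    """The published 69-row significant-association table bundled with the package.

    Columns: trait, chrom, position, snp, lod, region_ini, region_fin,
    gene_ini, gene_fin, gene, distance (all coordinates 1-based bp; gene
    fields NA for the hit without a candidate).
    """
    ref = resources.files("grapegwas.data").joinpath("published_associations.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
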