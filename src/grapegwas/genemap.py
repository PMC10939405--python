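"""Tiered candidate-gene search around significant SNPs.

Primary tier: every gene whose interval intersects the +/-10-kbp bin around
the SNP.  If the bin is empty, fallback tier: the single nearest gene on
the chromosome, accepted only if it lies within +/-25 kbp.  Otherwise the
hit is recorded without a candidate.  Distances are SNP-to-nearest-gene-
boundary in bp (0 when the SNP falls inside the gene), strand-ignorant,
with all coordinates 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["find_candidates", "summarize_hits", "hits_from_table", "CandidateHit"]

PRIMARY_HALF = 10_000
FALLBACK_HALF = 25_000


@dataclass
class CandidateHit:
    """Candidate genes for one significant SNP."""

    snp_id: str
    chrom: str
    pos: int
    trait: str | None = None
    lod: float | None = None
    window_start: int = 0  # primary +/-10-kbp bin
    window_end: int = 0
    region_start: int = 0  # +/-25-kbp search region (reported table layout)
    region_end: int = 0
    genes: list[tuple[str, int]] = field(default_factory=list)  # (gene id, distance bp)
    tier: str = "missing"  # primary_10kb | fallback_25kb | missing

    @property
    def min_distance(self) -> float:
        return min((d for _g, d in self.genes), default=np.nan)


def _distance(pos: int, start: int, end: int) -> int:
    if start <= pos <= end:
        return 0
    return min(abs(pos - start), abs(pos - end))


def find_candidates(
    snp: tuple[str, int],
    genes: pd.DataFrame,
    primary_half: int = PRIMARY_HALF,
    fallback_half: int = FALLBACK_HALF,
    snp_id: str | None = None,
    trait: str | None = None,
    lod: float | None = None,
) -> CandidateHit:
    """Tiered window search for one SNP against a gene annotation table.

    ``genes`` needs columns ``gene_id, chrom, start, end`` (1-based,
    inclusive).  Window intersection is inclusive on both ends; the
    fallback tier returns exactly one gene, ties broken by lower start
    coordinate.
    """
    chrom, pos = snp
    hit = CandidateHit(
        snp_id=snp_id or f"M_{str(chrom).removeprefix('chr')}_{pos}",
        chrom=chrom,
        pos=int(pos),
        trait=trait,
        lod=lod,
        window_start=max(1, pos - primary_half),
        window_end=pos + primary_half,
        region_start=pos - fallback_half,
        region_end=pos + fallback_half,
    )
    on_chrom = genes.loc[genes["chrom"] == chrom]
    if on_chrom.empty:
        warnings.warn(f"chromosome {chrom!r} absent from annotation", stacklevel=2)
        return hit

    lo, hi = pos - primary_half, pos + primary_half
    inside = on_chrom.loc[(on_chrom["start"] <= hi) & (on_chrom["end"] >= lo)]
    if not inside.empty:
        inside = inside.sort_values(["start", "gene_id"])
        hit.genes = [
            (g.gene_id, _distance(pos, int(g.start), int(g.end)))
            for g in inside.itertuples()
        ]
        hit.tier = "primary_10kb"
        return hit

    dists = np.array(
        [_distance(pos, int(s), int(e)) for s, e in zip(on_chrom["start"], on_chrom["end"])]
    )
    best = dists.min()
    if best <= fallback_half:
        cand = on_chrom.loc[dists == best].sort_values(["start", "gene_id"]).iloc[0]
        hit.genes = [(cand["gene_id"], int(best))]
        hit.tier = "fallback_25kb"
    return hit


def summarize_hits(hits: list[CandidateHit], primary_half: int = PRIMARY_HALF) -> dict:
    """Counts of the candidate-gene funnel over a hit list.

    Reports the number of SNPs inside a gene (distance 0), near a gene
    (0 < distance <= primary window), found only via the fallback tier,
    and with no candidate; plus the mean number of genes per non-missing
    hit and the number of distinct candidate genes.
    """
    n_within = n_near = n_fallback = n_missing = 0
    gene_ids: set[str] = set()
    n_genes_total = 0
    for h in hits:
        if h.tier == "missing" or not h.genes:
            n_missing += 1
            continue
        n_genes_total += len(h.genes)
        gene_ids.update(g for g, _d in h.genes)
        d = h.min_distance
        if h.tier == "fallback_25kb" and d > primary_half:
            n_fallback += 1
        elif d == 0:
            n_within += 1
        else:
            n_near += 1
    n_nonmissing = len(hits) - n_missing
    return {
        "n_hits": len(hits),
        "within_gene": n_within,
        "near_gene": n_near,
        "fallback": n_fallback,
        "missing": n_missing,
        "genes_per_hit": n_genes_total / n_nonmissing if n_nonmissing else 0.0,
        "distinct_genes": len(gene_ids),
    }


def hits_from_table(table: pd.DataFrame) -> list[CandidateHit]:
    """Build hit objects from a reported association table.

    Expects columns ``trait, chrom, position, snp, lod, gene, distance``
    (``gene``/``distance`` NaN when the hit lacks a candidate), the layout
    of :func:`grapegwas.io.read_published_associations`.
    """
    hits = []
    for r in table.itertuples():
        h = CandidateHit(
            snp_id=r.snp,
            chrom=r.chrom,
            pos=int(r.position),
            trait=r.trait,
            lod=float(r.lod),
            window_start=max(1, int(r.position) - PRIMARY_HALF),
            window_end=int(r.position) + PRIMARY_HALF,
            region_start=int(r.position) - FALLBACK_HALF,
            region_end=int(r.position) + FALLBACK_HALF,
        )
        if isinstance(r.gene, str) and r.gene not in ("", "NA"):
            d = int(r.distance)
            h.genes = [(r.gene, d)]
            h.tier = "primary_10kb" if d <= PRIMARY_HALF else "fallback_25kb"
        hits.append(h)
    return hits
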