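"""Trait x GO occurrence matrix and trait correlation networks.

Every (hit, candidate gene, GO term) triple contributes one count to the
trait x GO matrix — a gene shared by two hits therefore counts twice.
Terms seen fewer than three times in total are dropped ("appeared more than
twice" rule).  Trait networks are built two ways: GO-based (Pearson r
between per-trait GO count vectors, split by CC/MF/BP category) and
phenotype-based (Pearson r between trait BLUEs within an accession group).
Edges are classified weak when 0.3 < |r| <= 0.7 and strong when |r| > 0.7.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .blues import BlueTable
from .genemap import CandidateHit

logger = logging.getLogger(__name__)

__all__ = [
    "build_go_matrix",
    "go_correlations",
    "phenotype_correlations",
    "top_go_contributions",
    "TraitGOMatrix",
    "classify_edge",
    "GO_CATEGORIES",
]

GO_CATEGORIES = ("CC", "MF", "BP")
WEAK_R, STRONG_R = 0.3, 0.7


@dataclass
class TraitGOMatrix:
    """Trait x GO count matrix with per-term category labels."""

    counts: pd.DataFrame  # index traits, columns GO ids, integer counts
    categories: pd.Series  # GO id -> CC | MF | BP
    terms: pd.Series = field(default=None)  # GO id -> label, when available

    def category_counts(self, category: str) -> pd.DataFrame:
        if category not in GO_CATEGORIES:
            raise ValueError(f"unknown GO category {category!r}")
        cols = self.categories.index[self.categories == category]
        return self.counts[[c for c in self.counts.columns if c in set(cols)]]


def build_go_matrix(
    hits: list[CandidateHit], go: pd.DataFrame, min_total: int = 3
) -> TraitGOMatrix:
    """Count (hit, gene, GO) occurrences per trait and filter rare terms.

    ``go`` needs columns ``gene_id, go_id, category`` (optionally ``term``).
    Terms with total count < ``min_total`` are dropped.
    """
    if go.empty:
        warnings.warn("empty GO table; trait x GO matrix is empty", stacklevel=2)
        return TraitGOMatrix(
            counts=pd.DataFrame(), categories=pd.Series(dtype=object),
            terms=pd.Series(dtype=object),
        )
    by_gene = go.groupby("gene_id")
    rows = []
    for h in hits:
        if h.trait is None:
            raise ValueError(f"hit {h.snp_id} carries no trait label")
        for gene_id, _d in h.genes:
            try:
                annots = by_gene.get_group(gene_id)
            except KeyError:
                continue
            for a in annots.itertuples():
                rows.append((h.trait, a.go_id))
    if not rows:
        return TraitGOMatrix(
            counts=pd.DataFrame(), categories=pd.Series(dtype=object),
            terms=pd.Series(dtype=object),
        )
    occ = pd.DataFrame(rows, columns=["trait", "go_id"])
    counts = (
        occ.groupby(["trait", "go_id"]).size().unstack(fill_value=0).sort_index(axis=1)
    )
    keep = counts.sum(axis=0) >= min_total
    counts = counts.loc[:, keep]
    categories = go.drop_duplicates("go_id").set_index("go_id")["category"]
    categories = categories.loc[categories.index.isin(counts.columns)]
    terms = None
    if "term" in go.columns:
        terms = go.drop_duplicates("go_id").set_index("go_id")["term"]
        terms = terms.loc[terms.index.isin(counts.columns)]
    return TraitGOMatrix(counts=counts, categories=categories, terms=terms)


def classify_edge(r: float) -> str:
    if abs(r) > STRONG_R:
        return "strong"
    if abs(r) > WEAK_R:
        return "weak"
    return "none"


def _edge_frame(values: pd.DataFrame, source: str) -> pd.DataFrame:
    """All pairwise Pearson correlations between columns of ``values``."""
    rows = []
    for a, b in combinations(values.columns, 2):
        pair = values[[a, b]].dropna()
        if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
            continue
        r = float(np.corrcoef(pair[a], pair[b])[0, 1])
        rows.append((a, b, r, classify_edge(r), source))
    return pd.DataFrame(
        rows, columns=["trait_a", "trait_b", "r", "edge_class", "source"]
    )


def go_correlations(m: TraitGOMatrix, category: str) -> pd.DataFrame:
    """Pairwise trait correlations over one GO category's count vectors.

    Traits whose count vector has zero variance in the category are
    excluded (logged).  Returns an edge list ``trait_a, trait_b, r,
    edge_class, source``.
    """
    counts = m.category_counts(category)
    if counts.empty:
        raise ValueError(f"no retained GO terms in category {category}")
    variances = counts.var(axis=1)
    dropped = variances.index[variances == 0].tolist()
    if dropped:
        logger.info("go_correlations(%s): excluding zero-variance traits %s", category, dropped)
    usable = counts.loc[variances > 0]
    if len(usable) < 2:
        raise ValueError(f"fewer than two usable traits in category {category}")
    return _edge_frame(usable.T, source=f"GO:{category}")


def phenotype_correlations(
    blues: BlueTable | pd.DataFrame, groups: pd.Series | np.ndarray
) -> dict[str, pd.DataFrame]:
    """Per-group pairwise trait correlations of BLUE values.

    ``groups`` assigns each accession (row of the BLUE matrix) to a panel,
    e.g. the diversity panel versus breeding lines.  Groups with fewer than
    three accessions are skipped with a warning.  Correlations use
    pairwise-complete observations.
    """
    values = blues.values if isinstance(blues, BlueTable) else blues
    groups = pd.Series(np.asarray(groups), index=values.index)
    out: dict[str, pd.DataFrame] = {}
    for g, idx in groups.groupby(groups).groups.items():
        if len(idx) < 3:
            warnings.warn(f"group {g!r} has fewer than 3 accessions; skipped", stacklevel=2)
            continue
        out[str(g)] = _edge_frame(values.loc[idx], source=f"phenotype:{g}")
    return out


def top_go_contributions(
    m: TraitGOMatrix, top_n: int = 10
) -> dict[str, pd.DataFrame]:
    """Per-category top GO terms and each trait's share of their counts.

    For each category: the ``top_n`` terms by total occurrence (ties broken
    by GO id), with columns ``go_id, total, category`` plus one share
    column per trait (shares sum to 1 per term).  The per-category total
    occurrence count is stored in ``attrs['category_total']``.
    """
    out: dict[str, pd.DataFrame] = {}
    for category in GO_CATEGORIES:
        counts = m.category_counts(category)
        if counts.empty:
            out[category] = pd.DataFrame(columns=["go_id", "total", "category"])
            out[category].attrs["category_total"] = 0
            continue
        totals = counts.sum(axis=0)
        order = sorted(totals.index, key=lambda g: (-totals[g], g))[:top_n]
        rows = []
        for go_id in order:
            shares = counts[go_id] / totals[go_id]
            rows.append(
                {"go_id": go_id, "total": int(totals[go_id]), "category": category,
                 **shares.to_dict()}
            )
        frame = pd.DataFrame(rows)
        frame.attrs["category_total"] = int(totals.sum())
        out[category] = frame
    return out
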