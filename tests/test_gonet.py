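"""Trait x GO matrix construction, correlation networks and contributions."""

import numpy as np
import pandas as pd
import pytest

from grapegwas.genemap import CandidateHit
from grapegwas.gonet import (
    TraitGOMatrix,
    build_go_matrix,
    classify_edge,
    go_correlations,
    phenotype_correlations,
    top_go_contributions,
)


def _hit(snp, trait, genes):
    return CandidateHit(
        snp_id=snp, chrom="chr01", pos=1, trait=trait,
        genes=[(g, 0) for g in genes], tier="primary_10kb",
    )


def _go(rows):
    return pd.DataFrame(rows, columns=["gene_id", "go_id", "category", "term"])


GO = _go(
    [("g1", "GO:1", "CC", "nucleus"), ("g1", "GO:2", "MF", "binding"),
     ("g2", "GO:1", "CC", "nucleus"), ("g3", "GO:1", "CC", "nucleus"),
     ("g3", "GO:3", "BP", "proteolysis"), ("g4", "GO:2", "MF", "binding")]
)


class TestMatrix:
    def test_boundary_of_more_than_twice_rule(self):
        hits = [_hit("s1", "t1", ["g1"]), _hit("s2", "t2", ["g2"]), _hit("s3", "t3", ["g3"])]
        m = build_go_matrix(hits, GO)
        assert "GO:1" in m.counts.columns  # 3 occurrences: kept
        assert "GO:2" not in m.counts.columns  # 2 occurrences: dropped
        assert "GO:3" not in m.counts.columns

    def test_shared_gene_counts_once_per_hit(self):
        hits = [_hit("s1", "t1", ["g1"]), _hit("s2", "t2", ["g1"]), _hit("s3", "t1", ["g2"])]
        m = build_go_matrix(hits, GO)
        assert m.counts.loc["t1", "GO:1"] == 2
        assert m.counts.loc["t2", "GO:1"] == 1

    def test_counts_match_bruteforce_triple_count(self, rng):
        genes = [f"g{i}" for i in range(12)]
        gos = [f"GO:{i}" for i in range(6)]
        go_rows = []
        for g in genes:
            for go_id in rng.choice(gos, size=rng.integers(0, 4), replace=False):
                go_rows.append((g, go_id, "CC", "x"))
        go = _go(go_rows)
        hits = [
            _hit(f"s{i}", f"t{rng.integers(0, 3)}",
                 list(rng.choice(genes, size=rng.integers(1, 4), replace=False)))
            for i in range(25)
        ]
        m = build_go_matrix(hits, go, min_total=1)
        brute: dict[tuple[str, str], int] = {}
        pairs = {(r[0], r[1]) for r in go_rows}
        for h in hits:
            for g, _d in h.genes:
                for go_id in gos:
                    if (g, go_id) in pairs:
                        brute[(h.trait, go_id)] = brute.get((h.trait, go_id), 0) + 1
        for (trait, go_id), c in brute.items():
            assert m.counts.loc[trait, go_id] == c
        assert int(m.counts.to_numpy().sum()) == sum(brute.values())

    def test_empty_go_table_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            m = build_go_matrix([_hit("s1", "t1", ["g1"])], _go([]))
        assert m.counts.empty

    def test_hit_order_invariance(self):
        hits = [_hit("s1", "t1", ["g1"]), _hit("s2", "t2", ["g2"]), _hit("s3", "t1", ["g3"])]
        a = build_go_matrix(hits, GO, min_total=1).counts
        b = build_go_matrix(hits[::-1], GO, min_total=1).counts
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


def _matrix(counts: dict[str, dict[str, int]], categories: dict[str, str]) -> TraitGOMatrix:
    frame = pd.DataFrame(counts).T.fillna(0).astype(int)
    return TraitGOMatrix(counts=frame, categories=pd.Series(categories))


class TestCorrelations:
    def test_identical_vectors_give_strong_unit_edge(self):
        m = _matrix(
            {"t1": {"GO:1": 3, "GO:2": 1, "GO:3": 5},
             "t2": {"GO:1": 3, "GO:2": 1, "GO:3": 5}},
            {"GO:1": "CC", "GO:2": "CC", "GO:3": "CC"},
        )
        net = go_correlations(m, "CC")
        assert net.loc[0, "r"] == pytest.approx(1.0)
        assert net.loc[0, "edge_class"] == "strong"

    def test_orthogonal_indicators_anticorrelate(self):
        k = 4
        counts = {
            "t1": {f"GO:{i}": int(i == 0) for i in range(k)},
            "t2": {f"GO:{i}": int(i == 1) for i in range(k)},
        }
        m = _matrix(counts, {f"GO:{i}": "MF" for i in range(k)})
        net = go_correlations(m, "MF")
        # closed form for orthogonal one-hot vectors of length k
        assert net.loc[0, "r"] == pytest.approx(-1.0 / (k - 1), abs=1e-9)

    def test_matches_direct_recomputation(self, rng):
        traits = [f"t{i}" for i in range(4)]
        gos = [f"GO:{i}" for i in range(7)]
        counts = {t: {g: int(rng.integers(0, 6)) for g in gos} for t in traits}
        m = _matrix(counts, {g: "BP" for g in gos})
        net = go_correlations(m, "BP")
        for row in net.itertuples():
            a = np.array([counts[row.trait_a][g] for g in gos])
            b = np.array([counts[row.trait_b][g] for g in gos])
            assert row.r == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-9)
            assert row.edge_class == classify_edge(row.r)

    def test_zero_variance_traits_excluded(self):
        m = _matrix(
            {"t1": {"GO:1": 2, "GO:2": 2}, "t2": {"GO:1": 1, "GO:2": 4},
             "t3": {"GO:1": 5, "GO:2": 1}},
            {"GO:1": "CC", "GO:2": "CC"},
        )
        net = go_correlations(m, "CC")
        used = set(net.trait_a) | set(net.trait_b)
        assert "t1" not in used  # constant vector carries no correlation signal

    def test_too_few_usable_traits_rejected(self):
        m = _matrix({"t1": {"GO:1": 1, "GO:2": 1}}, {"GO:1": "CC", "GO:2": "CC"})
        with pytest.raises(ValueError):
            go_correlations(m, "CC")


class TestPhenotypeCorrelations:
    def test_duplicated_trait_has_unit_correlation(self, rng):
        vals = pd.DataFrame(
            {"t1": rng.normal(size=30)}, index=[f"a{i}" for i in range(30)]
        )
        vals["t1_copy"] = vals["t1"]
        nets = phenotype_correlations(vals, np.repeat("jardin", 30))
        edge = nets["jardin"].iloc[0]
        assert edge["r"] == pytest.approx(1.0)
        assert edge["edge_class"] == "strong"

    def test_independent_traits_uncorrelated_on_average(self, rng):
        vals = pd.DataFrame(
            rng.normal(size=(200, 5)), columns=[f"t{i}" for i in range(5)],
            index=[f"a{i}" for i in range(200)],
        )
        nets = phenotype_correlations(vals, np.repeat("breeding", 200))
        assert nets["breeding"]["r"].abs().mean() < 0.15

    def test_small_groups_skipped_with_warning(self, rng):
        vals = pd.DataFrame(
            rng.normal(size=(5, 2)), columns=["t1", "t2"],
            index=[f"a{i}" for i in range(5)],
        )
        groups = ["big", "big", "big", "small", "small"]
        with pytest.warns(UserWarning, match="fewer than 3"):
            nets = phenotype_correlations(vals, groups)
        assert set(nets) == {"big"}


class TestContributions:
    def test_single_trait_owns_all_shares(self):
        m = _matrix({"t1": {"GO:1": 4, "GO:2": 3}}, {"GO:1": "CC", "GO:2": "CC"})
        contrib = top_go_contributions(m)["CC"]
        np.testing.assert_allclose(contrib["t1"], 1.0)

    def test_ties_ordered_by_go_id(self):
        m = _matrix(
            {"t1": {"GO:b": 3, "GO:a": 3}, "t2": {"GO:b": 0, "GO:a": 0}},
            {"GO:a": "MF", "GO:b": "MF"},
        )
        contrib = top_go_contributions(m)["MF"]
        assert list(contrib["go_id"]) == ["GO:a", "GO:b"]

    def test_shares_sum_to_one_and_match_recount(self, rng):
        traits = [f"t{i}" for i in range(3)]
        counts = {t: {f"GO:{g}": int(rng.integers(0, 8)) for g in range(12)} for t in traits}
        m = _matrix(counts, {f"GO:{g}": "BP" for g in range(12)})
        contrib = top_go_contributions(m, top_n=5)["BP"]
        assert len(contrib) == 5
        for row in contrib.itertuples():
            total = sum(counts[t][row.go_id] for t in traits)
            assert row.total == total
            assert sum(getattr(row, t) for t in traits) == pytest.approx(1.0)
        assert contrib.attrs["category_total"] == sum(
            counts[t][g] for t in traits for g in counts[t]
        )
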