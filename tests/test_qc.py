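"""QC filtering, imputation, PCA, kinship, clustering and LD decay."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from grapegwas.containers import GenotypeMatrix
from grapegwas.qc import (
    cluster_accessions,
    impute_mean,
    ld_decay,
    qc_filter,
    run_pca,
    vanraden_kinship,
)
from grapegwas.simulate import SimConfig, simulate_genotypes

from conftest import small_config


def _matrix(dosages, positions=None, chrom="chr01", groups=None):
    dosages = np.asarray(dosages, dtype=np.float32)
    n_acc, n_snp = dosages.shape
    if positions is None:
        positions = np.arange(1, n_snp + 1) * 100
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"s{j}" for j in range(n_snp)]),
        chroms=np.repeat(chrom, n_snp),
        positions=np.asarray(positions),
        accession_ids=np.array([f"a{i}" for i in range(n_acc)]),
        group_labels=None if groups is None else np.asarray(groups),
    )


def _random_masked(rng, n_acc=100, n_snp=200, missing=0.15):
    dos = rng.binomial(2, rng.uniform(0.02, 0.5, n_snp), size=(n_acc, n_snp)).astype(float)
    mask = rng.random(dos.shape) < missing
    dos[mask] = np.nan
    return _matrix(dos)


class TestFilter:
    def test_monomorphic_snp_removed(self):
        dos = np.zeros((10, 2))
        dos[:, 1] = [0, 1] * 5
        out = qc_filter(_matrix(dos))
        assert list(out.snp_ids) == ["s1"]

    def test_low_call_rate_sample_removed(self):
        dos = np.array(
            [[0, 1, 2, 1, 0],
             [1, 0, 1, 2, 2],
             [2, 2, 0, 0, 1],
             [0, 1, 1, 2, 0]], dtype=float,
        )
        dos[0, :2] = np.nan  # 60% call rate: retained (threshold is strict <)
        dos[1, :3] = np.nan  # 40% call rate: removed
        out = qc_filter(_matrix(dos))
        assert "a1" not in out.accession_ids
        assert "a0" in out.accession_ids

    def test_matches_bruteforce_filter(self, rng):
        G = _random_masked(rng)
        out = qc_filter(G, maf_min=0.05, call_rate_min=0.5)
        # independent recomputation with explicit loops
        keep_acc = [
            i for i in range(G.n_accessions)
            if np.mean(~np.isnan(G.dosages[i])) >= 0.5
        ]
        keep_snp = []
        for j in range(G.n_snps):
            col = G.dosages[keep_acc, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                continue
            p = col.mean() / 2
            if min(p, 1 - p) >= 0.05:
                keep_snp.append(j)
        np.testing.assert_array_equal(
            out.accession_ids, G.accession_ids[keep_acc]
        )
        np.testing.assert_array_equal(out.snp_ids, G.snp_ids[keep_snp])

    def test_idempotent(self, rng):
        G = _random_masked(rng)
        once = qc_filter(G)
        twice = qc_filter(once)
        np.testing.assert_array_equal(once.snp_ids, twice.snp_ids)
        np.testing.assert_array_equal(once.accession_ids, twice.accession_ids)

    def test_everything_removed_is_an_error(self):
        dos = np.zeros((4, 3))
        with pytest.raises(ValueError, match="MAF"):
            qc_filter(_matrix(dos))


class TestImpute:
    def test_identity_without_missingness(self, rng):
        dos = rng.binomial(2, 0.4, size=(8, 12)).astype(float)
        G = _matrix(dos)
        np.testing.assert_array_equal(impute_mean(G).dosages, dos)

    def test_rounded_mean_fill(self):
        dos = np.array([[0.0], [2.0], [np.nan]])
        out = impute_mean(_matrix(dos))
        assert out.dosages[2, 0] == 1.0

    def test_mask_and_recover_beats_chance(self, rng):
        cfg = small_config(seed=23, n_snps=300)
        G = simulate_genotypes(cfg)
        truth = G.dosages.copy()
        masked = truth.copy()
        holes = rng.random(truth.shape) < 0.1
        masked[holes] = np.nan
        Gm = G.subset()
        Gm.dosages = masked
        rec = impute_mean(Gm).dosages[holes]
        assert np.isin(rec, [0.0, 1.0, 2.0]).all()
        concordance = (rec == truth[holes]).mean()
        # random guessing over three classes would give ~1/3
        assert concordance > 0.45


class TestPCA:
    def test_identical_accessions_share_scores(self, rng):
        dos = rng.binomial(2, 0.4, size=(10, 40)).astype(float)
        dos[3] = dos[7]
        pca = run_pca(_matrix(dos), n_components=4)
        np.testing.assert_allclose(pca.scores[3], pca.scores[7], atol=1e-8)

    def test_explained_fractions_match_spectral_oracle(self, rng):
        dos = rng.binomial(2, 0.4, size=(20, 50)).astype(float)
        pca = run_pca(_matrix(dos), n_components=5)
        cov = np.cov(dos, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            pca.explained_fraction, evals[:5] / evals.sum(), atol=1e-8
        )
        assert (np.diff(pca.explained_fraction) <= 1e-12).all()
        assert pca.explained_fraction.sum() <= 1.0 + 1e-12

    def test_first_component_separates_divergent_families(self):
        cfg = SimConfig(
            n_founders=4, family_spec=[(0, 1, 40), (2, 3, 40)],
            include_founder_panel=False, n_snps=300,
            chrom_lengths={"chr01": 3_000_000}, seed=31,
        )
        G = simulate_genotypes(cfg)
        pca = run_pca(G, n_components=2)
        labels = (G.group_labels == "F1_01").astype(int)
        assert silhouette_score(pca.scores[:, :1], labels) > 0

    def test_component_count_truncated_at_rank(self, rng):
        dos = rng.binomial(2, 0.5, size=(5, 30)).astype(float)
        with pytest.warns(UserWarning, match="rank"):
            pca = run_pca(_matrix(dos), n_components=10)
        assert pca.scores.shape[1] <= 4  # centered 5-row matrix has rank <= 4

    def test_explained_invariant_to_accession_order(self, rng):
        dos = rng.binomial(2, 0.4, size=(15, 60)).astype(float)
        perm = rng.permutation(15)
        a = run_pca(_matrix(dos), 4).explained_fraction
        b = run_pca(_matrix(dos[perm]), 4).explained_fraction
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestKinship:
    def test_duplicate_accession_equals_its_diagonal(self, rng):
        dos = rng.binomial(2, 0.4, size=(12, 80)).astype(float)
        dos[5] = dos[0]
        K = vanraden_kinship(_matrix(dos))
        assert K[0, 5] == pytest.approx(K[0, 0], abs=1e-10)
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_matches_direct_formula_evaluation(self, rng):
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 8), size=(5, 8)).astype(float)
        K = vanraden_kinship(_matrix(dos))
        p = dos.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        Z = dos[:, poly] - 2 * p[poly]
        expected = Z @ Z.T / (2 * np.sum(p[poly] * (1 - p[poly])))
        np.testing.assert_allclose(K, expected, atol=1e-10)

    def test_full_sibs_more_related_than_cross_family(self):
        cfg = SimConfig(
            n_founders=60, family_spec=[(0, 1, 25), (2, 3, 25)],
            n_snps=500, chrom_lengths={"chr01": 5_000_000}, seed=37,
        )
        G = simulate_genotypes(cfg)
        K = vanraden_kinship(impute_mean(G))
        f1 = np.flatnonzero(G.group_labels == "F1_01")
        f2 = np.flatnonzero(G.group_labels == "F1_02")
        within = K[np.ix_(f1, f1)][np.triu_indices(len(f1), k=1)].mean()
        across = K[np.ix_(f1, f2)].mean()
        assert within > 0.3
        assert across < 0.1
        assert within > across

    def test_invariant_to_snp_order(self, rng):
        dos = rng.binomial(2, 0.4, size=(10, 50)).astype(float)
        perm = rng.permutation(50)
        K1 = vanraden_kinship(_matrix(dos))
        K2 = vanraden_kinship(_matrix(dos[:, perm]))
        np.testing.assert_allclose(K1, K2, atol=1e-10)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError):
            vanraden_kinship(_matrix(np.zeros((5, 4))))


class TestClustering:
    def test_single_cluster_for_k_one(self, imputed_panel):
        _Gi, pca = imputed_panel
        res = cluster_accessions(pca, K=1)
        assert set(res.kmeans_labels) == {0}

    def test_recovers_simulated_families(self, imputed_panel):
        Gi, pca = imputed_panel
        res = cluster_accessions(pca, K=len(np.unique(Gi.group_labels)), seed=0)
        assert adjusted_rand_score(Gi.group_labels, res.kmeans_labels) > 0.9

    def test_deterministic_given_seed(self, imputed_panel):
        _Gi, pca = imputed_panel
        a = cluster_accessions(pca, K=4, seed=5)
        b = cluster_accessions(pca, K=4, seed=5)
        np.testing.assert_array_equal(a.kmeans_labels, b.kmeans_labels)

    def test_k_larger_than_panel_rejected(self, imputed_panel):
        _Gi, pca = imputed_panel
        with pytest.raises(ValueError):
            cluster_accessions(pca, K=pca.scores.shape[0] + 1)


class TestLDDecay:
    def test_duplicated_snp_pair_has_unit_r2(self, rng):
        dos = rng.binomial(2, 0.4, size=(40, 2)).astype(float)
        dos[:, 1] = dos[:, 0]
        table = ld_decay(_matrix(dos, positions=[100, 5100]), bin_width=1000)
        row = table[table.n_pairs > 0].iloc[0]
        assert row["mean_r2"] == pytest.approx(1.0)
        assert row["bin_start"] <= 5000 <= row["bin_end"]

    def test_bin_means_match_bruteforce(self, rng):
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 30), size=(50, 30)).astype(float)
        pos = np.sort(rng.choice(np.arange(1, 200_000), size=30, replace=False))
        G = _matrix(dos, positions=pos)
        table = ld_decay(G, max_dist=500_000, bin_width=10_000)
        sums = {}
        counts = {}
        for i in range(30):
            for j in range(i + 1, 30):
                if dos[:, i].std() == 0 or dos[:, j].std() == 0:
                    continue
                d = pos[j] - pos[i]
                b = (d - 1) // 10_000
                r2 = np.corrcoef(dos[:, i], dos[:, j])[0, 1] ** 2
                sums[b] = sums.get(b, 0.0) + r2
                counts[b] = counts.get(b, 0) + 1
        for b, c in counts.items():
            assert table.loc[b, "n_pairs"] == c
            assert table.loc[b, "mean_r2"] == pytest.approx(sums[b] / c, abs=1e-9)

    def test_crossing_distance_tracks_block_length(self):
        cfg = SimConfig(
            n_founders=300, family_spec=[], n_snps=200,
            chrom_lengths={"chr01": 400_000}, ld_block_len=20_000, seed=41,
        )
        G = simulate_genotypes(cfg)
        table = ld_decay(G, max_dist=200_000, r2_threshold=0.2, bin_width=5_000)
        crossing = table.attrs["crossing_distance"]
        assert 10_000 <= crossing <= 40_000

    def test_block_ld_exceeds_long_range_ld(self, panel):
        G, _ = panel
        Gi = impute_mean(qc_filter(G))
        table = ld_decay(Gi, max_dist=200_000, bin_width=10_000)
        near = table.loc[0, "mean_r2"]  # within one block length
        far = table[(table.bin_start > 50_000) & (table.n_pairs > 0)]["mean_r2"].mean()
        assert near > far

    def test_single_snp_rejected(self, rng):
        dos = rng.binomial(2, 0.4, size=(10, 1)).astype(float)
        with pytest.raises(ValueError):
            ld_decay(_matrix(dos))
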