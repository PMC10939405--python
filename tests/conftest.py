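"""Shared synthetic fixtures: a small multi-family panel used across modules."""

import numpy as np
import pytest

from grapegwas import qc as qc_mod
from grapegwas.simulate import SimConfig, simulate_genotypes, simulate_phenotypes


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A 125-accession, 1200-SNP panel: diversity panel + 3 F1 families + selfs."""
    base = dict(
        n_founders=20,
        family_spec=[(0, 1, 30), (0, 2, 30), (3, 4, 30), (0, 0, 15)],
        n_snps=1200,
        chrom_lengths={f"chr{i:02d}": 3_000_000 for i in (2, 5, 11, 14, 18)},
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def panel_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def panel(panel_cfg):
    G = simulate_genotypes(panel_cfg)
    pheno = simulate_phenotypes(G, panel_cfg)
    return G, pheno


@pytest.fixture(scope="session")
def imputed_panel(panel):
    G, _pheno = panel
    Gi = qc_mod.impute_mean(qc_mod.qc_filter(G))
    pca = qc_mod.run_pca(Gi, n_components=8)
    return Gi, pca


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_103)
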