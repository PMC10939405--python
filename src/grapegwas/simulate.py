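"""Synthetic study-design generator.

Emulates the data layout of a table-grape association panel: a diversity
panel of cultivars plus several related F1 families (and one selfed family)
genotyped at tens of thousands of biallelic SNPs, phenotyped for 13
yield-related traits over three seasons.  Founders carry block-haplotype
genomes (linkage decays at block boundaries); offspring are produced by
Mendelian transmission with recombination only between blocks.  Phenotypes
follow the fixed-effects model

    y = season effect + covariate slopes + additive genetic value + noise

with per-accession genetic values driven by a small set of causal SNPs,
including one major-effect seed-dry-weight locus on chromosome 18 that also
feeds berry/harvest traits through the seed-dry-weight covariate (the
classic seedlessness-locus confounding in table grapes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "SimConfig",
    "TRAITS",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_annotation",
    "default_causal_spec",
]

SEED_TRAITS = ["S_number", "S_fresh", "S_dry"]
BERRY_TRAITS = ["B_height", "B_width", "B_shape", "B_weight"]
HARVEST_TRAITS = ["H_cluster", "H_rachis"]
POSTHARVEST_TRAITS = ["P_cluster", "P_cluster_loss", "P_rachis", "P_rachis_loss"]
TRAITS = SEED_TRAITS + BERRY_TRAITS + HARVEST_TRAITS + POSTHARVEST_TRAITS

# Approximate chromosome sizes (bp) of the grape reference assembly.
GRAPE_CHROM_LENGTHS = {
    "chr01": 23_000_000, "chr02": 18_800_000, "chr03": 19_900_000,
    "chr04": 23_900_000, "chr05": 25_000_000, "chr06": 21_800_000,
    "chr07": 21_400_000, "chr08": 22_400_000, "chr09": 23_200_000,
    "chr10": 18_100_000, "chr11": 19_800_000, "chr12": 22_400_000,
    "chr13": 24_400_000, "chr14": 30_300_000, "chr15": 20_300_000,
    "chr16": 22_100_000, "chr17": 17_100_000, "chr18": 29_400_000,
    "chr19": 24_200_000,
}

# Per-operation RNG stream offsets (seeded as default_rng([seed, offset]))
_GENO_STREAM, _PHENO_STREAM, _ANNOT_STREAM = 1, 2, 3


def _default_family_spec() -> list[tuple[int, int, int]]:
    # 7 F1 crosses (4 sharing founder 0 as the female parent, mimicking the
    # half-sib supercluster of the real panel) plus a selfed family of
    # founder 0.  68 panel cultivars + 7*68 + 44 = 588 accessions.
    return [
        (0, 1, 68), (0, 2, 68), (0, 3, 68), (0, 4, 68),
        (5, 2, 68), (6, 7, 68), (8, 9, 68),
        (0, 0, 44),
    ]


def _default_season_effects() -> dict[str, float]:
    return {"2018": 0.0, "2019": 0.5, "2020": -0.5}


def _default_covariate_effects() -> dict[tuple[str, str], float]:
    eff: dict[tuple[str, str], float] = {}
    for t in BERRY_TRAITS + HARVEST_TRAITS + POSTHARVEST_TRAITS:
        eff[(t, "soluble_solids")] = 0.3
    for t in BERRY_TRAITS + HARVEST_TRAITS:
        eff[(t, "S_dry")] = 0.5
    return eff


@dataclass
class SimConfig:
    """Parameters of the synthetic study design (defaults = study scale)."""

    n_founders: int = 68
    family_spec: list[tuple[int, int, int]] = field(default_factory=_default_family_spec)
    include_founder_panel: bool = True
    # raw marker count; ~71% of block-haplotype SNPs pass the 5% MAF filter,
    # so the post-QC panel lands near the 49 210-marker study scale
    n_snps: int = 69_000
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(GRAPE_CHROM_LENGTHS))
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_len: int = 10_000
    n_ancestral_haplotypes: int = 4
    founder_mutation_rate: float = 0.01
    causal_spec: list[tuple[int, str, float]] | None = None  # (snp index, trait, effect)
    season_effects: dict[str, float | dict[str, float]] = field(
        default_factory=_default_season_effects
    )
    covariate_effects: dict[tuple[str, str], float] = field(
        default_factory=_default_covariate_effects
    )
    noise_sd: float | dict[str, float] = 1.0
    missing_rate: float = 0.0
    # annotation layer
    gene_density: float = 1.0 / 15_000  # genes per bp
    gene_len_range: tuple[int, int] = (1_000, 6_000)
    go_annotation_prob: float = 0.48
    go_max_terms: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for *_parents, n in self.family_spec):
            raise ValueError("offspring counts must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")
        for sd in self._noise_sd_map().values():
            if not sd > 0:
                raise ValueError("noise_sd must be > 0")
        if self.causal_spec is not None:
            for idx, _trait, _eff in self.causal_spec:
                if not (0 <= idx < self.n_snps):
                    raise ValueError(f"causal snp index {idx} out of range")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    # -- small accessors ---------------------------------------------------

    def traits(self) -> list[str]:
        return list(TRAITS)

    def seasons(self) -> list[str]:
        return list(self.season_effects)

    def season_offset(self, season: str, trait: str) -> float:
        off = self.season_effects[season]
        return off[trait] if isinstance(off, dict) else float(off)

    def _noise_sd_map(self) -> dict[str, float]:
        if isinstance(self.noise_sd, dict):
            return {t: float(self.noise_sd.get(t, 1.0)) for t in TRAITS}
        return {t: float(self.noise_sd) for t in TRAITS}


# ---------------------------------------------------------------------------
# genotypes


def _distinct_positions(rng: np.random.Generator, length: int, m: int) -> np.ndarray:
    """m distinct, sorted, 1-based positions on [1, length]."""
    if m > length:
        raise ValueError("more SNPs than base pairs on a chromosome")
    pos = np.unique(rng.integers(1, length + 1, size=m))
    while pos.size < m:
        extra = rng.integers(1, length + 1, size=m - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate founder + family genotypes under the block-haplotype model.

    Founder haplotypes are drawn per LD block from a small pool of ancestral
    haplotypes (plus rare mutations), which yields high within-block and low
    between-block correlation.  Offspring receive one haplotype per block
    from each parent, chosen independently per block, i.e. recombination
    happens only at block boundaries.
    """
    if cfg.n_founders <= 0:
        raise ValueError("need at least one founder")
    if cfg.n_snps <= 0:
        raise ValueError("need at least one SNP")
    for f, m, _n in cfg.family_spec:
        if not (0 <= f < cfg.n_founders and 0 <= m < cfg.n_founders):
            raise ValueError("family_spec parent index out of range")

    rng = np.random.default_rng([cfg.seed, _GENO_STREAM])

    # allocate SNPs to chromosomes proportional to length (largest remainder)
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    quota = cfg.n_snps * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(quota - counts)[::-1][: cfg.n_snps - counts.sum()]:
        counts[i] += 1

    chrom_arr, pos_arr, block_arr = [], [], []
    block_offset = 0
    for c, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        pos = _distinct_positions(rng, cfg.chrom_lengths[c], int(n_c))
        chrom_arr.append(np.repeat(c, n_c))
        pos_arr.append(pos)
        blocks = (pos - 1) // cfg.ld_block_len
        block_arr.append(blocks + block_offset)
        block_offset += blocks.max() + 1
    chrom_all = np.concatenate(chrom_arr)
    pos_all = np.concatenate(pos_arr)
    _, block_idx = np.unique(np.concatenate(block_arr), return_inverse=True)
    n_blocks = block_idx.max() + 1
    n_snps = pos_all.size
    col = np.arange(n_snps)

    # Ancestral haplotype pool: one latent uniform per (haplotype, block),
    # thresholded by each SNP's allele frequency.  SNPs in a block share the
    # latent draw, which creates strong within-block and no between-block LD.
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_snps)
    latent = rng.random((cfg.n_ancestral_haplotypes, n_blocks))
    anc = (latent[:, block_idx] < p).astype(np.int8)
    n_fhap = 2 * cfg.n_founders
    choice = rng.integers(0, cfg.n_ancestral_haplotypes, size=(n_fhap, n_blocks))
    fhaps = anc[choice[:, block_idx], col]
    if cfg.founder_mutation_rate > 0:
        flips = rng.random(fhaps.shape) < cfg.founder_mutation_rate
        fhaps = np.where(flips, 1 - fhaps, fhaps).astype(np.int8)
    fhaps = fhaps.reshape(cfg.n_founders, 2, n_snps)

    dosage_blocks, acc_ids, groups = [], [], []
    if cfg.include_founder_panel:
        dosage_blocks.append(fhaps.sum(axis=1))
        acc_ids += [f"cv{f:03d}" for f in range(cfg.n_founders)]
        groups += ["jardin"] * cfg.n_founders

    for fam_no, (fem, mal, n_off) in enumerate(cfg.family_spec, start=1):
        if n_off == 0:
            continue
        name = f"self_cv{fem:03d}" if fem == mal else f"F1_{fam_no:02d}"
        kid = np.zeros((n_off, n_snps), dtype=np.int8)
        for parent in (fem, mal):
            pick = rng.integers(0, 2, size=(n_off, n_blocks))
            kid += fhaps[parent][pick[:, block_idx], col]
        dosage_blocks.append(kid)
        acc_ids += [f"{name}_{k:03d}" for k in range(n_off)]
        groups += [name] * n_off

    if not dosage_blocks:
        raise ValueError("configuration produces zero accessions")
    dosages = np.concatenate(dosage_blocks, axis=0).astype(np.float32)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    snp_ids = np.array([f"M_{c[3:]}_{p}" for c, p in zip(chrom_all, pos_all)])
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chroms=chrom_all,
        positions=pos_all,
        accession_ids=np.array(acc_ids),
        group_labels=np.array(groups),
        meta={"simulated": True, "seed": cfg.seed, "ld_block_len": cfg.ld_block_len},
    )


# ---------------------------------------------------------------------------
# phenotypes


def default_causal_spec(G: GenotypeMatrix) -> list[tuple[int, str, float]]:
    """Deterministic default causal architecture for a simulated panel.

    One major-effect S_dry locus near the middle of chr18 (the
    seedlessness-locus analogue), a major B_width locus on chr11, and a few
    modest loci for the remaining traits.  S_number and P_rachis_loss get no
    causal SNPs (traits for which no association is expected).  Effects are
    additive per alt-allele dosage, in trait units.
    """

    maf = np.nan_to_num(G.maf(), nan=0.0)

    def pick(chrom: str, frac: float) -> int:
        on = np.flatnonzero((G.chroms == chrom) & (maf >= 0.1))
        if on.size == 0:
            on = np.flatnonzero(maf >= 0.1)
        if on.size == 0:
            on = np.arange(G.n_snps)
        target = G.positions[on[0]] if on.size == 1 else np.quantile(
            G.positions[on], frac
        )
        return int(on[np.argmin(np.abs(G.positions[on] - target))])

    spec: list[tuple[int, str, float]] = [
        (pick("chr18", 0.85), "S_dry", 2.0),
        (pick("chr02", 0.35), "S_dry", 0.5),
        (pick("chr18", 0.85), "S_fresh", 1.2),
        (pick("chr14", 0.25), "S_fresh", 0.6),
        (pick("chr11", 0.22), "B_width", 1.5),
        (pick("chr08", 0.80), "B_width", 0.5),
        (pick("chr05", 0.10), "B_height", 0.8),
        (pick("chr14", 0.08), "B_shape", 0.5),
        (pick("chr15", 0.02), "B_weight", 0.6),
        (pick("chr04", 0.85), "H_cluster", 0.5),
        (pick("chr12", 0.25), "H_rachis", 0.6),
        (pick("chr18", 0.03), "P_cluster", 0.8),
        (pick("chr11", 0.38), "P_cluster_loss", 0.7),
        (pick("chr02", 0.14), "P_rachis", 0.8),
    ]
    return spec


def simulate_phenotypes(G: GenotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """One record per accession x season x trait under the fixed-effects model.

    Returns a long-format table with columns ``accession, season, trait,
    value, soluble_solids, S_dry``.  Soluble solids are drawn N(16, 2) Brix
    independent of genotype; the S_dry covariate column carries the
    *generated* S_dry trait value of the same accession-season, so traits
    corrected for S_dry inherit its genetic signal (covariate confounding).
    """
    causal = cfg.causal_spec if cfg.causal_spec is not None else default_causal_spec(G)
    traits = cfg.traits()
    for idx, trait, _eff in causal:
        if trait not in traits:
            raise ValueError(f"causal trait {trait!r} unknown")
        for season in cfg.seasons():
            off = cfg.season_effects[season]
            if isinstance(off, dict) and trait not in off:
                raise ValueError(f"trait {trait!r} missing from season_effects[{season!r}]")
        if not (0 <= idx < G.n_snps):
            raise ValueError(f"causal snp index {idx} out of range for this matrix")
    if not cfg.seasons():
        raise ValueError("need at least one season")

    rng = np.random.default_rng([cfg.seed, _PHENO_STREAM])
    n = G.n_accessions
    seasons = cfg.seasons()
    sd = cfg._noise_sd_map()

    # mean-impute dosages for genetic values if the matrix carries missingness
    dos = G.dosages.astype(np.float64)
    if np.isnan(dos).any():
        means = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.where(np.isnan(dos))
        dos[nan_r, nan_c] = means[nan_c]

    gvalues = {t: np.zeros(n) for t in traits}
    for idx, trait, eff in causal:
        gvalues[trait] += eff * dos[:, idx]

    soluble = rng.normal(16.0, 2.0, size=(n, len(seasons)))

    # S_dry first: it is both a trait and a covariate of berry/harvest traits
    ordered = ["S_dry"] + [t for t in traits if t != "S_dry"]
    values: dict[str, np.ndarray] = {}
    for trait in ordered:
        v = np.empty((n, len(seasons)))
        for j, season in enumerate(seasons):
            v[:, j] = (
                cfg.season_offset(season, trait)
                + gvalues[trait]
                + rng.normal(0.0, sd[trait], size=n)
            )
            slope_ss = cfg.covariate_effects.get((trait, "soluble_solids"), 0.0)
            if slope_ss:
                v[:, j] += slope_ss * soluble[:, j]
            slope_sd = cfg.covariate_effects.get((trait, "S_dry"), 0.0)
            if slope_sd:
                v[:, j] += slope_sd * values["S_dry"][:, j]
        values[trait] = v

    rows = []
    for trait in traits:
        for j, season in enumerate(seasons):
            rows.append(
                pd.DataFrame(
                    {
                        "accession": G.accession_ids,
                        "season": season,
                        "trait": trait,
                        "value": values[trait][:, j],
                        "soluble_solids": soluble[:, j],
                        "S_dry": values["S_dry"][:, j],
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["causal_spec"] = list(causal)
    return out


# ---------------------------------------------------------------------------
# annotation


# Fixed GO vocabulary: (go id, category, term).  Frequent terms of the grape
# candidate-gene literature padded with generic terms; sampling weights are
# Zipf-like so a handful of terms dominate, as in real annotation sets.
GO_VOCABULARY: list[tuple[str, str, str]] = [
    ("GO:0005634", "CC", "nucleus"),
    ("GO:0016020", "CC", "membrane"),
    ("GO:0005737", "CC", "cytoplasm"),
    ("GO:0005739", "CC", "mitochondrion"),
    ("GO:0009507", "CC", "chloroplast"),
    ("GO:0005829", "CC", "cytosol"),
    ("GO:0005576", "CC", "extracellular region"),
    ("GO:0005773", "CC", "vacuole"),
    ("GO:0005783", "CC", "endoplasmic reticulum"),
    ("GO:0005794", "CC", "Golgi apparatus"),
    ("GO:0008270", "MF", "zinc ion binding"),
    ("GO:0005524", "MF", "ATP binding"),
    ("GO:0003723", "MF", "RNA binding"),
    ("GO:0043565", "MF", "sequence-specific DNA binding"),
    ("GO:0003700", "MF", "DNA-binding transcription factor activity"),
    ("GO:0004672", "MF", "protein kinase activity"),
    ("GO:0046872", "MF", "metal ion binding"),
    ("GO:0003824", "MF", "catalytic activity"),
    ("GO:0022857", "MF", "transmembrane transporter activity"),
    ("GO:0005525", "MF", "GTP binding"),
    ("GO:0006508", "BP", "proteolysis"),
    ("GO:0045454", "BP", "cell redox homeostasis"),
    ("GO:0006355", "BP", "regulation of DNA-templated transcription"),
    ("GO:0006468", "BP", "protein phosphorylation"),
    ("GO:0055085", "BP", "transmembrane transport"),
    ("GO:0006412", "BP", "translation"),
    ("GO:0009737", "BP", "response to abscisic acid"),
    ("GO:0009611", "BP", "response to wounding"),
    ("GO:0048364", "BP", "root development"),
    ("GO:0009753", "BP", "response to jasmonic acid"),
]


def simulate_annotation(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping gene intervals plus a gene -> GO table.

    Returns ``(genes, go)`` where *genes* has columns
    ``gene_id, chrom, start, end, strand`` (1-based inclusive) and *go* has
    ``gene_id, go_id, category, term``.  A fraction
    :attr:`SimConfig.go_annotation_prob` of genes carries 1..go_max_terms GO
    terms drawn (without replacement per gene) from a fixed vocabulary.
    """
    if not cfg.chrom_lengths:
        raise ValueError("chrom_lengths must be defined")
    lo_len, hi_len = cfg.gene_len_range
    if not (0 < lo_len <= hi_len):
        raise ValueError("invalid gene_len_range")
    if cfg.gene_density < 0:
        raise ValueError("gene_density must be >= 0")

    rng = np.random.default_rng([cfg.seed, _ANNOT_STREAM])
    gene_rows: list[tuple[str, str, int, int, str]] = []
    if cfg.gene_density > 0:
        mean_len = 0.5 * (lo_len + hi_len)
        mean_gap = 1.0 / cfg.gene_density - mean_len
        if mean_gap <= 0:
            raise ValueError(
                "gene_density incompatible with gene_len_range: mean inter-gene gap <= 0"
            )
        for chrom, L in cfg.chrom_lengths.items():
            pos, i = 1, 0
            while True:
                start = pos + 1 + int(rng.exponential(mean_gap))
                end = start + int(rng.integers(lo_len, hi_len + 1)) - 1
                if end >= L:
                    break
                i += 1
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append((f"Synvi{chrom[3:]}g{i:05d}", chrom, start, end, strand))
                pos = end
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )

    vocab = pd.DataFrame(GO_VOCABULARY, columns=["go_id", "category", "term"])
    weights = 1.0 / np.arange(1, len(vocab) + 1)  # Zipf-like popularity
    weights /= weights.sum()
    go_rows = []
    for gene_id in genes["gene_id"]:
        if rng.random() >= cfg.go_annotation_prob:
            continue
        k = int(rng.integers(1, cfg.go_max_terms + 1))
        picks = rng.choice(len(vocab), size=min(k, len(vocab)), replace=False, p=weights)
        for j in sorted(picks):
            go_rows.append((gene_id, *vocab.iloc[j]))
    go = pd.DataFrame(go_rows, columns=["gene_id", "go_id", "category", "term"])
    return genes, go
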