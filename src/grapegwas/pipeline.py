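"""End-to-end orchestration: adjust -> qc -> scan -> validate -> candidates -> GO.

Inputs are either simulated from a :class:`~grapegwas.simulate.SimConfig`
or loaded from files (VCF / CSV / GFF3 / TSV).  Every stage writes its
table under the output directory and the run finishes with a
machine-readable ``manifest.json`` holding parameters, seeds, versions and
the record-count funnel, so a rerun can be compared line by line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assoc, blues as blues_mod, genemap, gonet, io as gio, markerval, qc as qc_mod
from .simulate import SimConfig, simulate_annotation, simulate_genotypes, simulate_phenotypes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    outdir: str | Path = "grapegwas_out"
    seed: int = 0
    # inputs: either a simulation config or file paths
    sim: SimConfig | None = None
    genotype_vcf: str | None = None
    phenotype_csv: str | None = None
    annotation_gff3: str | None = None
    go_tsv: str | None = None
    # stage parameters
    use_covariates: bool = True
    maf_min: float = 0.05
    call_rate_min: float = 0.5
    n_pcs: int = 6
    alpha: float = 0.05
    k_clusters: int = 9
    ld_max_dist: int = 500_000
    ld_r2_threshold: float = 0.2
    replicates: int = 200
    sample_size: int = 250
    n_null_snps: int = 10
    primary_half: int = 10_000
    fallback_half: int = 25_000
    go_min_total: int = 3
    write_inputs: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            if "seed" not in sim_raw:
                sim_raw["seed"] = cfg.seed
            sim_raw = {
                k: (
                    [tuple(x) for x in v]
                    if k in ("family_spec", "causal_spec") and v is not None
                    else tuple(v) if k in ("maf_range", "gene_len_range") else v
                )
                for k, v in sim_raw.items()
            }
            if "covariate_effects" in sim_raw:
                sim_raw["covariate_effects"] = {
                    tuple(k.split(":")): v for k, v in sim_raw["covariate_effects"].items()
                }
            cfg.sim = SimConfig(**sim_raw)
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full downstream analysis; returns the manifest dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in vars(cfg).items()
            if k not in ("sim", "outdir") and not isinstance(v, Path)
        },
        "stages": {},
    }

    # ---- inputs ---------------------------------------------------------
    @_stage("inputs")
    def load_inputs():
        if cfg.sim is not None:
            sim = cfg.sim
            G = simulate_genotypes(sim)
            pheno = simulate_phenotypes(G, sim)
            genes, go = simulate_annotation(sim)
            manifest["stages"]["inputs"] = {
                "mode": "simulated",
                "causal_spec": [
                    [int(i), t, float(e)] for i, t, e in pheno.attrs["causal_spec"]
                ],
            }
            if cfg.write_inputs:
                gio.write_vcf(G, outdir / "genotypes.vcf")
                gio.write_phenotypes(pheno, outdir / "phenotypes.csv")
                gio.write_gff3(genes, outdir / "annotation.gff3")
                gio.write_go_table(go, outdir / "go_annotations.tsv")
        else:
            if not (cfg.genotype_vcf and cfg.phenotype_csv):
                raise ValueError("need either a sim config or genotype/phenotype paths")
            G = gio.read_vcf(cfg.genotype_vcf)
            pheno = gio.read_phenotypes(cfg.phenotype_csv)
            genes = (
                gio.read_gff3(cfg.annotation_gff3)
                if cfg.annotation_gff3
                else pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
            )
            go = (
                gio.read_go_table(cfg.go_tsv)
                if cfg.go_tsv
                else pd.DataFrame(columns=["gene_id", "go_id", "category", "term"])
            )
            manifest["stages"]["inputs"] = {"mode": "files"}
        return G, pheno, genes, go

    G, pheno, genes, go = load_inputs()

    # ---- BLUE adjustment ------------------------------------------------
    @_stage("adjust")
    def adjust():
        table = blues_mod.fit_all_blues(pheno, use_covariates=cfg.use_covariates)
        out = table.values.copy()
        out.insert(0, "accession", out.index)
        _write_tsv(out, outdir / "blues.tsv", "accession BLUEs per trait (trait units)")
        manifest["stages"]["adjust"] = {
            "traits": list(table.values.columns),
            "use_covariates": cfg.use_covariates,
            "records_dropped": {t: r.n_dropped for t, r in table.fits.items()},
            "sigma2": {t: r.sigma2 for t, r in table.fits.items()},
        }
        return table

    blue_table = adjust()

    # ---- genotype QC + structure ---------------------------------------
    @_stage("qc")
    def run_qc():
        Gf = qc_mod.qc_filter(G, maf_min=cfg.maf_min, call_rate_min=cfg.call_rate_min)
        Gi = qc_mod.impute_mean(Gf)
        pca = qc_mod.run_pca(Gi, n_components=max(cfg.n_pcs, 8))
        K = qc_mod.vanraden_kinship(Gi)
        k_eff = min(cfg.k_clusters, Gi.n_accessions)
        clusters = qc_mod.cluster_accessions(pca, K=k_eff, seed=cfg.seed)
        ld = qc_mod.ld_decay(
            Gi, max_dist=cfg.ld_max_dist, r2_threshold=cfg.ld_r2_threshold
        )
        scores = pd.DataFrame(
            pca.scores,
            columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
        )
        scores.insert(0, "accession", Gi.accession_ids)
        scores["kmeans_cluster"] = clusters.kmeans_labels
        scores["hclust_cluster"] = clusters.hclust_labels
        _write_tsv(scores, outdir / "pca.tsv", "PC scores and cluster labels")
        _write_tsv(
            pd.DataFrame(K, index=Gi.accession_ids, columns=Gi.accession_ids)
            .reset_index()
            .rename(columns={"index": "accession"}),
            outdir / "kinship.tsv",
            "VanRaden genomic relationship matrix",
        )
        _write_tsv(ld, outdir / "ld_decay.tsv", "mean dosage r^2 per distance bin (bp, 1-based bins)")
        manifest["stages"]["qc"] = {
            **Gf.meta["qc"],
            "imputed_calls": Gi.meta.get("imputed", 0),
            "explained_fraction": [float(f) for f in pca.explained_fraction],
            "cluster_agreement_ari": clusters.agreement_ari,
            "ld_crossing_distance_bp": None
            if np.isnan(ld.attrs["crossing_distance"])
            else float(ld.attrs["crossing_distance"]),
        }
        if cfg.write_inputs:
            gio.write_vcf(Gi, outdir / "genotypes.filtered.vcf")
        return Gi, pca

    Gi, pca = run_qc()

    # ---- association scan ----------------------------------------------
    @_stage("scan")
    def scan():
        frames = []
        for trait in blue_table.values.columns:
            res = assoc.scan_trait(
                Gi, blue_table.values[trait].dropna(), trait, pca,
                n_pcs=cfg.n_pcs, alpha=cfg.alpha,
            )
            res.attrs.clear()
            frames.append(res)
        allres = pd.concat(frames, ignore_index=True)
        sig = allres.loc[allres["above_fdr"]].reset_index(drop=True)
        _write_tsv(
            sig, outdir / "associations.tsv",
            "FDR-significant single-marker associations (positions 1-based bp)",
        )
        manifest["stages"]["scan"] = {
            "n_tests_per_trait": int(Gi.n_snps),
            "bonferroni_lod": float(
                -np.log10(cfg.alpha / Gi.n_snps)
            ),
            "n_significant_fdr": int(len(sig)),
            "n_significant_bonferroni": int(sig["above_bonferroni"].sum()),
            "per_trait_fdr": sig.groupby("trait").size().to_dict(),
        }
        return allres, sig

    allres, sig = scan()

    # ---- marker suitability ---------------------------------------------
    @_stage("validate")
    def validate():
        acc_index = pd.Index(Gi.accession_ids)
        prof_rows, summ_rows, null_rows = [], [], []
        for t_i, trait in enumerate(sorted(sig["trait"].unique())):
            strait = sig.loc[sig["trait"] == trait]
            top = strait.loc[strait["lod"].idxmax()]
            j = int(np.flatnonzero(Gi.snp_ids == top["snp"])[0])
            y = blue_table.values[trait].reindex(acc_index)
            keep = y.notna().to_numpy()
            prof = markerval.rank_genotype_profile(
                y.to_numpy()[keep], Gi.dosages[keep, j],
                R=cfg.replicates, S=cfg.sample_size, seed=cfg.seed + 101 + t_i,
            )
            null = markerval.null_experiment(
                y.to_numpy()[keep], Gi.subset(accessions=keep),
                n_snps=min(cfg.n_null_snps, Gi.n_snps),
                R=cfg.replicates, S=cfg.sample_size, seed=cfg.seed + 201 + t_i,
            )
            prof_rows.append(
                pd.DataFrame(
                    {"trait": trait, "rank": np.arange(1, prof.S + 1),
                     "mean_dosage": prof.profile}
                )
            )
            summ_rows.append(
                {"trait": trait, "snp": top["snp"], "lod": float(top["lod"]),
                 "rho": prof.rho, "abs_rho": prof.abs_rho,
                 "population_mean_dosage": prof.population_mean_dosage,
                 "R": prof.R, "S": prof.S}
            )
            null_rows.append(
                {"trait": trait, "n_snps": null.n_snps,
                 "mean_rho": null.mean, "sd_rho": null.sd}
            )
        profiles = (
            pd.concat(prof_rows, ignore_index=True) if prof_rows else
            pd.DataFrame(columns=["trait", "rank", "mean_dosage"])
        )
        summary = pd.DataFrame(
            summ_rows, columns=["trait", "snp", "lod", "rho", "abs_rho",
                                "population_mean_dosage", "R", "S"]
        )
        nulls = pd.DataFrame(null_rows, columns=["trait", "n_snps", "mean_rho", "sd_rho"])
        _write_tsv(profiles, outdir / "profiles.tsv", "bootstrap rank-genotype profiles")
        _write_tsv(summary, outdir / "marker_summary.tsv", "top-SNP suitability statistic per trait")
        _write_tsv(nulls, outdir / "null_summary.tsv", "random-SNP null of the suitability statistic")
        manifest["stages"]["validate"] = {
            "abs_rho": {r["trait"]: float(r["abs_rho"]) for r in summ_rows},
            "replicates": cfg.replicates,
            "sample_size": cfg.sample_size,
        }
        return summary

    marker_summary = validate()

    # ---- candidate genes -------------------------------------------------
    @_stage("candidates")
    def candidates():
        hits = []
        for r in sig.itertuples():
            hits.append(
                genemap.find_candidates(
                    (r.chrom, int(r.pos)), genes,
                    primary_half=cfg.primary_half, fallback_half=cfg.fallback_half,
                    snp_id=r.snp, trait=r.trait, lod=float(r.lod),
                )
            )
        bounds = genes.set_index("gene_id") if len(genes) else None
        rows = []
        for h in hits:
            base = {
                "trait": h.trait, "chrom": h.chrom, "position": h.pos,
                "snp": h.snp_id, "lod": h.lod,
                "region_ini": h.region_start, "region_fin": h.region_end,
                "tier": h.tier,
            }
            if not h.genes:
                rows.append({**base, "gene_ini": "NA", "gene_fin": "NA",
                             "gene": "NA", "distance": "NA"})
            for g, d in h.genes:
                rows.append(
                    {**base,
                     "gene_ini": int(bounds.loc[g, "start"]),
                     "gene_fin": int(bounds.loc[g, "end"]),
                     "gene": g, "distance": d}
                )
        table = pd.DataFrame(
            rows, columns=["trait", "chrom", "position", "snp", "lod",
                           "region_ini", "region_fin", "gene_ini", "gene_fin",
                           "gene", "distance", "tier"]
        )
        _write_tsv(table, outdir / "candidates.tsv", "candidate genes per hit (1-based bp)")
        gio.write_bed_windows(hits, outdir / "hit_windows.bed")
        summary = genemap.summarize_hits(hits, primary_half=cfg.primary_half)
        manifest["stages"]["candidates"] = summary
        return hits

    hits = candidates()

    # ---- GO networks -----------------------------------------------------
    @_stage("go-net")
    def go_net():
        m = gonet.build_go_matrix(hits, go, min_total=cfg.go_min_total)
        counts = m.counts.copy()
        if not counts.empty:
            counts.insert(0, "trait", counts.index)
        _write_tsv(
            counts if not counts.empty else pd.DataFrame(columns=["trait"]),
            outdir / "go_matrix.tsv", "trait x GO occurrence counts (totals >= min_total)",
        )
        edges = []
        for cat in gonet.GO_CATEGORIES:
            try:
                edges.append(gonet.go_correlations(m, cat))
            except ValueError as exc:
                logger.info("go correlations skipped for %s: %s", cat, exc)
        groups = None
        if Gi.group_labels is not None:
            groups = np.where(Gi.group_labels == "jardin", "jardin", "breeding")
            pheno_nets = gonet.phenotype_correlations(
                blue_table.values.reindex(pd.Index(Gi.accession_ids)), groups
            )
            edges.extend(pheno_nets.values())
        edges = [e for e in edges if not e.empty]
        edge_table = (
            pd.concat(edges, ignore_index=True)
            if edges
            else pd.DataFrame(columns=["trait_a", "trait_b", "r", "edge_class", "source"])
        )
        _write_tsv(edge_table, outdir / "trait_network.tsv", "trait correlation edges")
        contrib = gonet.top_go_contributions(m)
        contrib_table = (
            pd.concat([c for c in contrib.values() if not c.empty], ignore_index=True)
            if any(not c.empty for c in contrib.values())
            else pd.DataFrame(columns=["go_id", "total", "category"])
        )
        _write_tsv(contrib_table, outdir / "go_contributions.tsv",
                   "top GO terms per category with per-trait shares")
        manifest["stages"]["go-net"] = {
            "go_terms_retained": int(m.counts.shape[1]) if not m.counts.empty else 0,
            "go_occurrences": int(m.counts.to_numpy().sum()) if not m.counts.empty else 0,
            "n_edges": int(len(edge_table)),
        }
        return m

    go_net()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
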