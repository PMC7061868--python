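"""End-to-end pipeline: filter -> windows -> statistics -> sweep calls ->
LD -> tree/PCA -> enrichment, with a JSON manifest.

All randomness flows from the seeds recorded in the configuration, and the
manifest carries no wall-clock state, so re-running an identical
configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .variants import (GenotypeMatrix, SiteFilterConfig, filter_sites,
                       read_popmap, read_vcf, sample_heterozygosity)
from .popgen import WindowSpec, compute_window_stats, genome_fst, make_windows
from .sweep import (annotate_regions, call_candidate_windows,
                    enrich_hypergeometric, merge_regions, permutation_cutoff,
                    read_pathway_map, write_regions_bed)
from .ld import compare_ld_decay, ld_decay
from .structure import (assign_membership, genotype_pca,
                        genotypes_to_sequences, k2p_distance_matrix, nj_tree,
                        read_q_matrix)

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("filter", "stats", "sweep", "ld", "tree", "pca", "membership",
              "enrich")


@dataclass
class PipelineConfig:
    """Paths, population labels and per-stage parameters for one run."""

    vcf: str
    popmap: str
    out_dir: str
    gff: str | None = None
    pathways: str | None = None
    q_matrix: str | None = None
    chrom_lengths: dict[str, int] | None = None

    pop_a: str = "H"
    pop_b: str = "S"

    # site filters
    min_maf: float = 0.05
    min_integrity: float = 0.5
    cluster_window_bp: int = 5
    cluster_max_snps: int = 2

    # windows / scan
    window_size_bp: int = 100_000
    window_step_bp: int = 10_000
    min_snps: int = 10
    alpha: float = 0.05
    n_perm: int = 200
    fst_rule_kind: str = "top_fraction"
    fst_rule_value: float = 0.05
    merge_gap_bp: int = 10_000
    ratio_cap: float = 100.0
    estimator: str = "hudson"

    # LD
    ld_bin_width_kb: float = 10.0
    ld_max_distance_kb: float = 1000.0
    ld_max_sites_per_chrom: int | None = 5000
    ld_n_perm: int = 200

    # tree / PCA / membership
    tree_bootstrap_n: int = 100
    tree_max_snps: int = 20_000
    het_policy: str = "random"
    pca_components: int = 10
    membership_threshold: float = 0.7

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def _preflight(cfg: PipelineConfig) -> None:
    missing = [p for p in (cfg.vcf, cfg.popmap, cfg.gff, cfg.pathways,
                           cfg.q_matrix)
               if p is not None and not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")


def _chrom_lengths(cfg: PipelineConfig, gm: GenotypeMatrix) -> dict[str, int]:
    if cfg.chrom_lengths:
        return dict(cfg.chrom_lengths)
    from cyvcf2 import VCF
    vcf = VCF(cfg.vcf)
    lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    present = pd.unique(gm.chrom)
    out = {c: int(lengths[c]) for c in present if lengths.get(c)}
    if len(out) < len(present):
        raise ValueError("chromosome lengths unavailable; provide "
                         "chrom_lengths in the config or VCF contig headers")
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written to
    ``out_dir/manifest.json``).  A stage failure is recorded in the manifest
    and later stages that do not depend on it still run."""
    _preflight(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "popsweep_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg.to_dict(),
        "stages": {},
        "row_counts": {},
        "warnings": {},
    }

    def done(stage: str, **extra) -> None:
        manifest["stages"][stage] = {"status": "ok", **extra}

    def failed(stage: str, exc: Exception) -> None:
        logger.error("stage %s failed: %s", stage, exc)
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}

    popmap = read_popmap(cfg.popmap)
    gm = read_vcf(cfg.vcf, popmap)
    manifest["row_counts"]["input_sites"] = gm.n_sites
    manifest["row_counts"]["samples"] = gm.n_samples

    # ---- filter ----
    if "filter" in cfg.stages:
        try:
            fcfg = SiteFilterConfig(cfg.min_maf, cfg.min_integrity,
                                    cfg.cluster_window_bp, cfg.cluster_max_snps)
            gm, report = filter_sites(gm, fcfg)
            report.write_tsv(out / "filter_report.tsv")
            het = sample_heterozygosity(gm)
            het.to_csv(out / "heterozygosity.tsv", sep="\t")
            manifest["row_counts"]["filtered_sites"] = gm.n_sites
            done("filter", removed=report.n_input - report.n_retained)
        except Exception as exc:
            failed("filter", exc)

    stats = None
    lengths = None
    if "stats" in cfg.stages:
        try:
            lengths = _chrom_lengths(cfg, gm)
            windows = make_windows(lengths, WindowSpec(cfg.window_size_bp,
                                                       cfg.window_step_bp))
            stats = compute_window_stats(gm, windows, cfg.pop_a, cfg.pop_b,
                                         estimator=cfg.estimator,
                                         ratio_cap=cfg.ratio_cap)
            stats.to_csv(out / "window_stats.tsv", sep="\t", index=False)
            manifest["row_counts"]["windows"] = len(stats)
            manifest["warnings"]["masked_windows"] = int(
                (stats["n_sites"] < cfg.min_snps).sum())
            done("stats",
                 genome_fst=genome_fst(gm, cfg.pop_a, cfg.pop_b, cfg.estimator),
                 mean_window_fst=float(np.nanmean(stats["fst"])))
        except Exception as exc:
            failed("stats", exc)

    if "sweep" in cfg.stages and stats is not None:
        try:
            windows = stats[["chrom", "start", "end"]]
            cutoffs = {}
            for pop, (num, den) in ((cfg.pop_a, (cfg.pop_b, cfg.pop_a)),
                                    (cfg.pop_b, (cfg.pop_a, cfg.pop_b))):
                cutoffs[pop] = permutation_cutoff(
                    gm, windows, num, den, n_perm=cfg.n_perm, alpha=cfg.alpha,
                    seed=cfg.seed, min_snps=cfg.min_snps,
                    ratio_cap=cfg.ratio_cap)
            candidates = call_candidate_windows(
                stats, cutoffs, (cfg.fst_rule_kind, cfg.fst_rule_value),
                min_snps=cfg.min_snps)
            n_regions = {}
            all_regions = []
            for pop, cand in candidates.items():
                regions = merge_regions(cand, cfg.merge_gap_bp, population=pop)
                if cfg.gff:
                    regions = annotate_regions(regions, cfg.gff)
                regions.to_csv(out / f"sweep_regions_{pop}.tsv", sep="\t",
                               index=False)
                write_regions_bed(regions, out / f"sweep_regions_{pop}.bed")
                n_regions[pop] = len(regions)
                all_regions.append(regions)
                manifest["row_counts"][f"sweep_regions_{pop}"] = len(regions)
            manifest["sweep_cutoffs"] = cutoffs
            done("sweep", n_regions=n_regions)

            if "enrich" in cfg.stages and cfg.gff and cfg.pathways:
                try:
                    pmap = read_pathway_map(cfg.pathways)
                    background = set().union(*pmap.values())
                    for pop, regions in zip(candidates, all_regions):
                        genes: set[str] = set()
                        for g in regions.get("gene_ids", []):
                            genes.update(x for x in str(g).split(",") if x)
                        genes &= background
                        enr = enrich_hypergeometric(genes, background, pmap)
                        enr.to_csv(out / f"enrichment_{pop}.tsv", sep="\t",
                                   index=False)
                        manifest["row_counts"][f"enrichment_{pop}"] = len(enr)
                    done("enrich")
                except Exception as exc:
                    failed("enrich", exc)
        except Exception as exc:
            failed("sweep", exc)

    if "ld" in cfg.stages:
        try:
            for pop in (cfg.pop_a, cfg.pop_b):
                curve = ld_decay(gm, pop, cfg.ld_bin_width_kb,
                                 cfg.ld_max_distance_kb,
                                 cfg.ld_max_sites_per_chrom)
                curve.write_tsv(out / f"ld_decay_{pop}.tsv")
                manifest["row_counts"][f"ld_bins_{pop}"] = int(
                    (curve.bins["n_pairs"] > 0).sum())
            cmp_res = compare_ld_decay(
                gm, cfg.pop_a, cfg.pop_b, cfg.ld_bin_width_kb,
                cfg.ld_max_distance_kb, n_perm=cfg.ld_n_perm, seed=cfg.seed,
                max_sites_per_chrom=cfg.ld_max_sites_per_chrom)
            (out / "ld_comparison.json").write_text(
                json.dumps(cmp_res, indent=2) + "\n")
            done("ld", **cmp_res)
        except Exception as exc:
            failed("ld", exc)

    if "tree" in cfg.stages:
        try:
            from .ld import thin_site_index
            sub = gm
            if gm.n_sites > cfg.tree_max_snps:
                per_chrom = max(1, cfg.tree_max_snps
                                // max(1, len(pd.unique(gm.chrom))))
                sub = gm.take_sites(thin_site_index(gm, per_chrom))
            seqs = genotypes_to_sequences(sub, cfg.het_policy, seed=cfg.seed)
            dm = k2p_distance_matrix(seqs, sub.samples)
            dm.write_phylip(out / "distances.phylip")
            tree = nj_tree(dm, seqs, bootstrap_n=cfg.tree_bootstrap_n,
                           seed=cfg.seed)
            (out / "nj_tree.nwk").write_text(str(tree))
            done("tree", n_snps_used=sub.n_sites)
        except Exception as exc:
            failed("tree", exc)

    if "pca" in cfg.stages:
        try:
            pca = genotype_pca(gm, cfg.pca_components)
            pca.write_tsv(out / "pca_scores.tsv")
            manifest["pca_variance_fraction"] = [
                float(v) for v in pca.variance_fraction]
            done("pca")
        except Exception as exc:
            failed("pca", exc)

    if "membership" in cfg.stages and cfg.q_matrix:
        try:
            q = read_q_matrix(cfg.q_matrix)
            assign = assign_membership(q, cfg.membership_threshold)
            assign.to_csv(out / "membership.tsv", sep="\t")
            done("membership")
        except Exception as exc:
            failed("membership", exc)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n")
    return manifest
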