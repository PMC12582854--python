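"""End-to-end synthetic pipeline: simulate, filter, map, benchmark, wavelets."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .demography import bottleneck_decline, equilibrium
from .divmut import (
    build_accessibility_mask,
    rate_conversion_table,
    windowed_divergence,
    windowed_diversity,
)
from .genome import GenomeSpec, TrueRateTrack
from .intervals import AccessibilityMask
from .ldrec import (
    BenchmarkConfig,
    PEDIGREE_MAP_LENGTH_CM,
    aggregate_windows,
    benchmark_estimator,
    compare_motif_rates,
    estimate_map,
    filter_outlier_windows,
    rescale_map,
)
from .synthdata import place_motifs, simulate_annotations, simulate_haplotypes, simulate_substitutions
from .twolocus import build_two_locus_table
from .variants import PolymorphismSet, filter_hwe, filter_snp_clusters
from .wavescale import bin_feature_tracks, kendall_detail_correlations, scale_linear_models, split_halves

logger = logging.getLogger("ratemaps")

# Table 1 inputs: generation times (years), divergence-time bounds (years),
# pedigree-based mutation rates (per bp per generation)
TABLE1_G_YEARS = (3.0, 5.0)
TABLE1_T_YEARS = (54.9e6, 74.7e6)
TABLE1_MU_PEDIGREE = (4.0e-9, 1.1e-8, 2.0e-8)
MEAN_NEUTRAL_DIVERGENCE = 0.043


@dataclass
class PipelineConfig:
    """All knobs for a synthetic end-to-end run (desk-scale defaults)."""

    outdir: str = "results/pipeline"
    seed: int = 1
    scaffold_length: int = 5_000_000
    gc: float = 0.41
    # substitutions: mean rate and branch length chosen so divergence ~ 0.043
    mu_true: float = 2.36e-9
    branch_gens: float = 54.9e6 / 3.0
    mu_track_windows: int = 10
    # haplotype panel
    n_diploids: int = 5
    rec_rate_cm_mb: float = 0.85
    demography: str = "bottleneck_decline"
    rec_track_windows: int = 20
    rec_track_sigma: float = 0.5
    # annotations / motifs
    exon_density: float = 0.05
    mean_exon_len: int = 1500
    n_motifs: int = 40
    motif_enrichment: float = 8.0
    # analysis windows
    flank: int = 10_000
    div_window: int = 100_000
    div_step: int = 50_000
    rec_window: int = 50_000
    pair_span: int = 30
    mu_for_conversion: float = 0.4e-8
    target_cm: float | None = None  # default: pedigree length scaled to genome
    fold: float = 100.0
    table_reps: int = 3_000
    alpha: float = 0.01
    benchmark: bool = False
    benchmark_region: int = 200_000
    benchmark_replicates: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _demography(name: str):
    if name == "bottleneck_decline":
        return bottleneck_decline()
    if name == "equilibrium":
        return equilibrium()
    raise ValueError(f"unknown demography {name!r}")


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage on synthetic data and write the artifact bundle.

    Stages: simulate inputs -> SNP filters -> divergence/mutation maps ->
    LD recombination map (filter, rescale, aggregate) -> motif comparison ->
    wavelet reports (+ optional estimator benchmark). Any stage failure
    aborts with a stage-named diagnostic. Reruns with the same config are
    byte-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    artifacts: dict[str, object] = {}
    stage = "setup"
    try:
        stage = "simulate"
        L = config.scaffold_length
        spec = GenomeSpec.single(L, gc=config.gc)
        scaf = spec.names[0]
        model = _demography(config.demography)
        # ground-truth mutation-rate track: log-normal variation around mu_true
        k = config.mu_track_windows
        bounds = np.linspace(0, L, k + 1)
        mu_rates = config.mu_true * np.exp(rng.normal(0, 0.25, size=k))
        mu_track = TrueRateTrack(scaf, bounds, mu_rates)
        # heterogeneous truth recombination landscape (log-normal by window)
        kr = config.rec_track_windows
        rec_bounds = np.linspace(0, L, kr + 1)
        sigma = config.rec_track_sigma
        rec_rates = config.rec_rate_cm_mb * 1e-8 * np.exp(
            rng.normal(-sigma**2 / 2, sigma, size=kr)
        )
        rec_track = TrueRateTrack(scaf, rec_bounds, rec_rates)
        subs = simulate_substitutions(spec, mu_track, config.branch_gens, seed=config.seed)
        panel = simulate_haplotypes(
            model,
            config.mu_for_conversion,
            rec_track,
            2 * config.n_diploids,
            L,
            seed=config.seed + 1,
        )
        annots = simulate_annotations(spec, config.exon_density, config.mean_exon_len, seed=config.seed + 2)
        motifs = place_motifs(spec, rec_track, config.motif_enrichment, config.n_motifs, seed=config.seed + 3)
        io.write_substitutions_bed(out / "substitutions.bed", subs)
        io.write_gff3(out / "annotations.gff3", annots)
        io.write_motifs_bed(out / "motifs.bed", motifs)
        logger.info("simulate: %d substitutions, %d SNPs, %d exons", subs.total(), panel.n_sites, annots.get(scaf).shape[0])

        stage = "filter"
        snps = PolymorphismSet.from_panel(panel)
        snps, n_cluster = filter_snp_clusters(snps)
        snps, n_hwe = filter_hwe(snps)
        io.write_vcf(out / "snps.filtered.vcf", snps)
        logger.info("filter: removed %d cluster SNPs, %d HWE SNPs", n_cluster, n_hwe)

        stage = "divmut"
        callable_mask = AccessibilityMask.full({scaf: L})
        mask = build_accessibility_mask(
            annots, callable_mask, flank=config.flank, scaffold_lengths={scaf: L}
        )
        divmap = windowed_divergence(
            subs, {scaf: snps.positions}, mask, config.div_window, config.div_step,
            scaffold_lengths={scaf: L},
        )
        # per-generation mutation rate: divergence over the branch length
        mut_map = divmap.table.copy()
        mut_map["mu"] = mut_map["d"] / config.branch_gens
        io.write_map_table(out / "mutation_rate_map.tsv", mut_map)
        io.write_bedgraph(out / "divergence.bedgraph", divmap.table, "d")
        table1 = rate_conversion_table(
            MEAN_NEUTRAL_DIVERGENCE, list(TABLE1_G_YEARS), list(TABLE1_T_YEARS), list(TABLE1_MU_PEDIGREE)
        )
        io.write_map_table(out / "table1_replica.tsv", table1)
        logger.info("divmut: genome-wide d = %.4f", divmap.genome_wide_d())

        stage = "ldrec"
        table = build_two_locus_table(
            2 * config.n_diploids, model, reps=config.table_reps, seed=config.seed + 4
        )
        fine_map = estimate_map(
            snps.to_panel(), table, config.mu_for_conversion,
            window=config.rec_window, pair_span=config.pair_span,
        )
        fine_map, removed = filter_outlier_windows(fine_map, config.fold)
        target = config.target_cm
        if target is None:
            # pedigree map length prorated to the synthetic genome size
            target = PEDIGREE_MAP_LENGTH_CM * L / 1e6 / 2_000
        rescaled, factor = rescale_map(fine_map, target)
        coarse = aggregate_windows(rescaled, window=1_000_000, step=500_000)
        io.write_map_table(out / "recombination_map.fine.tsv", rescaled.with_cumulative())
        io.write_map_table(out / "recombination_map.1Mb.tsv", coarse.table)
        motif_report = compare_motif_rates(rescaled, motifs)
        pd.DataFrame([asdict(motif_report)]).to_csv(out / "motif_ttest.tsv", sep="\t", index=False)
        logger.info("ldrec: rescale factor %.3f, %d outlier windows removed", factor, len(removed))

        stage = "wavescale"
        pi = windowed_diversity(snps.to_panel(), mask, 1000)
        div1kb = windowed_divergence(subs, {scaf: snps.positions}, mask, 1000, scaffold_lengths={scaf: L})
        tracks = bin_feature_tracks(
            scaf, L,
            sequence=spec.sequence(scaf, seed=config.seed + 5),
            exons=annots.get(scaf),
            pi=pi, divergence=div1kb.table, recombination=rescaled.table,
            mask=mask,
        )
        halves = {name: split_halves(tr) for name, tr in tracks.items()}
        reports = []
        for side, idx in (("left", 0), ("right", 1)):
            dec = {name: h[idx] for name, h in halves.items()}
            rep = kendall_detail_correlations(dec, alpha=config.alpha)
            rep.insert(0, "half", side)
            reports.append(rep)
        kendall_report = pd.concat(reports, ignore_index=True)
        io.write_map_table(out / "wavelet_kendall.tsv", kendall_report)
        lm_dec = {name: h[0] for name, h in halves.items()}
        lm_report = scale_linear_models(lm_dec)
        io.write_map_table(out / "wavelet_linear_models.tsv", lm_report)

        if config.benchmark:
            stage = "benchmark"
            bench = benchmark_estimator(
                BenchmarkConfig(
                    replicates=config.benchmark_replicates,
                    region_length=config.benchmark_region,
                    table_reps=config.table_reps,
                ),
                seed=config.seed + 6,
            )
            io.write_map_table(out / "benchmark.tsv", bench)
            artifacts["benchmark"] = bench
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    log = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "genome_wide_d": divmap.genome_wide_d(),
        "rescale_factor": factor,
        "removed_outlier_windows": int(len(removed)),
        "snp_filters": {"cluster": int(n_cluster), "hwe": int(n_hwe)},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    artifacts.update(
        divergence=divmap, mutation_map=mut_map, table1=table1,
        fine_map=rescaled, coarse_map=coarse, motif_report=motif_report,
        kendall=kendall_report, linear_models=lm_report, run_log=log,
    )
    return artifacts


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
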