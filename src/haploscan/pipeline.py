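"""End-to-end orchestration: simulate -> filter -> annotate -> SV/motif/expression.

One seeded configuration drives every stage; re-running with the same
configuration reproduces every output byte for byte.  Each output table
carries a header comment naming the seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cascade import run_indel_cascade, run_snv_cascade
from .expression import expression_phenotype_trend, fold_changes, fold_regression
from .genome import robo1_model
from .motifs import compare_alleles, comparison_table, find_consensus
from .pooled import aaf_consistency, expected_pool_aaf
from .simulate import (
    SimulationConfig,
    demo_allele_pair,
    demo_gain_table,
    emit_ct_table,
    emit_individual_callsets,
    emit_phenotype_table,
    emit_pooled_callset,
    emit_read_pairs,
    frequency_panel,
    generate_truth,
    indel_contexts,
    known_catalog,
    panel_frame,
    catalog_frame,
    plant_svs,
    truth_table,
)
from .svscan import candidates_table, pairs_from_frame, scan_svs
from .vcfio import write_pool_vcf, write_tsv, write_vcf

log = logging.getLogger("haploscan")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "haploscan_run"
    upstream_windows: Sequence[int] = (1_000_000, 5_000_000)
    max_maf: float = 0.05
    kmer_threshold: float = 0.45
    sv_z_threshold: float = 4.0
    sv_min_support: int = 3
    ct_noise_sd: float = 0.15
    knockdown_fold: float = 0.5
    n_cell_lines: int = 6
    n_phenotype_subjects: int = 20

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "region" in sim_raw:
            from .genome import GenomeInterval

            sim_raw["region"] = GenomeInterval(**sim_raw["region"])
        return cls(sim=SimulationConfig(**sim_raw), **raw)


@dataclass
class RunReport:
    """Per-stage summary of one pipeline run."""

    seed: int
    version: str
    snv_step_counts: list
    snv_survivors: pd.DataFrame
    indel_step_counts: list
    sv_candidates: pd.DataFrame
    motif_count_difference: int
    consensus_offsets: list
    fold_change_table: pd.DataFrame
    trend_rho: float
    trend_direction: str


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage, writing tables under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.sim.seed
    stamp = f"haploscan {__version__} seed={seed}"
    t0 = time.perf_counter()

    # -- simulate ------------------------------------------------------------
    truth = generate_truth(config.sim)
    calls_a, calls_b = emit_individual_callsets(truth, config.sim)
    pooled = emit_pooled_callset(truth, config.sim)
    write_tsv(truth_table(truth), str(out / "truth.tsv"), stamp)
    write_vcf(calls_a, str(out / "individual_a.vcf"))
    write_vcf(calls_b, str(out / "individual_b.vcf"))
    write_pool_vcf(pooled, str(out / "pool.vcf"))
    write_tsv(panel_frame(truth), str(out / "frequency_panel.tsv"), stamp)
    write_tsv(catalog_frame(truth), str(out / "catalog.tsv"), stamp)
    log.info("simulate: %d truth records (%.2fs)", len(truth), time.perf_counter() - t0)

    # -- filter cascade ------------------------------------------------------
    panel = frequency_panel(truth)
    catalog = known_catalog(truth)
    gene = robo1_model()
    snv_a = _snvs_only(calls_a)
    snv_b = _snvs_only(calls_b)
    snv_result = run_snv_cascade(
        snv_a, snv_b, pooled, config.sim.region, panel, [catalog],
        gene=gene, upstream_width=max(config.upstream_windows), max_maf=config.max_maf,
    )
    indel_result = run_indel_cascade(
        _indels_only(calls_a), _indels_only(calls_b), pooled, config.sim.region,
        panel, [catalog], contexts=indel_contexts(truth), gene=gene,
        upstream_width=max(config.upstream_windows), max_maf=config.max_maf,
    )
    write_tsv(snv_result.counts_table(), str(out / "snv_step_counts.tsv"), stamp)
    write_tsv(snv_result.survivor_table(), str(out / "snv_survivors.tsv"), stamp)
    write_tsv(snv_result.provenance_table(), str(out / "snv_provenance.tsv"), stamp)
    write_tsv(indel_result.counts_table(), str(out / "indel_step_counts.tsv"), stamp)
    write_tsv(indel_result.survivor_table(), str(out / "indel_survivors.tsv"), stamp)

    # -- pooled-model consistency of survivors -------------------------------
    expected = expected_pool_aaf(config.sim.n_pool_carriers, "het")
    consistency_rows = []
    for s in snv_result.survivors:
        if s.depth:
            res = aaf_consistency(
                round(s.aaf * s.depth), s.depth, expected, seed=seed
            )
            consistency_rows.append(
                {"chrom": s.key[0], "pos": s.key[1], "depth": s.depth,
                 "aaf": round(s.aaf, 2), "lower": round(res.lower, 3),
                 "upper": round(res.upper, 3), "inside": res.inside}
            )
    write_tsv(pd.DataFrame(consistency_rows), str(out / "aaf_consistency.tsv"), stamp)

    # -- SV scan -------------------------------------------------------------
    svs = plant_svs(config.sim)
    pair_frame = emit_read_pairs(config.sim, svs)
    write_tsv(pair_frame.drop(columns=["origin"]), str(out / "read_pairs.tsv"), stamp)
    pairs = pairs_from_frame(pair_frame)
    _, candidates = scan_svs(
        pairs, z_threshold=config.sv_z_threshold, min_support=config.sv_min_support
    )
    write_tsv(candidates_table(candidates), str(out / "sv_candidates.tsv"), stamp)

    # -- motif scan ----------------------------------------------------------
    allele_pair = demo_allele_pair()
    table = demo_gain_table(allele_pair, threshold=config.kmer_threshold)
    comparison = compare_alleles(allele_pair, table)
    write_tsv(
        comparison_table(comparison, allele_pair), str(out / "motif_comparison.tsv"), stamp
    )
    consensus = find_consensus(allele_pair.ref_seq)

    # -- expression ----------------------------------------------------------
    ct = emit_ct_table(
        {"LHX2": config.knockdown_fold, "ROBO1": 0.7},
        n_lines=config.n_cell_lines, seed=seed, noise_sd=config.ct_noise_sd,
    )
    write_tsv(ct, str(out / "ct_table.tsv"), stamp)
    fc = fold_changes(ct)
    write_tsv(fc, str(out / "fold_changes.tsv"), stamp)
    wide = fc.pivot(index="line", columns="gene", values="fold")
    regression = fold_regression(wide["LHX2"], wide["ROBO1"])
    pheno = emit_phenotype_table(config.n_phenotype_subjects, seed=seed)
    write_tsv(pheno, str(out / "phenotype.tsv"), stamp)
    trend = expression_phenotype_trend(pheno, seed=seed)

    report = RunReport(
        seed=seed,
        version=__version__,
        snv_step_counts=snv_result.steps,
        snv_survivors=snv_result.survivor_table(),
        indel_step_counts=indel_result.steps,
        sv_candidates=candidates_table(candidates),
        motif_count_difference=comparison.count_difference,
        consensus_offsets=consensus,
        fold_change_table=fc,
        trend_rho=trend.rho,
        trend_direction=trend.direction,
    )
    summary = {
        "seed": seed,
        "version": __version__,
        "config": _config_echo(config),
        "snv_step_counts": snv_result.steps,
        "indel_step_counts": indel_result.steps,
        "n_snv_survivors": len(snv_result.survivors),
        "n_sv_candidates": len(candidates),
        "motif_count_difference": comparison.count_difference,
        "consensus_offsets": consensus,
        "fold_regression": {"slope": regression.slope, "r": regression.r},
        "trend": {"rho": trend.rho, "direction": trend.direction},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("run complete (%.2fs)", time.perf_counter() - t0)
    return report


def _config_echo(config: RunConfig) -> dict:
    d = asdict(config)
    d.pop("out_dir")  # not part of the scientific configuration
    d["upstream_windows"] = list(config.upstream_windows)
    d["sim"]["sv_sizes"] = list(config.sim.sv_sizes)
    d["sim"]["region"] = asdict(config.sim.region)
    return d


def _snvs_only(callset):
    from .calls import CallSet

    return CallSet(
        (c for c in callset if not c.is_indel), callset.sample, callset.platform
    )


def _indels_only(callset):
    from .calls import CallSet

    return CallSet(
        (c for c in callset if c.is_indel), callset.sample, callset.platform
    )
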