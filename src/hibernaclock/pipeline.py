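"""End-to-end orchestration of the seasonal methylation analysis.

A single :class:`PipelineConfig` drives all stages on a synthetic cohort
(or user-supplied files in the same formats): clock fitting and the seasonal
age-acceleration test, DMP detection, genomic-region statistics,
functional-element permutation enrichment and gene-set overlaps.  Every
stage writes plain-text tables into a run directory plus one
machine-readable ``summary.json``; the run is byte-reproducible for a fixed
seed.  The top-level seed fans out to per-stage seeds via a stable hash of
the stage name, so stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hibernaclock import annotation as ann
from hibernaclock import clock as clk
from hibernaclock import dmp as dmpmod
from hibernaclock import enrichment as enr
from hibernaclock import io as hio
from hibernaclock import synthetic as syn

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed below 2^31."""
    return (seed ^ zlib.crc32(stage.encode())) % (2 ** 31 - 1)


@dataclass
class PipelineConfig:
    """Thresholds, clock options and the synthetic-cohort configuration."""

    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)
    fdr_threshold: float = 0.05
    enrichment_fdr: float = 0.01
    n_perm: int = 1000
    proximity_bp: int = 1000
    clock_alpha: float = 0.5
    clock_folds: int = 5
    clock_training_individuals: int = 60
    eforge_cap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "enrichment_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")


def _training_cohort(config: PipelineConfig):
    """A separate known-aged, active-season reference cohort for clock training.

    Emulates training a species clock on previously profiled known-aged
    animals disjoint from the study individuals.
    """
    cfg = syn.SyntheticConfig(**{
        **config.synthetic.to_dict(),
        "age_range": tuple(config.synthetic.age_range),
        "n_individuals": config.clock_training_individuals,
        "frac_paired": 0.0,
        "frac_wild": 0.0,
        "seed": stage_seed(config.seed, "clock-training"),
        "probe_seed": (config.synthetic.probe_seed
                       if config.synthetic.probe_seed is not None
                       else config.synthetic.seed),
    })
    cohort = syn.generate_cohort(cfg)
    betas, _ = syn.generate_beta_matrix(cohort, cfg)
    return cohort, betas


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run all stages and write their outputs under ``outdir``.

    Any stage failure aborts with the failing stage named; outputs of
    completed stages are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("hibernaclock")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    summary: dict = {"seed": config.seed, "stages": {}}
    stage = "setup"
    try:
        t0 = time.time()
        logger.info("pipeline start, seed=%d", config.seed)

        stage = "synthetic_data"
        scfg = config.synthetic
        cohort = syn.generate_cohort(scfg)
        betas, truth = syn.generate_beta_matrix(cohort, scfg)
        genome = syn.generate_genome_annotation(scfg)
        gene_sets = syn.generate_gene_sets(genome, scfg)
        element_maps = syn.generate_element_maps(genome, scfg)
        hio.write_sample_sheet(cohort, out / "sample_sheet.csv")
        hio.write_beta_matrix(betas, out / "beta_matrix.csv")
        hio.write_probe_bed(genome.probes, out / "probes.bed")
        hio.write_gene_models(genome, out / "genes.tsv")
        hio.write_gmt(gene_sets, out / "gene_sets.gmt")
        hio.write_element_maps(element_maps, out / "element_maps.tsv")
        hio.write_config(scfg, out / "synthetic_config.yaml")
        hio.write_table(truth.dmp_sites, out / "truth_dmp_sites.tsv")
        summary["stages"][stage] = {
            "n_samples": len(cohort),
            "n_individuals": int(cohort["individual_id"].nunique()),
            "n_probes": int(betas.shape[0]),
            "elapsed_s": round(time.time() - t0, 2)}

        stage = "clock"
        t1 = time.time()
        train_cohort, train_betas = _training_cohort(config)
        exact = ~train_cohort["age_is_minimum"]
        model = clk.fit_clock(
            train_betas[train_cohort.loc[exact, "sample_id"]],
            train_cohort.loc[exact, "age_years"],
            mixing=config.clock_alpha, cv_folds=config.clock_folds,
            seed=stage_seed(config.seed, "clock"))
        model.save(out / "clock_model.tsv")
        pred = clk.predict_ages(model, betas, cohort)
        hio.write_table(pred, out / "age_predictions.tsv")
        r2, mae = clk.clock_fit_metrics(pred)
        season = clk.test_season_effect(pred)
        summary["stages"][stage] = {
            "r_squared": r2, "mae_years": mae,
            "season_effect_years": season.season_effect,
            "season_se_years": season.standard_error,
            "season_F": season.F_statistic,
            "season_df": [season.df_num, season.df_den],
            "season_p": season.p_value,
            "n_nonzero_coefficients": len(model.nonzero_coefficients),
            "elapsed_s": round(time.time() - t1, 2)}

        stage = "dmp_detection"
        t1 = time.time()
        dmp_table = dmpmod.detect_dmps(betas, cohort, fdr=config.fdr_threshold)
        hio.write_table(dmp_table, out / "dmp_table.tsv")
        dirs = dmpmod.direction_summary(dmp_table)
        summary["stages"][stage] = {**dirs,
                                    "elapsed_s": round(time.time() - t1, 2)}

        stage = "genome_annotation"
        t1 = time.time()
        probe_annot = ann.annotate_probes(genome)
        hio.write_table(probe_annot, out / "probe_annotation.tsv")
        dmp_ids = dmp_table.loc[dmp_table["direction"] != "none", "probe_id"]
        region_table, omnibus = ann.region_enrichment(dmp_ids, probe_annot)
        hio.write_table(region_table, out / "region_enrichment.tsv")
        nonsig = dmp_table.loc[dmp_table["direction"] == "none", "probe_id"]
        tss_cmp = (ann.tss_distance_comparison(dmp_ids, nonsig, probe_annot)
                   if len(dmp_ids) >= 2 else None)
        n_hit, n_total = ann.scaffold_coverage(dmp_ids, genome)
        summary["stages"][stage] = {
            "region_omnibus": omnibus,
            "tss_distance": tss_cmp,
            "scaffolds_hit": n_hit, "scaffolds_total": n_total,
            "elapsed_s": round(time.time() - t1, 2)}

        stage = "element_enrichment"
        t1 = time.time()
        if len(dmp_ids) == 0:
            logger.info("no DMPs: skipping enrichment stages")
            summary["stages"][stage] = {"skipped": "no DMPs"}
            summary["stages"]["gene_sets"] = {"skipped": "no DMPs"}
        else:
            enrich_results = {}
            for direction in ("winter-up", "winter-down"):
                sub = dmp_table[dmp_table["direction"] == direction]
                sub = sub.nsmallest(config.eforge_cap, "p_raw")
                if len(sub) == 0:
                    continue
                res = enr.permutation_enrichment(
                    sub["probe_id"], list(probe_annot["probe_id"]),
                    element_maps, genome.probes, n_perm=config.n_perm,
                    proximity_bp=config.proximity_bp,
                    seed=stage_seed(config.seed, f"enrich-{direction}"))
                hio.write_table(res, out / f"element_enrichment_{direction}.tsv")
                enrich_results[direction] = {
                    "n_significant_maps": int(
                        (res["p_by"] < config.enrichment_fdr).sum()),
                    "top_maps": res.nsmallest(3, "p_emp")["map"].tolist()}
            summary["stages"][stage] = {**enrich_results,
                                        "elapsed_s": round(time.time() - t1, 2)}

            stage = "gene_sets"
            t1 = time.time()
            gene_dirs = enr.assign_gene_directions(dmp_table, probe_annot)
            hio.write_table(gene_dirs, out / "gene_directions.tsv")
            hib_genes = gene_dirs.loc[gene_dirs["direction"] != "none", "gene"]
            overlaps = {}
            for set_name in ("immunity", "longevity"):
                if set_name not in gene_sets or len(hib_genes) == 0:
                    continue
                table, chi, p_chi = enr.overlap_test(
                    hib_genes, gene_sets[set_name], gene_sets["background"],
                    method="chi_sq")
                _, _, p_fet = enr.overlap_test(
                    hib_genes, gene_sets[set_name], gene_sets["background"],
                    method="fisher")
                overlaps[set_name] = {
                    "table": [table.a, table.b, table.c, table.d],
                    "chi_sq": chi, "p_chi": p_chi, "p_fisher": p_fet}
            summary["stages"][stage] = {
                "n_hibernation_genes": int(len(hib_genes)),
                "overlaps": overlaps,
                "elapsed_s": round(time.time() - t1, 2)}

        summary["elapsed_s"] = round(time.time() - t0, 2)
        summary["status"] = "ok"
        hio.write_json(summary, out / "summary.json")
        logger.info("pipeline done in %.1fs", time.time() - t0)
        return out
    except Exception as exc:
        summary["status"] = "failed"
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        hio.write_json(summary, out / "summary.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def clock_recovery_experiment(seed: int, n_training: int = 60,
                              config: syn.SyntheticConfig | None = None) -> dict:
    """Train a clock on a disjoint known-aged cohort, apply it to a paired
    seasonal cohort sharing the same array biology, and score recovery.

    Returns predicted-vs-true-age r², clock accuracy versus recorded ages,
    and the seasonal age-acceleration estimate with its standard error.
    """
    from scipy import stats as sps

    base = config if config is not None else syn.SyntheticConfig()
    probe_seed = stage_seed(seed, "recovery-array")
    train_cfg = syn.SyntheticConfig(**{
        **base.to_dict(), "age_range": tuple(base.age_range),
        "n_individuals": n_training, "frac_paired": 0.0, "frac_wild": 0.0,
        "seed": stage_seed(seed, "recovery-train"), "probe_seed": probe_seed})
    test_cfg = syn.SyntheticConfig(**{
        **base.to_dict(), "age_range": tuple(base.age_range),
        "seed": stage_seed(seed, "recovery-test"), "probe_seed": probe_seed})

    tr_sheet = syn.generate_cohort(train_cfg)
    tr_betas, _ = syn.generate_beta_matrix(tr_sheet, train_cfg)
    model = clk.fit_clock(tr_betas, tr_sheet["age_years"], cv_folds=5,
                          seed=stage_seed(seed, "recovery-fit"))
    te_sheet = syn.generate_cohort(test_cfg)
    te_betas, truth = syn.generate_beta_matrix(te_sheet, test_cfg)
    pred = clk.predict_ages(model, te_betas, te_sheet)
    true_age = truth.sample_true_ages[pred["sample_id"]].to_numpy()
    r2_true = float(sps.pearsonr(true_age, pred["predicted_age"])[0] ** 2)
    r2, mae = clk.clock_fit_metrics(pred)
    season = clk.test_season_effect(pred)
    return {"r_squared_true_age": r2_true, "r_squared": r2,
            "mae_years": mae,
            "season_effect_years": season.season_effect,
            "season_se_years": season.standard_error,
            "season_p": season.p_value,
            "planted_offset_years": test_cfg.seasonal_age_offset,
            "n_samples": len(pred)}


def summarize(run_dir) -> dict:
    """Load a run's summary and render a short text report.

    Missing stages are marked absent rather than raising.
    """
    run = Path(run_dir)
    summary_path = run / "summary.json"
    report: dict = {"run_dir": str(run)}
    if summary_path.exists():
        report.update(hio.read_json(summary_path))
    else:
        report["status"] = "absent"
    stages = report.get("stages", {})
    lines = [f"run: {run}", f"status: {report.get('status', 'absent')}"]
    clock = stages.get("clock")
    if clock:
        lines.append(
            f"clock: r^2={clock['r_squared']:.3f} MAE={clock['mae_years']:.3f}y; "
            f"season effect {clock['season_effect_years']:+.2f} ± "
            f"{clock['season_se_years']:.2f} y (F={clock['season_F']:.2f}, "
            f"p={clock['season_p']:.3g})")
    dmp = stages.get("dmp_detection")
    if dmp:
        lines.append(
            f"DMPs: {dmp['n_dmps']} ({dmp['n_winter_up']} winter-up, "
            f"{dmp['n_winter_down']} winter-down; "
            f"proportion up={dmp.get('proportion_up', float('nan')):.3f})")
    ga = stages.get("genome_annotation")
    if ga and ga.get("region_omnibus"):
        om = ga["region_omnibus"]
        lines.append(f"regions: omnibus chi^2={om['chi_sq']:.1f} "
                     f"(df={om['df']}, p={om['p']:.3g}); scaffolds "
                     f"{ga['scaffolds_hit']}/{ga['scaffolds_total']}")
    gs = stages.get("gene_sets")
    if gs and gs.get("overlaps"):
        for name, ov in gs["overlaps"].items():
            lines.append(f"{name} overlap: a={ov['table'][0]} "
                         f"chi^2={ov['chi_sq']:.2f} p={ov['p_chi']:.3g}")
    for name in ("clock", "dmp_detection", "genome_annotation",
                 "element_enrichment", "gene_sets"):
        if name not in stages:
            lines.append(f"{name}: absent")
    report["text"] = "\n".join(lines)
    return report
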