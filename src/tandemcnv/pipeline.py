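"""End-to-end orchestration: simulate → normalize → calibrate → V_ST → scans.

`run_all` executes the fixed stage order on a synthetic study with planted
truth, writes every intermediate table as TSV, logs a per-stage funnel
(features in → out) and drops the resolved configuration next to the
outputs so a run is reproducible from its artifact directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, calibration, counts, popgen_evolution, synthetic_data
from .io_formats import (
    ValidationError,
    write_count_matrix,
    write_probe_bed,
    write_records,
    write_sample_table,
)
from .probe_design import build_windows

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Every tunable threshold with its standard default, plus simulation sizes."""

    seed: int = 0
    # counts QC
    cv_threshold: float = 0.1
    deviation: float = 0.30
    min_individuals: int = 2
    min_mean_count: float = 100.0
    literal_normalization: bool = False
    # SNP filters & LD
    maf_min: float = 0.1
    hwe_alpha: float = 0.05
    ld_flank_bp: int = 250_000
    ld_min_identity: float = 95.0
    ld_permutations: int = 10_000
    # expression / methylation
    cis_flank_bp: int = 500_000
    expr_mean_min: float = 6.0
    expr_iqr_min: float = 0.25
    expr_permutations: int = 10_000
    meth_top_quantile: float = 0.98
    meth_slope_min: float = 0.1
    meth_perm_alpha: float = 0.01
    meth_per_pop_alpha: float = 0.05
    meth_permutations: int = 1_000
    # popgen
    vst_threshold: float = 0.2
    gain_min_identity: float = 95.0
    loss_min_identity: float = 98.0
    fold_flag: float = 3.0
    # simulation sizes
    n_test_probes: int = 12
    n_snps_per_probe: int = 25
    n_transcripts_per_probe: int = 6
    n_cpgs_per_probe: int = 12
    meth_pool_size: int = 2_000
    planted: dict = field(default_factory=dict)  # probe_id -> {tag_r2, expr_slope, meth_slope}

    def validate(self) -> None:
        positive = {
            "cv_threshold": self.cv_threshold,
            "deviation": self.deviation,
            "min_individuals": self.min_individuals,
            "maf_min": self.maf_min,
            "hwe_alpha": self.hwe_alpha,
            "ld_flank_bp": self.ld_flank_bp,
            "cis_flank_bp": self.cis_flank_bp,
            "ld_permutations": self.ld_permutations,
            "meth_permutations": self.meth_permutations,
            "vst_threshold": self.vst_threshold,
        }
        for name, value in positive.items():
            if value < 0:
                raise ValidationError(f"config {name} must be non-negative, got {value}")
        if not (0 < self.meth_top_quantile < 1):
            raise ValidationError("meth_top_quantile must lie in (0, 1)")


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full synthetic pipeline; returns a summary dict (also on disk).

    Stage order: simulate → background/normalize → low-count exclusion →
    variability classification → read-depth calibration → V_ST → tag-SNP
    scan → expression scan → methylation pipeline.  Any stage failure raises
    with the stage named.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    funnel: dict = {"seed": config.seed, "version": __version__}

    stage = "simulate"
    try:
        truth = synthetic_data.default_truth(
            config.seed, n_test_probes=config.n_test_probes
        )
        planted = config.planted or _default_planted(truth)
        raw = synthetic_data.simulate_counts(truth, rng)
        panel = synthetic_data.simulate_snps(
            truth,
            n_null_per_probe=config.n_snps_per_probe,
            planted_tags=[(p, v["tag_r2"]) for p, v in planted.items() if "tag_r2" in v],
            flank=config.ld_flank_bp,
            rng=rng,
        )
        expr = synthetic_data.simulate_expression(
            truth,
            n_null_per_probe=config.n_transcripts_per_probe,
            planted_effects=[
                (p, v["expr_slope"]) for p, v in planted.items() if "expr_slope" in v
            ],
            flank=config.cis_flank_bp,
            rng=rng,
        )
        meth, pool = synthetic_data.simulate_methylation(
            truth,
            n_null_per_probe=config.n_cpgs_per_probe,
            planted_effects=[
                (p, v["meth_slope"]) for p, v in planted.items() if "meth_slope" in v
            ],
            pool_size=config.meth_pool_size,
            flank=config.cis_flank_bp,
            rng=rng,
        )
        rd = synthetic_data.simulate_readdepth(truth, rng=rng)
        write_count_matrix(raw, outdir / "raw_counts.tsv")
        write_probe_bed(truth.probes, outdir / "probes.bed", outdir / "probe_classes.tsv")
        write_sample_table(truth.samples, outdir / "samples.tsv")
        funnel["simulate"] = {
            "probes": len(truth.probes),
            "samples": len(truth.samples.sample_ids),
            "snps": len(panel.snp_ids),
            "transcripts": len(expr.feature_ids),
            "cpgs": len(meth.feature_ids),
        }

        stage = "normalize"
        negative = truth.probe_ids("negative")
        invariant = truth.probe_ids("invariant")
        corrected, background = counts.background_correct(raw, negative)
        factors = counts.normalization_factors(
            corrected, invariant, literal=config.literal_normalization
        )
        norm = counts.normalize(corrected, factors, background)
        write_count_matrix(norm.matrix, outdir / "normalized_counts.tsv")

        stage = "exclude_low_counts"
        kept, dropped = counts.exclude_low_count_probes(norm, config.min_mean_count)
        test_ids = [p for p in truth.probe_ids("test") if p in kept.feature_ids]
        funnel["low_count_exclusion"] = {
            "in": len(norm.matrix.feature_ids),
            "dropped": dropped,
            "out": len(kept.feature_ids),
        }

        stage = "classify_variability"
        calls = counts.classify_variability(
            kept,
            cv_threshold=config.cv_threshold,
            deviation=config.deviation,
            min_individuals=config.min_individuals,
            probe_ids=test_ids,
        )
        variable_ids = [c.probe_id for c in calls if c.is_variable]
        funnel["variability"] = {"tested": len(calls), "variable": len(variable_ids)}

        stage = "calibrate"
        rd_grid = calibration.collapse_readdepth(rd)
        est = calibration.calibrate(kept.subset_features(test_ids), rd_grid)
        write_count_matrix(est.matrix, outdir / "copy_number.tsv")
        funnel["calibration"] = {
            "calibrated": int(est.n_calibration_samples.gt(0).sum()),
            "uncalibratable": est.uncalibratable,
        }

        stage = "vst"
        groups = truth.samples.df["population"]
        vst_records = []
        for pid in variable_ids:
            vst_records.append(
                popgen_evolution.vst(est.values.loc[pid], groups, probe_id=pid)
            )
        flagged = popgen_evolution.flag_differentiated(vst_records, config.vst_threshold)
        write_records(vst_records, outdir / "vst.tsv")
        funnel["vst"] = {
            "tested": len(vst_records),
            "differentiated": [r.probe_id for r in flagged],
        }

        stage = "ld_scan"
        probe_map = {p.probe_id: p for p in truth.probes}
        ld_records = []
        for pid in variable_ids:
            ws = build_windows(probe_map[pid], config.ld_flank_bp, config.ld_min_identity)
            ld_records.extend(
                association.tag_snp_scan(
                    pid, est.values.loc[pid], panel, ws, truth.samples,
                    n_permutations=config.ld_permutations, rng=rng,
                )
            )
        write_records(ld_records, outdir / "ld_scan.tsv")
        best_r2 = {}
        for pid in variable_ids:
            best = association.best_record([r for r in ld_records if r.probe_id == pid])
            if best is not None:
                best_r2[pid] = best.r2
        funnel["ld_scan"] = {
            "probes": len(variable_ids),
            "median_best_r2": float(np.median(list(best_r2.values()))) if best_r2 else None,
        }

        stage = "expression_scan"
        expr_records = []
        for pid in variable_ids:
            ws = build_windows(probe_map[pid], config.cis_flank_bp, config.ld_min_identity)
            expr_records.extend(
                association.expression_scan(
                    pid, est.values.loc[pid], expr, ws, truth.samples,
                    target_name=probe_map[pid].target_name,
                    n_permutations=config.expr_permutations, rng=rng,
                    mean_min=config.expr_mean_min, iqr_min=config.expr_iqr_min,
                )
            )
        write_records(expr_records, outdir / "expression_scan.tsv")
        funnel["expression_scan"] = {
            "records": len(expr_records),
            "significant": sum(
                1 for r in expr_records if r.p_perm is not None and r.p_perm < 0.01
            ),
        }

        stage = "methylation_pipeline"
        windows = {
            pid: build_windows(
                probe_map[pid], config.cis_flank_bp, config.ld_min_identity,
                exclude_unplaced=True,
            )
            for pid in variable_ids
        }
        meth_cfg = association.MethylationStageConfig(
            top_quantile=config.meth_top_quantile,
            slope_min=config.meth_slope_min,
            perm_alpha=config.meth_perm_alpha,
            per_population_alpha=config.meth_per_pop_alpha,
            n_permutations=config.meth_permutations,
        )
        meth_records, meth_funnel = association.methylation_pipeline(
            est.values.loc[variable_ids], meth, windows, pool.values,
            truth.samples, meth_cfg, rng=rng,
        )
        write_records(meth_records, outdir / "methylation_scan.tsv")
        funnel["methylation"] = meth_funnel
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise

    summary = {
        "funnel": funnel,
        "truth": {
            "planted_tags": truth.planted_tags,
            "planted_expr_effects": truth.planted_expr_effects,
            "planted_meth_effects": truth.planted_meth_effects,
        },
        "recovered": {
            "best_tag_r2": best_r2,
            "methylation_survivors": [
                (r.probe_id, r.feature_id) for r in meth_records
            ],
        },
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (outdir / "resolved_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str)
    )
    logger.info("pipeline complete; funnel: %s", funnel)
    return summary


def _default_planted(truth: synthetic_data.SimTruth) -> dict:
    """Plant one tag, one expression and one methylation effect by default."""
    variable = truth.variable_probes
    planted: dict = {}
    if variable:
        planted[variable[0]] = {"tag_r2": 0.5}
    if len(variable) > 1:
        planted[variable[1]] = {"expr_slope": 0.1}
    if len(variable) > 2:
        planted[variable[2]] = {"meth_slope": 0.3}
    return planted
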