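"""Recovery experiments: how well each pipeline stage recovers planted truth.

Each experiment builds a seeded synthetic study at the study's default
conditions, runs the relevant pipeline stage, and measures recovery —
calibration error against true copy number, type-I error calibration of the
permutation engine, realized vs target r² of planted tag SNPs, sign recovery
of planted expression effects, and survival of planted methylation effects
through the multi-stage filter.  These functions power both the test suite's
end-to-end checks and the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import calibration, counts, synthetic_data
from .association import (
    MethylationStageConfig,
    PermutationConfig,
    best_record,
    correlate,
    methylation_pipeline,
    permutation_p,
    tag_snp_scan,
)
from .io_formats import FeatureMatrix, ProbeAnnotation
from .probe_design import build_windows


def snp_density_fold_reduction(
    spacing_near_probes_bp: float = 3300.0, spacing_genome_bp: float = 738.0
) -> float:
    """Fold reduction in SNP density near assayed loci vs the genome average.

    Density is 1/spacing, so the fold reduction is the ratio of the mean
    inter-SNP spacings (one SNP per 3.3 kb near probes vs one per 738 bp
    genome-wide).
    """
    return spacing_near_probes_bp / spacing_genome_bp


def alignments_per_probe_summary(probes: list[ProbeAnnotation]) -> dict[str, float]:
    """Mean and median number of genomic alignments per probe."""
    counts_ = [len(p.alignments) for p in probes if p.alignments]
    return {"mean": float(np.mean(counts_)), "median": float(np.median(counts_))}


def copy_number_summary(cn: pd.DataFrame) -> dict[str, float]:
    """Mean and median of the per-locus mean diploid copy number."""
    per_locus = cn.mean(axis=1)
    return {"mean": float(per_locus.mean()), "median": float(per_locus.median())}


# ---------------------------------------------------------------------------
# calibration recovery


def calibration_recovery_experiment(
    seed: int,
    n_probes: int = 200,
    n_samples: int = 165,
    noise_cv: float = 0.05,
    cn_range: tuple[int, int] = (2, 60),
    efficiency_range: tuple[float, float] = (0.5, 2.0),
) -> dict[str, float]:
    """Recover true CN through calibration under multiplicative noise.

    Counts are probe-efficiency-scaled true copy numbers with log-normal
    noise of CV ``noise_cv`` (the calibration stage in isolation: sample
    scale and background are handled upstream by normalization); read-depth
    anchors carry the same noise level.  Reports the per-probe median
    absolute relative error's median and maximum over probes, plus the exact
    (noise-free) recovery error.
    """
    rng = np.random.default_rng(seed)
    probes = [f"P{i:03d}" for i in range(n_probes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    # per-probe baseline in {2..60}, per-sample log-normal biological spread
    baseline = rng.integers(cn_range[0], cn_range[1] + 1, size=(n_probes, 1)).astype(float)
    true_cn = pd.DataFrame(
        baseline * np.exp(rng.normal(0.0, 0.2, size=(n_probes, n_samples))),
        index=probes, columns=samples,
    )
    eff = rng.uniform(*efficiency_range, size=(n_probes, 1))

    def run(cv: float) -> pd.DataFrame:
        counts_ = eff * true_cn.to_numpy() * np.exp(cv * rng.standard_normal(true_cn.shape))
        rd = true_cn.to_numpy() * np.exp(cv * rng.standard_normal(true_cn.shape))
        fm = FeatureMatrix(pd.DataFrame(counts_, index=probes, columns=samples))
        rd_long = pd.DataFrame(
            {
                "probe_id": np.repeat(probes, n_samples),
                "sample_id": samples * n_probes,
                "cn": rd.ravel(),
            }
        )
        grid = calibration.collapse_readdepth(rd_long)
        return calibration.calibrate(fm, grid).values

    exact = run(0.0)
    exact_err = float((exact - true_cn).abs().to_numpy().max())
    noisy = run(noise_cv)
    rel_err = (noisy - true_cn).abs() / true_cn
    per_probe_median = rel_err.median(axis=1)
    return {
        "exact_max_abs_error": exact_err,
        "median_abs_relative_error_pct_median": float(per_probe_median.median() * 100),
        "median_abs_relative_error_pct_max": float(per_probe_median.max() * 100),
    }


# ---------------------------------------------------------------------------
# permutation calibration


def permutation_type1_experiment(
    seed: int,
    n_tests: int = 1000,
    n_permutations: int = 1000,
    n_samples: int = 60,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Empirical type-I error of the shuffle permutation test under the null.

    Independent Gaussian probe/feature pairs; the rejection rate at
    ``alpha`` should match ``alpha`` to within binomial error when the test
    is calibrated.
    """
    rng = np.random.default_rng(seed)
    idx = pd.RangeIndex(n_samples)
    cfg = PermutationConfig(n_permutations=n_permutations)
    rejections = 0
    pvals = np.empty(n_tests)
    for t in range(n_tests):
        x = pd.Series(rng.standard_normal(n_samples), index=idx)
        y = pd.Series(rng.standard_normal(n_samples), index=idx)
        res = correlate(x, y, "pearson_r")
        perm = permutation_p(res.r, x, y, cfg, "pearson_r", rng=rng)
        pvals[t] = perm.p
        if perm.p < alpha:
            rejections += 1
    lo, hi = stats.binom.interval(0.95, n_tests, alpha)
    return {
        "type1_error_rate": rejections / n_tests,
        "alpha": alpha,
        "n_tests": n_tests,
        "binomial_ci_low": lo / n_tests,
        "binomial_ci_high": hi / n_tests,
        "mean_p": float(pvals.mean()),
    }


# ---------------------------------------------------------------------------
# planted-effect recovery


def tag_recovery_experiment(
    seed: int,
    n_replicates: int = 100,
    target_r2: float = 0.5,
    n_null_snps: int = 20,
    n_permutations: int = 200,
) -> dict[str, float]:
    """Median best tag-SNP R² recovered when one tag of target r² is planted.

    Each replicate builds a small cohort-sized study with one variable probe,
    one planted tag and ``n_null_snps`` independent SNPs, then runs the LD
    scan and records the best combined-population R².
    """
    best_r2 = []
    realized = []
    for rep in range(n_replicates):
        truth = synthetic_data.default_truth(
            seed + rep, n_test_probes=1, fraction_variable=1.0, n_differentiated=0
        )
        rng = np.random.default_rng(seed * 100_003 + rep)
        pid = truth.probe_ids("test")[0]
        panel = synthetic_data.simulate_snps(
            truth,
            n_null_per_probe=n_null_snps,
            planted_tags=[(pid, target_r2)],
            rng=rng,
        )
        windows = build_windows(truth.probes[0], 250_000, 95.0)
        records = tag_snp_scan(
            pid, truth.true_cn.loc[pid], panel, windows, truth.samples,
            n_permutations=n_permutations, rng=rng,
        )
        combined = [r for r in records if r.population_set == "combined"]
        best = best_record(combined)
        if best is not None:
            best_r2.append(best.r2)
        realized.append(truth.planted_tags[0]["realized_r2"])
    return {
        "target_r2": target_r2,
        "median_best_r2": float(np.median(best_r2)),
        "mean_realized_r2": float(np.mean(realized)),
        "n_replicates": n_replicates,
    }


def expression_sign_experiment(
    seed: int,
    n_replicates: int = 100,
    snr: float = 3.0,
    slope: float = -0.05,
) -> dict[str, float]:
    """Fraction of replicates recovering the planted expression slope's sign.

    Noise is set from the signal-to-noise ratio: noise_sd = |slope|·sd(cn)/snr.
    The recovered record is the planted transcript's combined-population
    correlation; sign recovery means sign(r) == sign(slope).
    """
    hits = 0
    for rep in range(n_replicates):
        truth = synthetic_data.default_truth(
            seed + rep, n_test_probes=1, fraction_variable=1.0, n_differentiated=0
        )
        rng = np.random.default_rng(seed * 99_991 + rep)
        pid = truth.probe_ids("test")[0]
        cn_sd = float(truth.true_cn.loc[pid].std())
        noise_sd = abs(slope) * cn_sd / snr
        expr = synthetic_data.simulate_expression(
            truth, planted_effects=[(pid, slope)], noise_sd=noise_sd,
            n_null_per_probe=0, rng=rng,
        )
        tid = truth.planted_expr_effects[0]["transcript_id"]
        res = correlate(truth.true_cn.loc[pid], expr.values.loc[tid], "pearson_r")
        if math.copysign(1, res.r) == math.copysign(1, slope):
            hits += 1
    return {
        "sign_recovery_rate": hits / n_replicates,
        "snr": snr,
        "n_replicates": n_replicates,
    }


def methylation_survival_experiment(
    seed: int,
    n_replicates: int = 100,
    planted_slope: float = 0.3,
    n_probes: int = 10,
    n_cpgs_per_probe: int = 12,
    pool_size: int = 2000,
    n_permutations: int = 1000,
    n_ceu: int = 60,
    n_yri: int = 58,
) -> dict[str, float]:
    """Survival rate of a planted methylation effect through all five stages.

    Each replicate plants one CpG with normalized slope ``planted_slope`` on
    one variable probe among ``n_probes`` probes of null CpGs, runs the
    staged methylation pipeline (top-2% |rho| → slope → resampling
    permutation → per-population replication) on a two-population cohort,
    and checks whether the planted pair survives.
    """
    survived = 0
    for rep in range(n_replicates):
        truth = synthetic_data.default_truth(
            seed + rep, n_test_probes=n_probes, fraction_variable=1.0,
            n_differentiated=0, n_ceu=n_ceu, n_yri=n_yri, n_chb=0,
        )
        rng = np.random.default_rng(seed * 7_919 + rep)
        pid = truth.probe_ids("test")[0]
        meth, pool = synthetic_data.simulate_methylation(
            truth,
            n_null_per_probe=n_cpgs_per_probe,
            planted_effects=[(pid, planted_slope)],
            pool_size=pool_size,
            rng=rng,
        )
        windows = {
            p.probe_id: build_windows(p, 500_000, 95.0, exclude_unplaced=True)
            for p in truth.probes
            if p.probe_class == "test"
        }
        cfg = MethylationStageConfig(n_permutations=n_permutations)
        records, _ = methylation_pipeline(
            truth.true_cn.loc[truth.probe_ids("test")], meth, windows,
            pool.values, truth.samples, cfg, rng=rng,
        )
        planted_cpg = truth.planted_meth_effects[0]["cpg_id"]
        if any(r.probe_id == pid and r.feature_id == planted_cpg for r in records):
            survived += 1
    return {
        "survival_rate": survived / n_replicates,
        "planted_normalized_slope": planted_slope,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# variability classification on the full count pipeline


def variability_recovery_experiment(
    seed: int, n_test_probes: int = 40, fraction_variable: float = 0.6
) -> dict[str, float]:
    """Sensitivity/specificity of the variability classifier on a full run.

    Simulates raw counts at default noise, runs background correction,
    normalization and classification, and compares calls against which
    probes truly vary in copy number.
    """
    truth = synthetic_data.default_truth(
        seed, n_test_probes=n_test_probes, fraction_variable=fraction_variable
    )
    rng = np.random.default_rng(seed + 10)
    raw = synthetic_data.simulate_counts(truth, rng)
    corrected, bg = counts.background_correct(raw, truth.probe_ids("negative"))
    factors = counts.normalization_factors(corrected, truth.probe_ids("invariant"))
    norm = counts.normalize(corrected, factors, bg)
    calls = counts.classify_variability(norm, probe_ids=truth.probe_ids("test"))
    truly_variable = set(truth.variable_probes)
    called = {c.probe_id for c in calls if c.is_variable}
    tested = set(truth.probe_ids("test"))
    tp = len(called & truly_variable)
    tn = len((tested - called) & (tested - truly_variable))
    return {
        "fraction_called_variable_pct": 100 * len(called) / len(tested),
        "true_fraction_variable_pct": 100 * len(truly_variable) / len(tested),
        "sensitivity": tp / len(truly_variable) if truly_variable else float("nan"),
        "specificity": tn / len(tested - truly_variable)
        if tested - truly_variable
        else float("nan"),
    }
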