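"""Tag-SNP LD, cis expression and cis methylation association with permutation nulls.

The multi-allelic copy-number genotype is treated as a quantitative trait:
association with a nearby feature (SNP dosage, log2 expression, CpG beta
value) is a simple correlation over samples.  SNP dosages use the 0/1/2
coding with the alphabetically first observed allele designated as 0 — the
orientation only flips the sign of r, never R².  Significance comes from
permutation: LD and expression scans shuffle the sample labels; the
methylation scan resamples feature vectors from a genome-wide pool of
autosomal CpGs, matching the multi-stage filter (top-2% |rho| → normalized
slope > 0.1 → resampling p < 0.01 → per-population replication p < 0.05).
Sex-chromosome loci are analysed within one sex at a time (X methylation:
males only).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FeatureMatrix, SampleTable, ValidationError
from .probe_design import WindowSet, features_in_windows

logger = logging.getLogger(__name__)


class DegenerateInput(ValueError):
    """Zero variance or too few complete pairs for a correlation."""


# ---------------------------------------------------------------------------
# SNP panel


@dataclass
class SnpPanel:
    """SNP positions, verbatim calls, 0/1/2 dosage codes and QC statistics.

    ``calls``: snp × sample allele-pair strings ("AA", "AG", ...; NA missing).
    ``meta``: per-snp chrom, pos (0-based) and the boolean QC flags
    tri_allelic, multi_mapped_51bp, in_segdup, in_cnv.  ``codes`` holds NaN
    for missing calls and for tri-allelic SNPs.
    """

    calls: pd.DataFrame
    meta: pd.DataFrame
    codes: pd.DataFrame
    maf: pd.Series
    hwe_p: pd.Series

    FLAG_COLUMNS = ("tri_allelic", "multi_mapped_51bp", "in_segdup", "in_cnv")

    @classmethod
    def from_calls(cls, calls: pd.DataFrame, meta: pd.DataFrame) -> "SnpPanel":
        meta = meta.copy()
        for col in cls.FLAG_COLUMNS:
            if col not in meta.columns:
                meta[col] = False
            meta[col] = meta[col].astype(bool)
        codes = pd.DataFrame(np.nan, index=calls.index, columns=calls.columns)
        maf = pd.Series(np.nan, index=calls.index)
        hwe = pd.Series(np.nan, index=calls.index)
        for snp in calls.index:
            row = calls.loc[snp]
            alleles = allele_inventory(row)
            if len(alleles) > 2:
                meta.loc[snp, "tri_allelic"] = True
                continue
            coded = encode_genotypes(row)
            codes.loc[snp] = coded
            n = coded.notna().sum()
            if n == 0:
                continue
            freq = float(coded.sum()) / (2 * n)  # non-designated allele frequency
            maf[snp] = min(freq, 1 - freq)
            counts = coded.value_counts()
            hwe[snp] = hwe_test(
                int(counts.get(0.0, 0)), int(counts.get(1.0, 0)), int(counts.get(2.0, 0))
            )
        return cls(calls=calls, meta=meta, codes=codes, maf=maf, hwe_p=hwe)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.index)

    def codes_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(self.codes, self.meta[["chrom", "pos"]])

    def subset(self, snp_ids: list[str]) -> "SnpPanel":
        ids = list(snp_ids)
        return SnpPanel(
            calls=self.calls.loc[ids],
            meta=self.meta.loc[ids],
            codes=self.codes.loc[ids],
            maf=self.maf.loc[ids],
            hwe_p=self.hwe_p.loc[ids],
        )


def allele_inventory(calls: pd.Series) -> dict[str, int]:
    """Count alleles across a SNP's non-missing allele-pair calls."""
    inv: dict[str, int] = {}
    for call in calls.dropna():
        for allele in str(call):
            inv[allele] = inv.get(allele, 0) + 1
    return dict(sorted(inv.items()))


def encode_genotypes(calls: pd.Series) -> pd.Series:
    """Allele-pair calls → dosage of the non-designated allele (0/1/2).

    The designated allele is the alphabetically first observed; the
    homozygous designated genotype codes 0, the heterozygote 1, the other
    homozygote 2.  Missing calls stay missing.  More than two observed
    alleles is an error (tri-allelic SNPs must be removed beforehand).
    """
    alleles = sorted(allele_inventory(calls))
    if len(alleles) > 2:
        raise ValidationError(f"more than two alleles observed: {alleles}")
    designated = alleles[0] if alleles else None
    out = pd.Series(np.nan, index=calls.index)
    for sample, call in calls.dropna().items():
        out[sample] = sum(1 for a in str(call) if a != designated)
    return out


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Chi-square (1 df, no continuity correction) Hardy–Weinberg test."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValidationError("HWE test on zero genotypes")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def filter_snps(
    panel: SnpPanel,
    maf_min: float = 0.1,
    hwe_alpha: float = 0.05,
    stringent: bool = False,
) -> tuple[SnpPanel, dict[str, int]]:
    """Basic QC (MAF, HWE, tri-allelic) plus optional stringent flag filter.

    The stringent set additionally drops SNPs flagged as multi-mapped over a
    51 bp interval, inside segmental duplications, or inside known CNV
    regions (flags are inputs).  Returns the filtered panel and per-rule
    removal counts.
    """
    meta = panel.meta
    funnel = {"input": len(panel.snp_ids)}
    tri = meta["tri_allelic"]
    low_maf = panel.maf.fillna(0.0) < maf_min
    hwe_fail = panel.hwe_p < hwe_alpha
    drop = tri | low_maf | hwe_fail.fillna(False)
    funnel["tri_allelic"] = int(tri.sum())
    funnel["maf_below_min"] = int((low_maf & ~tri).sum())
    funnel["hwe_fail"] = int((hwe_fail.fillna(False) & ~tri & ~low_maf).sum())
    if stringent:
        flagged = meta["multi_mapped_51bp"] | meta["in_segdup"] | meta["in_cnv"]
        funnel["stringent_flags"] = int((flagged & ~drop).sum())
        drop = drop | flagged
    kept = [s for s, d in drop.items() if not d]
    funnel["output"] = len(kept)
    logger.info("filter_snps funnel: %s", funnel)
    return panel.subset(kept), funnel


# ---------------------------------------------------------------------------
# correlation & permutation engine


@dataclass
class CorrelationResult:
    r: float
    p_nominal: float
    slope: float
    n: int


@dataclass
class PermutationConfig:
    n_permutations: int = 10000
    seed: int | None = None
    tail: str = "two_sided"
    null_kind: str = "shuffle_samples"  # or resample_features

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.tail != "two_sided":
            raise ValidationError("only the two-sided tail is supported")
        if self.null_kind not in ("shuffle_samples", "resample_features"):
            raise ValidationError(f"unknown null_kind {self.null_kind!r}")


@dataclass
class PermutationResult:
    p: float
    n_permutations: int
    below_resolution: bool  # p == 0: true p below 1/B


@dataclass
class AssociationRecord:
    probe_id: str
    feature_id: str | None
    feature_kind: str  # snp | transcript | cpg
    population_set: str
    n: int
    stat_kind: str  # pearson_r | spearman_rho
    r: float
    r2: float
    slope: float
    normalized_slope: float | None
    p_nominal: float
    p_perm: float | None
    n_permutations: int
    flag: str = ""


def _complete_pairs(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    idx = x.index.intersection(y.index)
    xv = x[idx].to_numpy(dtype=float)
    yv = y[idx].to_numpy(dtype=float)
    ok = ~(np.isnan(xv) | np.isnan(yv))
    return xv[ok], yv[ok]


def correlate(
    probe_values: pd.Series,
    feature_values: pd.Series,
    stat_kind: str = "pearson_r",
    min_n: int = 3,
) -> CorrelationResult:
    """Pearson r or Spearman rho (average ranks) with OLS slope and t-test p.

    Pairwise-complete; the slope regresses the feature on the probe value.
    Zero variance on either side or < ``min_n`` pairs raises
    :class:`DegenerateInput`.
    """
    x, y = _complete_pairs(probe_values, feature_values)
    if len(x) < min_n:
        raise DegenerateInput(f"only {len(x)} complete pairs (< {min_n})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInput("zero variance")
    if stat_kind == "pearson_r":
        r, p = stats.pearsonr(x, y)
    elif stat_kind == "spearman_rho":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown stat_kind {stat_kind!r}")
    slope = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    return CorrelationResult(r=float(r), p_nominal=float(p), slope=slope, n=len(x))


def _rowwise_corr(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with ``y``."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rc @ yc) / denom


def permutation_p(
    observed_stat: float,
    probe_values: pd.Series,
    feature_values: pd.Series,
    config: PermutationConfig,
    stat_kind: str = "pearson_r",
    pool: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Two-tailed permutation p: fraction of null |stat| strictly above |observed|.

    ``shuffle_samples`` permutes the probe vector across samples (equivalent
    to permuting either side).  ``resample_features`` draws replacement
    feature vectors from ``pool`` (features × samples, aligned on sample
    ids), without replacement across draws while the pool lasts.  p = 0 is
    reported with ``below_resolution`` set rather than a pseudo-count.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    B = config.n_permutations

    idx = probe_values.index.intersection(feature_values.index)
    x = probe_values[idx].to_numpy(dtype=float)
    y = feature_values[idx].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    kept_samples = idx[ok]

    if stat_kind == "spearman_rho":
        x = stats.rankdata(x)

    if config.null_kind == "shuffle_samples":
        yv = stats.rankdata(y) if stat_kind == "spearman_rho" else y
        perms = np.tile(x, (B, 1))
        rng.permuted(perms, axis=1, out=perms)
        null = _rowwise_corr(perms, yv)
    else:
        if pool is None or len(pool) == 0:
            raise ValidationError("resample_features requires a non-empty pool")
        cols = [s for s in kept_samples if s in pool.columns]
        if len(cols) < len(kept_samples):
            raise ValidationError("pool does not cover the analysis samples")
        mat = pool[cols].to_numpy(dtype=float)
        complete = ~np.isnan(mat).any(axis=1)
        if not complete.all():
            logger.warning(
                "resample pool: dropping %d features with missing values",
                int((~complete).sum()),
            )
            mat = mat[complete]
        if len(mat) == 0:
            raise ValidationError("resample pool empty after dropping missing rows")
        if len(mat) >= B:
            draw = rng.choice(len(mat), size=B, replace=False)
        else:
            logger.warning(
                "resample pool smaller than %d draws; sampling with replacement", B
            )
            draw = rng.choice(len(mat), size=B, replace=True)
        drawn = mat[draw]
        if stat_kind == "spearman_rho":
            drawn = stats.rankdata(drawn, axis=1)
        null = _rowwise_corr(drawn, x)

    exceed = int(np.nansum(np.abs(null) > abs(observed_stat)))
    p = exceed / B
    return PermutationResult(p=p, n_permutations=B, below_resolution=(p == 0.0))


# ---------------------------------------------------------------------------
# population sets


def population_sets(
    samples: SampleTable,
    available: list[str],
    sex_stratify: bool = False,
    min_n: int = 3,
) -> dict[str, list[str]]:
    """Analysis strata: each population, all combined; optionally per sex."""
    avail = [s for s in samples.sample_ids if s in set(available)]
    pops = [p for p in ("CEU", "YRI", "CHB") if samples.samples_of(population=p)]
    base: dict[str, list[str]] = {}
    for pop in pops:
        ids = [s for s in samples.samples_of(population=pop) if s in set(avail)]
        if len(ids) >= min_n:
            base[pop] = ids
    if len(avail) >= min_n:
        base["combined"] = avail
    if not sex_stratify:
        return base
    out: dict[str, list[str]] = {}
    for name, ids in base.items():
        for sex in ("male", "female"):
            sub = [s for s in ids if s in set(samples.samples_of(sex=sex))]
            if len(sub) >= min_n:
                out[f"{sex}_{name}" if name == "combined" else f"{name}_{sex}"] = sub
    return out


# ---------------------------------------------------------------------------
# tag-SNP scan


def tag_snp_scan(
    probe_id: str,
    probe_values: pd.Series,
    panel: SnpPanel,
    windows: WindowSet,
    samples: SampleTable,
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
    sex_stratify: bool = False,
    min_n: int = 3,
) -> list[AssociationRecord]:
    """Best tagging SNP per population set for one copy-number probe.

    Every in-window SNP is correlated (Pearson, on 0/1/2 dosages) with the
    probe's values within each population set; the SNP with maximal R² is
    reported with its shuffle-permutation p.  Ties break by smaller nominal
    p, then genomic position.  ``sex_stratify`` is used for X/Y probes.
    An empty window yields a record with a missing feature id.
    """
    if rng is None:
        rng = np.random.default_rng()
    snp_ids = features_in_windows(windows, panel.codes_matrix())
    sets = population_sets(samples, list(probe_values.index), sex_stratify, min_n)
    records: list[AssociationRecord] = []
    for set_name, ids in sets.items():
        x = probe_values[ids]
        best: tuple | None = None  # (-r2, p_nominal, pos, snp, CorrelationResult)
        for snp in snp_ids:
            try:
                res = correlate(x, panel.codes.loc[snp, ids], "pearson_r", min_n)
            except DegenerateInput:
                continue
            key = (-res.r**2, res.p_nominal, int(panel.meta.loc[snp, "pos"]))
            if best is None or key < best[:3]:
                best = (*key, snp, res)
        if best is None:
            records.append(
                AssociationRecord(
                    probe_id, None, "snp", set_name, len(ids), "pearson_r",
                    float("nan"), float("nan"), float("nan"), None,
                    float("nan"), None, 0, flag="no_snps_in_window",
                )
            )
            continue
        snp, res = best[3], best[4]
        perm = permutation_p(
            res.r, x, panel.codes.loc[snp, ids],
            PermutationConfig(n_permutations=n_permutations), "pearson_r", rng=rng,
        )
        records.append(
            AssociationRecord(
                probe_id, snp, "snp", set_name, res.n, "pearson_r",
                res.r, res.r**2, res.slope, None, res.p_nominal,
                perm.p, perm.n_permutations,
                flag="below_resolution" if perm.below_resolution else "",
            )
        )
    return records


def best_record(records: list[AssociationRecord]) -> AssociationRecord | None:
    """The record with the highest R² (ties by nominal p)."""
    candidates = [r for r in records if r.feature_id is not None and not math.isnan(r.r2)]
    if not candidates:
        return None
    return min(candidates, key=lambda r: (-r.r2, r.p_nominal))


# ---------------------------------------------------------------------------
# expression scan


def expression_filter(
    expr: FeatureMatrix, mean_min: float = 6.0, iqr_min: float = 0.25
) -> tuple[FeatureMatrix, list[str]]:
    """Drop transcripts with mean log2 expression < 6 or IQR < 0.25."""
    vals = expr.values
    means = vals.mean(axis=1)
    iqr = vals.quantile(0.75, axis=1) - vals.quantile(0.25, axis=1)
    drop = (means < mean_min) | (iqr < iqr_min)
    kept = expr.subset_features(list(vals.index[~drop]))
    return kept, list(vals.index[drop])


def expression_scan(
    probe_id: str,
    probe_values: pd.Series,
    expr: FeatureMatrix,
    windows: WindowSet,
    samples: SampleTable,
    target_name: str = "",
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
    sex_stratify: bool = False,
    mean_min: float = 6.0,
    iqr_min: float = 0.25,
    min_n: int = 3,
) -> list[AssociationRecord]:
    """Pearson correlation of copy number with every in-window transcript.

    The expression filter (mean log2 < 6 or IQR < 0.25 removed) runs first;
    each surviving transcript is tested per population set with a
    shuffle-permutation p.  Records where the transcript is the probe's own
    target gene are flagged as auto-correlations.
    """
    if rng is None:
        rng = np.random.default_rng()
    filtered, _ = expression_filter(expr, mean_min, iqr_min)
    transcript_ids = features_in_windows(windows, filtered)
    sets = population_sets(samples, list(probe_values.index), sex_stratify, min_n)
    records: list[AssociationRecord] = []
    for set_name, ids in sets.items():
        x = probe_values[ids]
        for tid in transcript_ids:
            y = filtered.values.loc[tid, [s for s in ids if s in filtered.sample_ids]]
            try:
                res = correlate(x, y, "pearson_r", min_n)
            except DegenerateInput:
                continue
            perm = permutation_p(
                res.r, x, y, PermutationConfig(n_permutations=n_permutations),
                "pearson_r", rng=rng,
            )
            flags = []
            if target_name and tid == target_name:
                flags.append("auto_correlation")
            if perm.below_resolution:
                flags.append("below_resolution")
            records.append(
                AssociationRecord(
                    probe_id, tid, "transcript", set_name, res.n, "pearson_r",
                    res.r, res.r**2, res.slope, None, res.p_nominal,
                    perm.p, perm.n_permutations, flag=";".join(flags),
                )
            )
    return records


# ---------------------------------------------------------------------------
# methylation


def normalized_slope(
    beta_values: pd.Series, cn_values: pd.Series, min_n: int = 3
) -> tuple[float, str]:
    """OLS slope of beta on CN × the observed CN range (sign preserved).

    The predicted beta-value difference between the lowest and highest
    observed copy number under the best linear fit.  A zero CN range yields
    0 with a flag.
    """
    cn, beta = _complete_pairs(cn_values, beta_values)
    if len(cn) < min_n:
        raise DegenerateInput(f"only {len(cn)} complete pairs (< {min_n})")
    rng_cn = float(np.ptp(cn))
    if rng_cn == 0:
        return 0.0, "zero_cn_range"
    slope = float(np.cov(cn, beta, ddof=1)[0, 1] / np.var(cn, ddof=1))
    return slope * rng_cn, ""


def methylation_qc(
    meth: FeatureMatrix,
    probe_flags: pd.DataFrame | None = None,
    missing_threshold: float = 0.05,
) -> tuple[FeatureMatrix, FeatureMatrix, dict[str, int]]:
    """Array-level CpG probe filters and autosome/chrX partition.

    Removes probes flagged multi-loci or SNP-overlapping (flags are inputs),
    probes on chrY, and probes with a missing fraction > ``missing_threshold``.
    Returns (autosomal matrix, chrX matrix, funnel counts).
    """
    if meth.coords is None:
        raise ValidationError("methylation matrix needs coordinates")
    funnel = {"input": len(meth.feature_ids)}
    keep = pd.Series(True, index=meth.values.index)
    if probe_flags is not None:
        for col in ("multi_loci", "snp_overlap"):
            if col in probe_flags.columns:
                flagged = probe_flags[col].reindex(meth.values.index).fillna(False).astype(bool)
                funnel[col] = int((flagged & keep).sum())
                keep &= ~flagged
    chry = meth.coords["chrom"].reindex(meth.values.index) == "chrY"
    funnel["chrY"] = int((chry & keep).sum())
    keep &= ~chry
    miss_frac = meth.values.isna().mean(axis=1)
    high_missing = miss_frac > missing_threshold
    funnel["high_missing"] = int((high_missing & keep).sum())
    keep &= ~high_missing
    kept = meth.subset_features(list(keep.index[keep]))
    chrx_mask = kept.coords["chrom"].reindex(kept.values.index) == "chrX"
    autosomal = kept.subset_features(list(chrx_mask.index[~chrx_mask]))
    chrx = kept.subset_features(list(chrx_mask.index[chrx_mask]))
    funnel["autosomal"] = len(autosomal.feature_ids)
    funnel["chrX"] = len(chrx.feature_ids)
    logger.info("methylation_qc funnel: %s", funnel)
    return autosomal, chrx, funnel


@dataclass
class MethylationStageConfig:
    top_quantile: float = 0.98  # keep top 2% of |rho|
    slope_min: float = 0.1
    perm_alpha: float = 0.01
    per_population_alpha: float = 0.05
    n_permutations: int = 1000
    populations: tuple[str, ...] = ("CEU", "YRI")
    male_only: bool = False  # chrX analysis: males only, no per-pop replication
    min_n: int = 3


def methylation_pipeline(
    probe_cn: pd.DataFrame,
    meth: FeatureMatrix,
    windows: dict[str, WindowSet],
    pool: pd.DataFrame,
    samples: SampleTable,
    config: MethylationStageConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[AssociationRecord], dict[str, int]]:
    """Staged CNV:methylation association over all probes.

    Stage 1 computes Spearman rho for every probe × in-window CpG pair on
    the combined populations (males only when ``male_only``); stage 2 keeps
    the top 2% by |rho| across all tested pairs; stage 3 requires
    |normalized slope| > 0.1; stage 4 a resampling permutation p <
    ``perm_alpha`` drawn from the genome-wide ``pool``; stage 5 a nominal
    Spearman p < ``per_population_alpha`` in each population separately
    (skipped for the male-only X analysis).  Returns the surviving records
    and the per-stage funnel.
    """
    if config is None:
        config = MethylationStageConfig()
    if rng is None:
        rng = np.random.default_rng()

    if config.male_only:
        analysis_samples = [
            s for s in samples.samples_of(sex="male") if s in probe_cn.columns
        ]
    else:
        analysis_samples = [s for s in samples.sample_ids if s in probe_cn.columns]
    analysis_samples = [s for s in analysis_samples if s in meth.sample_ids]

    # stage 1: all in-window pairs, combined samples
    tested: list[tuple[str, str, CorrelationResult]] = []
    for pid, ws in windows.items():
        if pid not in probe_cn.index:
            continue
        x = probe_cn.loc[pid, analysis_samples]
        for cpg in features_in_windows(ws, meth):
            y = meth.values.loc[cpg, analysis_samples]
            try:
                res = correlate(x, y, "spearman_rho", config.min_n)
            except DegenerateInput:
                continue
            tested.append((pid, cpg, res))
    funnel = {"tested_pairs": len(tested)}
    if not tested:
        return [], funnel

    # stage 2: empirical top-|rho| quantile across the whole run
    abs_rho = np.array([abs(res.r) for _, _, res in tested])
    cutoff = float(np.quantile(abs_rho, config.top_quantile))
    stage2 = [t for t in tested if abs(t[2].r) >= cutoff]
    funnel["top_quantile_cutoff_rho"] = cutoff
    funnel["after_top_quantile"] = len(stage2)

    # stage 3: effect size on the beta scale
    stage3 = []
    slopes: dict[tuple[str, str], float] = {}
    for pid, cpg, res in stage2:
        ns, ns_flag = normalized_slope(
            meth.values.loc[cpg, analysis_samples], probe_cn.loc[pid, analysis_samples]
        )
        if ns_flag == "" and abs(ns) > config.slope_min:
            slopes[(pid, cpg)] = ns
            stage3.append((pid, cpg, res))
    funnel["after_normalized_slope"] = len(stage3)

    # stage 4: resampling permutation against the genome-wide pool
    perm_cfg = PermutationConfig(
        n_permutations=config.n_permutations, null_kind="resample_features"
    )
    stage4 = []
    perms: dict[tuple[str, str], PermutationResult] = {}
    for pid, cpg, res in stage3:
        perm = permutation_p(
            res.r,
            probe_cn.loc[pid, analysis_samples],
            meth.values.loc[cpg, analysis_samples],
            perm_cfg,
            "spearman_rho",
            pool=pool,
            rng=rng,
        )
        if perm.p < config.perm_alpha:
            perms[(pid, cpg)] = perm
            stage4.append((pid, cpg, res))
    funnel["after_permutation"] = len(stage4)

    # stage 5: per-population replication
    if config.male_only:
        stage5 = stage4
        funnel["per_population_replication"] = "skipped_male_only"
    else:
        stage5 = []
        for pid, cpg, res in stage4:
            ok = True
            for pop in config.populations:
                ids = [s for s in samples.samples_of(population=pop) if s in analysis_samples]
                try:
                    sub = correlate(
                        probe_cn.loc[pid, ids], meth.values.loc[cpg, ids],
                        "spearman_rho", config.min_n,
                    )
                except DegenerateInput:
                    ok = False
                    break
                if sub.p_nominal >= config.per_population_alpha:
                    ok = False
                    break
            if ok:
                stage5.append((pid, cpg, res))
        funnel["after_replication"] = len(stage5)

    records = []
    for pid, cpg, res in stage5:
        perm = perms[(pid, cpg)]
        records.append(
            AssociationRecord(
                pid, cpg, "cpg",
                "male_combined" if config.male_only else "combined",
                res.n, "spearman_rho", res.r, res.r**2, res.slope,
                slopes[(pid, cpg)], res.p_nominal, perm.p, perm.n_permutations,
                flag="below_resolution" if perm.below_resolution else "",
            )
        )
    logger.info("methylation funnel: %s", funnel)
    return records, funnel


# ---------------------------------------------------------------------------
# ChIP sliding windows


def sliding_window_enrichment(
    chip_coverage: np.ndarray,
    input_coverage: np.ndarray,
    window: int = 170,
    step: int = 85,
    region_start: int = 0,
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """Total-count-normalized ChIP/input ratio in sliding windows.

    Both per-base tracks are scaled by their totals, then for each window
    [start + k·step, start + k·step + window) the ratio
    (chip + ε)/(input + ε) of scaled sums is reported; windows with zero
    scaled input (and ε = 0) are missing.  A region shorter than the window
    yields an empty track; the number of windows is
    floor((L − window)/step) + 1.
    """
    chip = np.asarray(chip_coverage, dtype=float)
    inp = np.asarray(input_coverage, dtype=float)
    if chip.shape != inp.shape:
        raise ValidationError("chip and input tracks must have equal length")
    L = len(chip)
    if chip.sum() <= 0 or inp.sum() <= 0:
        raise ValidationError("track totals must be positive")
    if L < window:
        return pd.DataFrame(columns=["start", "end", "ratio"])
    chip = chip / chip.sum()
    inp = inp / inp.sum()
    n_windows = (L - window) // step + 1
    rows = []
    for k in range(n_windows):
        a = k * step
        b = a + window
        num = chip[a:b].sum() + epsilon
        den = inp[a:b].sum() + epsilon
        ratio = num / den if den > 0 else float("nan")
        rows.append({"start": region_start + a, "end": region_start + b, "ratio": ratio})
    return pd.DataFrame(rows)
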