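"""Background correction, invariant-probe normalization and count QC.

The digital count model: each probe yields a count proportional to target
copy number times a probe-specific binding efficiency, scaled by a
sample-level technical factor (input DNA amount, hybridisation efficiency),
on top of a nonspecific background measured by negative-control probes.
Pipeline order is fixed: background subtraction → per-sample normalization
factors from invariant-copy control probes → scaling → low-count exclusion →
variability classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FeatureMatrix, SampleTable, ValidationError

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class NormalizedCounts:
    """Background-corrected, per-sample-scaled counts plus the factors used."""

    matrix: FeatureMatrix
    normalization_factor: pd.Series  # per sample, > 0
    background_per_sample: pd.Series

    @property
    def values(self) -> pd.DataFrame:
        return self.matrix.values


@dataclass
class VariabilityCall:
    probe_id: str
    cv: float  # sd/mean, NaN when mean is 0
    n_outlier_samples: int
    is_variable: bool
    mean: float = float("nan")


def background_correct(raw: FeatureMatrix, negative_ids: list[str]) -> tuple[FeatureMatrix, pd.Series]:
    """Subtract each sample's mean negative-control count from every probe.

    Corrected counts are clamped at 0.  Negative probes stay in the output
    for QC.  Returns the corrected matrix and the per-sample background.
    """
    negative_ids = [p for p in negative_ids if p in raw.values.index]
    if not negative_ids:
        raise ConfigurationError("no negative control probes present in the matrix")
    background = raw.values.loc[negative_ids].mean(axis=0)
    corrected = (raw.values - background).clip(lower=0)
    return FeatureMatrix(corrected, raw.coords), background


def normalization_factors(
    corrected: FeatureMatrix, invariant_ids: list[str], literal: bool = False
) -> pd.Series:
    """Per-sample scale factors from invariant-copy control probes.

    Default (corrective) mode: factor_s = grand_mean / sample_mean_s of the
    invariant probes, so that multiplying a sample by its factor equalises
    invariant-probe signal across samples.  ``literal=True`` computes the
    reciprocal ratio (sample_mean / grand_mean) instead.
    """
    invariant_ids = [p for p in invariant_ids if p in corrected.values.index]
    if not invariant_ids:
        raise ConfigurationError("no invariant control probes present in the matrix")
    sample_means = corrected.values.loc[invariant_ids].mean(axis=0)
    grand_mean = float(corrected.values.loc[invariant_ids].to_numpy().mean())
    zero = sample_means[sample_means == 0]
    if len(zero):
        raise ValidationError(
            f"zero invariant-probe mean for sample(s): {list(zero.index)}"
        )
    if literal:
        return sample_means / grand_mean
    return grand_mean / sample_means


def normalize(
    corrected: FeatureMatrix,
    factors: pd.Series,
    background: pd.Series | None = None,
) -> NormalizedCounts:
    """Scale each sample's corrected counts by its normalization factor."""
    missing = [s for s in corrected.sample_ids if s not in factors.index]
    if missing:
        raise ValidationError(f"no normalization factor for sample(s): {missing}")
    values = corrected.values * factors[corrected.sample_ids]
    if background is None:
        background = pd.Series(0.0, index=corrected.sample_ids)
    return NormalizedCounts(
        matrix=FeatureMatrix(values, corrected.coords),
        normalization_factor=factors[corrected.sample_ids].astype(float),
        background_per_sample=background[corrected.sample_ids].astype(float),
    )


def exclude_low_count_probes(
    normalized: NormalizedCounts | FeatureMatrix, min_mean: float = 100.0
) -> tuple[FeatureMatrix, list[str]]:
    """Drop probes whose mean count across all samples is < ``min_mean``."""
    fm = normalized.matrix if isinstance(normalized, NormalizedCounts) else normalized
    means = fm.values.mean(axis=1)
    dropped = list(means.index[means < min_mean])
    if dropped:
        logger.info("excluding %d probes with mean count < %g: %s", len(dropped), min_mean, dropped)
    kept = fm.subset_features([p for p in fm.feature_ids if p not in set(dropped)])
    return kept, dropped


def classify_variability(
    normalized: NormalizedCounts | FeatureMatrix,
    cv_threshold: float = 0.1,
    deviation: float = 0.30,
    min_individuals: int = 2,
    probe_ids: list[str] | None = None,
) -> list[VariabilityCall]:
    """Call probes copy-number variable by CV or by the outlier rule.

    A probe is variable iff its coefficient of variation (sample sd, n-1
    denominator, over the full cohort) >= ``cv_threshold``, or at least
    ``min_individuals`` samples deviate from the cohort mean by
    >= ``deviation`` (counts >= mean*(1+dev) or <= mean*(1-dev)).
    Probes with mean 0 get an undefined CV and are called invariant.
    """
    fm = normalized.matrix if isinstance(normalized, NormalizedCounts) else normalized
    if fm.values.shape[1] < 2:
        raise ValidationError("variability classification needs >= 2 samples")
    if probe_ids is None:
        probe_ids = fm.feature_ids
    calls = []
    for pid in probe_ids:
        vals = fm.values.loc[pid].dropna().to_numpy(dtype=float)
        mean = vals.mean() if len(vals) else float("nan")
        if not len(vals) or mean == 0:
            logger.warning("probe %s: mean 0 or all-missing, CV undefined", pid)
            calls.append(VariabilityCall(pid, float("nan"), 0, False, mean))
            continue
        cv = vals.std(ddof=1) / mean
        hi = vals >= mean * (1 + deviation)
        lo = vals <= mean * (1 - deviation)
        n_out = int((hi | lo).sum())
        is_var = (cv >= cv_threshold) or (n_out >= min_individuals)
        calls.append(VariabilityCall(pid, float(cv), n_out, bool(is_var), float(mean)))
    return calls


def qc_gender(
    normalized: NormalizedCounts | FeatureMatrix,
    sry_ids: list[str],
    x_invariant_ids: list[str],
    samples: SampleTable,
    sry_fraction: float = 0.1,
    x_band: tuple[float, float] = (0.25, 0.75),
) -> pd.Series:
    """Check recorded sexes against sex-chromosome control probes.

    A female fails if her mean SRY-probe count exceeds ``sry_fraction`` of
    the male median; a male fails if his mean X-invariant count falls outside
    ``x_band`` × (female median) — females carry twice the male X dose, so
    the expected male/female ratio is 0.5.  Returns a boolean pass flag per
    sample (True = consistent).
    """
    fm = normalized.matrix if isinstance(normalized, NormalizedCounts) else normalized
    sry_ids = [p for p in sry_ids if p in fm.values.index]
    x_invariant_ids = [p for p in x_invariant_ids if p in fm.values.index]
    if not sry_ids and not x_invariant_ids:
        logger.warning("no gender control probes present; gender QC skipped")
        return pd.Series(True, index=fm.sample_ids)

    males = [s for s in samples.samples_of(sex="male") if s in fm.sample_ids]
    females = [s for s in samples.samples_of(sex="female") if s in fm.sample_ids]
    flags = pd.Series(True, index=fm.sample_ids)

    if sry_ids and males and females:
        sry = fm.values.loc[sry_ids].mean(axis=0)
        male_median = float(sry[males].median())
        if male_median > 0:
            flags[females] &= sry[females] <= sry_fraction * male_median
    if x_invariant_ids and males and females:
        xv = fm.values.loc[x_invariant_ids].mean(axis=0)
        female_median = float(xv[females].median())
        if female_median > 0:
            lo, hi = x_band
            flags[males] &= (xv[males] > lo * female_median) & (
                xv[males] < hi * female_median
            )
    return flags
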