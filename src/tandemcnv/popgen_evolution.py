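"""Population differentiation, primate comparison and selective constraint.

V_ST is the ANOVA analogue of F_ST for a continuous copy-number phenotype:

    V_ST = (V_total - V_within) / V_total

where V_total is the variance over all samples and V_within the
sample-size-weighted mean of the within-population variances (all variances
with the n-1 denominator).  V_ST lies in [0, 1] up to sampling noise; values
above 0.2 mark strong inter-population divergence, a possible signature of
local selection.  Sex-chromosome loci are stratified by sex and the mean of
the male and female statistics reported.

The primate comparison expresses each species' normalized signal as a fold
change over the (sex-matched, for X/Y loci) human mean; because probe/target
mismatches depress binding, records are retained only above per-direction
probe-identity thresholds (gains >= 95%, losses >= 98%).  Selective
constraint compares dN/dS distributions between multicopy genes and the
single-copy background with a two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class VstRecord:
    probe_id: str
    vst: float  # floored at 0 for reporting; NaN when undefined
    vst_raw: float  # unfloored value
    v_total: float
    v_within: float
    group_sizes: dict
    vst_male: float | None = None
    vst_female: float | None = None
    flag: str = ""


@dataclass
class PrimateRecord:
    probe_id: str
    species: str
    percent_identity: float
    normalized_count: float
    human_mean: float
    fold_change: float
    direction: str  # gain | loss
    retained: bool
    flagged_3fold: bool


@dataclass
class DnDsRecord:
    gene: str
    dnds: float
    percent_aa_identity: float
    is_multicopy: bool


# ---------------------------------------------------------------------------
# V_ST


def vst(
    values: pd.Series, groups: pd.Series, probe_id: str = "", min_per_group: int = 2
) -> VstRecord:
    """One-way variance decomposition of per-sample values over populations.

    Missing values are dropped; needs >= 2 groups with >= ``min_per_group``
    samples each.  When the total variance is 0 the statistic is undefined
    and reported as NaN with a flag.
    """
    values = values.dropna()
    groups = groups.loc[values.index]
    sizes = groups.value_counts()
    sizes = sizes[sizes >= min_per_group]
    if len(sizes) < 2:
        raise ValidationError(
            f"vst needs >= 2 groups with >= {min_per_group} samples, got {sizes.to_dict()}"
        )
    keep = groups.isin(sizes.index)
    values, groups = values[keep], groups[keep]

    x = values.to_numpy(dtype=float)
    v_total = float(np.var(x, ddof=1))
    n_k = sizes.to_numpy(dtype=float)
    var_k = np.array(
        [np.var(values[groups == g].to_numpy(dtype=float), ddof=1) for g in sizes.index]
    )
    v_within = float((n_k * var_k).sum() / n_k.sum())
    if v_total == 0:
        logger.warning("probe %s: total variance 0, V_ST undefined", probe_id)
        return VstRecord(
            probe_id, float("nan"), float("nan"), 0.0, v_within,
            sizes.to_dict(), flag="v_total_zero",
        )
    raw = (v_total - v_within) / v_total
    return VstRecord(probe_id, max(0.0, raw), raw, v_total, v_within, sizes.to_dict())


def vst_sex_aware(
    values: pd.Series,
    groups: pd.Series,
    sexes: pd.Series,
    chrom: str,
    probe_id: str = "",
) -> VstRecord:
    """V_ST for sex-chromosome loci: computed per sex, then averaged.

    chrY loci use males only (no averaging).  If one sex's statistic is
    undefined the other is reported alone with a flag.
    """
    if chrom not in ("chrX", "chrY", "X", "Y"):
        raise ValidationError(f"vst_sex_aware expects a sex chromosome, got {chrom}")
    is_y = chrom in ("chrY", "Y")

    def _stratum(sex: str) -> VstRecord | None:
        ids = sexes.index[sexes == sex].intersection(values.index)
        if len(ids) == 0:
            return None
        try:
            return vst(values[ids], groups[ids], probe_id=f"{probe_id}|{sex}")
        except ValidationError:
            return None

    male = _stratum("male")
    if is_y:
        if male is None:
            raise ValidationError(f"probe {probe_id}: no male samples for chrY V_ST")
        male.probe_id = probe_id
        male.vst_male = male.vst
        return male

    female = _stratum("female")
    if male is None or female is None:
        raise ValidationError(f"probe {probe_id}: both sexes required for chrX V_ST")
    vm, vf = male.vst, female.vst
    parts = [v for v in (vm, vf) if not np.isnan(v)]
    flag = "" if len(parts) == 2 else "one_sex_undefined"
    combined = float(np.mean(parts)) if parts else float("nan")
    raw = float(np.mean([v for v in (male.vst_raw, female.vst_raw) if not np.isnan(v)])) if parts else float("nan")
    return VstRecord(
        probe_id=probe_id,
        vst=combined,
        vst_raw=raw,
        v_total=float("nan"),
        v_within=float("nan"),
        group_sizes={"male": male.group_sizes, "female": female.group_sizes},
        vst_male=vm,
        vst_female=vf,
        flag=flag,
    )


def flag_differentiated(records: list[VstRecord], threshold: float = 0.2) -> list[VstRecord]:
    """Records with V_ST strictly above ``threshold``."""
    return [r for r in records if not np.isnan(r.vst) and r.vst > threshold]


# ---------------------------------------------------------------------------
# primate comparison


def primate_invariant_subset(
    primate_counts: pd.DataFrame,
    human_relative_means: pd.Series,
    tolerance: float = 0.20,
    min_controls: int = 3,
) -> dict[str, list[str]]:
    """Species-specific invariant-control subsets for normalization.

    ``primate_counts``: background-corrected counts, invariant probes ×
    primate samples (one column per species sample).  Relative values are
    each probe's share of the invariant-probe total in that sample; a control
    is kept for a species iff its relative share differs from the human
    relative mean by < ``tolerance`` (fractional).  Fewer than
    ``min_controls`` passing controls aborts that species.
    """
    out: dict[str, list[str]] = {}
    for sample in primate_counts.columns:
        col = primate_counts[sample]
        total = float(col.sum())
        if total <= 0:
            raise ValidationError(f"species sample {sample}: non-positive control total")
        rel = col / total
        dev = (rel - human_relative_means).abs() / human_relative_means
        passing = list(dev.index[dev < tolerance])
        if len(passing) < min_controls:
            raise ValidationError(
                f"species sample {sample}: only {len(passing)} invariant controls pass "
                f"(< {min_controls}); normalization aborted"
            )
        out[sample] = passing
    return out


def human_relative_invariant_means(human_counts: pd.DataFrame) -> pd.Series:
    """Mean per-sample share of each invariant probe in the human cohort."""
    rel = human_counts.div(human_counts.sum(axis=0), axis=1)
    return rel.mean(axis=1)


def primate_fold_change(
    species_normalized: pd.DataFrame,
    human_mean_per_probe: pd.Series,
    identities: pd.DataFrame,
    gain_min_identity: float = 95.0,
    loss_min_identity: float = 98.0,
    fold_flag: float = 3.0,
) -> list[PrimateRecord]:
    """Fold change of each probe in each species over the human mean.

    ``species_normalized``: probes × species samples; ``identities``:
    probe × species percent identity of the probe against that species'
    genome.  ``direction`` is gain iff fold > 1; retention needs identity >=
    95% for gains and >= 98% for losses (mismatches depress binding, so an
    apparent loss at low identity is unreliable).  Retained records with
    fold >= 3 or <= 1/3 are flagged.  For sex-chromosome probes the caller
    supplies a sex-matched ``human_mean_per_probe``.
    """
    records: list[PrimateRecord] = []
    for species in species_normalized.columns:
        for pid in species_normalized.index:
            val = species_normalized.loc[pid, species]
            if pd.isna(val):
                continue
            hm = human_mean_per_probe.get(pid, np.nan)
            if pd.isna(hm) or hm == 0:
                logger.info("probe %s: human mean 0/missing, skipped for %s", pid, species)
                continue
            ident = float(identities.loc[pid, species]) if pid in identities.index else np.nan
            if pd.isna(ident):
                continue
            fold = float(val) / float(hm)
            direction = "gain" if fold > 1 else "loss"
            threshold = gain_min_identity if direction == "gain" else loss_min_identity
            retained = ident >= threshold
            flagged = retained and (fold >= fold_flag or fold <= 1.0 / fold_flag)
            records.append(
                PrimateRecord(
                    probe_id=pid,
                    species=species,
                    percent_identity=ident,
                    normalized_count=float(val),
                    human_mean=float(hm),
                    fold_change=fold,
                    direction=direction,
                    retained=bool(retained),
                    flagged_3fold=bool(flagged),
                )
            )
    return records


# ---------------------------------------------------------------------------
# selective constraint


def dnds_compare(
    table: list[DnDsRecord], min_aa_identity: float = 80.0
) -> tuple[float, float, float, float]:
    """Two-sample KS comparison of dN/dS between multicopy and background genes.

    Records with amino-acid identity below ``min_aa_identity`` are excluded
    first.  Returns (ks_statistic, ks_p, fraction dN/dS > 1 in multicopy,
    fraction dN/dS > 1 in background).
    """
    kept = [r for r in table if r.percent_aa_identity >= min_aa_identity]
    multi = np.array([r.dnds for r in kept if r.is_multicopy], dtype=float)
    back = np.array([r.dnds for r in kept if not r.is_multicopy], dtype=float)
    if len(multi) < 2 or len(back) < 2:
        raise ValidationError(
            f"dnds_compare needs >= 2 records per group after filtering, "
            f"got {len(multi)} multicopy / {len(back)} background"
        )
    res = stats.ks_2samp(multi, back, method="auto")
    return (
        float(res.statistic),
        float(res.pvalue),
        float((multi > 1).mean()),
        float((back > 1).mean()),
    )
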