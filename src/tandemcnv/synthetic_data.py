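"""Synthetic study generator with known ground truth.

Emulates the data-generating structure of a multiplexed count assay for
high-copy tandem repeats: counts proportional to copy number with
probe-specific binding efficiencies and sample-level technical scale
factors, a nonspecific background captured by negative-control probes,
invariant-copy normalization probes, and sex-tracking gender controls, with
multiplicative log-normal noise.  Around the count matrix it plants the
downstream signals the pipeline is meant to recover: tag SNPs of chosen r²
(via a latent-threshold construction under Hardy–Weinberg), cis expression
effects of chosen slope, cis methylation effects of chosen normalized slope,
read-depth calibration anchors, and primate count tables with
identity-dependent binding attenuation.

The default cohort mirrors a three-population reference panel: 60 + 60 + 45
samples (CEU/YRI/CHB), sexes balanced.  Every generator takes an explicit
``numpy`` Generator; one seed reproduces all outputs bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    Alignment,
    FeatureMatrix,
    ProbeAnnotation,
    SampleTable,
    ValidationError,
)
from .association import SnpPanel

DEFAULT_SIGMA = 0.05  # multiplicative noise CV for counts


@dataclass
class SimTruth:
    """Ground-truth parameters behind one simulated study."""

    samples: SampleTable
    probes: list[ProbeAnnotation]
    true_cn: pd.DataFrame  # probes × samples, diploid copy number
    probe_efficiency: pd.Series
    sample_scale: pd.Series
    background_mean: float
    sigma: float
    seed: int
    count_gain: float = 100.0  # counts per copy at efficiency 1
    variable_probes: list[str] = field(default_factory=list)
    planted_tags: list[dict] = field(default_factory=list)
    planted_expr_effects: list[dict] = field(default_factory=list)
    planted_meth_effects: list[dict] = field(default_factory=list)

    def probe_ids(self, probe_class: str | None = None) -> list[str]:
        return [
            p.probe_id
            for p in self.probes
            if probe_class is None or p.probe_class == probe_class
        ]


def make_sample_table(
    n_ceu: int = 60, n_yri: int = 60, n_chb: int = 45, species: str = "human"
) -> SampleTable:
    """Cohort table with balanced sexes (alternating within population)."""
    rows = []
    for pop, n in (("CEU", n_ceu), ("YRI", n_yri), ("CHB", n_chb)):
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{pop}{i + 1:03d}",
                    "population": pop,
                    "sex": "male" if i % 2 == 0 else "female",
                    "species": species,
                }
            )
    return SampleTable(pd.DataFrame(rows).set_index("sample_id"))


def default_truth(
    seed: int,
    n_test_probes: int = 40,
    n_negative: int = 8,
    n_invariant: int = 10,
    include_gender: bool = True,
    n_ceu: int = 60,
    n_yri: int = 60,
    n_chb: int = 45,
    cn_range: tuple[float, float] = (2.0, 60.0),
    fraction_variable: float = 0.6,
    cn_spread: float = 0.2,
    n_differentiated: int = 4,
    pop_shift: tuple[float, float, float] = (1.0, 1.5, 0.7),
    efficiency_range: tuple[float, float] = (0.5, 2.0),
    scale_range: tuple[float, float] = (0.7, 1.4),
    background_mean: float = 15.0,
    sigma: float = DEFAULT_SIGMA,
    count_gain: float = 100.0,
) -> SimTruth:
    """A ready-made study: probes, cohort and a true copy-number grid.

    A ``fraction_variable`` share of test probes varies log-normally
    (per-sample CV ``cn_spread``) around a probe-level baseline drawn from
    ``cn_range``; the rest are copy-invariant.  The first
    ``n_differentiated`` variable probes additionally carry per-population
    multipliers (``pop_shift``, CEU/YRI/CHB order) to create genuinely
    differentiated loci.  Test probes get one perfect-identity alignment
    each, spaced so their analysis windows never overlap.
    """
    rng = np.random.default_rng(seed)
    samples = make_sample_table(n_ceu, n_yri, n_chb)
    sample_ids = samples.sample_ids

    probes: list[ProbeAnnotation] = []
    cn_rows: dict[str, np.ndarray] = {}
    pops = samples.df["population"].to_numpy()
    sexes = samples.df["sex"].to_numpy()

    n_variable = int(round(fraction_variable * n_test_probes))
    variable_probes: list[str] = []
    for i in range(n_test_probes):
        pid = f"P{i + 1:03d}"
        chrom = f"chr{(i % 20) + 1}"
        start = 10_000_000 + (i // 20) * 20_000_000
        probes.append(
            ProbeAnnotation(
                probe_id=pid,
                target_name=f"GENE{i + 1}",
                probe_class="test",
                locus_type="tandem",
                alignments=[Alignment(chrom, start, start + 1000, "+", 100.0)],
            )
        )
        baseline = rng.uniform(*cn_range)
        if i < n_variable:
            variable_probes.append(pid)
            cn = baseline * np.exp(rng.normal(0.0, cn_spread, size=len(sample_ids)))
            if i < n_differentiated:
                mult = {"CEU": pop_shift[0], "YRI": pop_shift[1], "CHB": pop_shift[2]}
                cn = cn * np.array([mult[p] for p in pops])
        else:
            cn = np.full(len(sample_ids), baseline)
        cn_rows[pid] = cn

    for i in range(n_negative):
        pid = f"NEG{i + 1:02d}"
        probes.append(ProbeAnnotation(pid, pid, "negative", "unknown", []))
        cn_rows[pid] = np.zeros(len(sample_ids))
    for i in range(n_invariant):
        pid = f"INV{i + 1:02d}"
        probes.append(ProbeAnnotation(pid, pid, "invariant", "unknown", []))
        cn_rows[pid] = np.full(len(sample_ids), 2.0)
    if include_gender:
        probes.append(
            ProbeAnnotation(
                "SRY", "SRY", "gender", "unknown",
                [Alignment("chrY", 2_650_000, 2_651_000, "+", 100.0)],
            )
        )
        cn_rows["SRY"] = np.where(sexes == "male", 1.0, 0.0)
        probes.append(
            ProbeAnnotation(
                "XINV", "XINV", "gender", "unknown",
                [Alignment("chrX", 50_000_000, 50_001_000, "+", 100.0)],
            )
        )
        cn_rows["XINV"] = np.where(sexes == "male", 1.0, 2.0)

    probe_ids = [p.probe_id for p in probes]
    true_cn = pd.DataFrame(cn_rows, index=sample_ids).T.loc[probe_ids]
    efficiency = pd.Series(
        rng.uniform(*efficiency_range, size=len(probe_ids)), index=probe_ids
    )
    scale = pd.Series(rng.uniform(*scale_range, size=len(sample_ids)), index=sample_ids)
    return SimTruth(
        samples=samples,
        probes=probes,
        true_cn=true_cn,
        probe_efficiency=efficiency,
        sample_scale=scale,
        background_mean=background_mean,
        sigma=sigma,
        seed=seed,
        count_gain=count_gain,
        variable_probes=variable_probes,
    )


def simulate_counts(truth: SimTruth, rng: np.random.Generator) -> FeatureMatrix:
    """Raw counts: scale_s × (gain × efficiency_p × cn(p,s) + background) × exp(σz).

    ``count_gain`` sets the counts-per-copy scale of the assay (hundreds of
    counts for a 2-copy locus at typical efficiency).  Negative controls
    carry cn 0 (background only), invariant controls cn 2, gender controls
    the sex-determined dose, all through the same formula.
    """
    if truth.sigma < 0:
        raise ValidationError(f"noise sigma must be >= 0, got {truth.sigma}")
    cn = truth.true_cn
    eff = truth.probe_efficiency[cn.index].to_numpy()[:, None]
    scale = truth.sample_scale[cn.columns].to_numpy()[None, :]
    noise = np.exp(truth.sigma * rng.standard_normal(cn.shape))
    raw = scale * (truth.count_gain * eff * cn.to_numpy() + truth.background_mean) * noise
    return FeatureMatrix(pd.DataFrame(raw, index=cn.index, columns=cn.columns))


# ---------------------------------------------------------------------------
# tag SNPs


def _normal_scores(values: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(values, method="average")
    x = stats.norm.ppf((ranks - 0.375) / (len(values) + 0.25))
    sd = x.std()
    if sd == 0:
        raise ValidationError("cannot plant a tag on a constant copy-number vector")
    return (x - x.mean()) / sd


def plant_tag_codes(
    cn_values: np.ndarray, target_r2: float, maf: float, rng: np.random.Generator
) -> np.ndarray:
    """Genotype codes whose squared correlation with CN approximates a target.

    A latent Gaussian u = a·x + √(1−a²)·e (x the normal scores of CN) is
    thresholded at the Hardy–Weinberg quantiles of the chosen allele
    frequency; the mixing weight a is solved from the closed-form
    genotype–latent correlation so that corr(g, x)² ≈ target.  Targets above
    the discretisation ceiling saturate at a = 1, making the genotype a
    deterministic monotone function of CN.
    """
    if not (0.0 < target_r2 <= 1.0):
        raise ValidationError(f"target_r2 must lie in (0, 1], got {target_r2}")
    q = maf
    x = _normal_scores(np.asarray(cn_values, dtype=float))
    t1 = stats.norm.ppf((1 - q) ** 2)
    t2 = stats.norm.ppf(1 - q**2)
    c = (stats.norm.pdf(t1) + stats.norm.pdf(t2)) / math.sqrt(2 * q * (1 - q))
    a = min(1.0, math.sqrt(target_r2) / c)
    u = a * x
    if a < 1.0:
        u = u + math.sqrt(1 - a * a) * rng.standard_normal(len(x))
    return np.where(u <= t1, 0, np.where(u <= t2, 1, 2))


def _codes_to_calls(codes: np.ndarray, alleles: tuple[str, str] = ("A", "G")) -> list[str]:
    a, b = alleles
    lut = {0: a + a, 1: "".join(sorted(a + b)), 2: b + b}
    return [lut[int(c)] for c in codes]


def simulate_snps(
    truth: SimTruth,
    cn: pd.DataFrame | None = None,
    n_null_per_probe: int = 30,
    planted_tags: list[tuple[str, float]] | None = None,
    maf_range: tuple[float, float] = (0.15, 0.5),
    flank: int = 250_000,
    rng: np.random.Generator | None = None,
) -> SnpPanel:
    """SNP panel with coordinates inside each test probe's LD window.

    Null SNPs are drawn under Hardy–Weinberg at uniform MAFs, independent of
    copy number.  ``planted_tags`` lists (probe_id, target_r2) pairs; each
    planted SNP's realized r² against the probe's CN is recorded in
    ``truth.planted_tags``.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1)
    if cn is None:
        cn = truth.true_cn
    planted = dict(planted_tags or [])
    sample_ids = list(cn.columns)
    n = len(sample_ids)

    calls: dict[str, list] = {}
    meta_rows: list[dict] = []
    for probe in truth.probes:
        if probe.probe_class != "test" or not probe.alignments:
            continue
        aln = probe.alignments[0]
        lo = max(0, aln.start - flank + 1000)
        hi = aln.end + flank - 1000
        positions = np.sort(rng.integers(lo, hi, size=n_null_per_probe))
        for j, pos in enumerate(positions):
            snp_id = f"{probe.probe_id}_snp{j + 1:03d}"
            maf = rng.uniform(*maf_range)
            codes = rng.binomial(2, maf, size=n)
            calls[snp_id] = _codes_to_calls(codes)
            meta_rows.append({"snp_id": snp_id, "chrom": aln.chrom, "pos": int(pos)})
        if probe.probe_id in planted:
            target = planted[probe.probe_id]
            snp_id = f"{probe.probe_id}_tag"
            maf = rng.uniform(0.25, 0.5)
            cn_vec = cn.loc[probe.probe_id].to_numpy(dtype=float)
            codes = plant_tag_codes(cn_vec, target, maf, rng)
            calls[snp_id] = _codes_to_calls(codes)
            pos = (aln.start + aln.end) // 2 + 5000
            meta_rows.append({"snp_id": snp_id, "chrom": aln.chrom, "pos": int(pos)})
            if np.ptp(codes) > 0:
                realized = float(np.corrcoef(codes, cn_vec)[0, 1] ** 2)
            else:
                realized = 0.0
            truth.planted_tags.append(
                {
                    "probe_id": probe.probe_id,
                    "snp_id": snp_id,
                    "target_r2": target,
                    "realized_r2": realized,
                    "maf": maf,
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("snp_id")
    calls_df = pd.DataFrame.from_dict(
        calls, orient="index", columns=sample_ids
    ).astype("string")
    return SnpPanel.from_calls(calls_df.loc[meta.index], meta)


# ---------------------------------------------------------------------------
# expression & methylation


def simulate_expression(
    truth: SimTruth,
    cn: pd.DataFrame | None = None,
    n_null_per_probe: int = 10,
    planted_effects: list[tuple[str, float]] | None = None,
    noise_sd: float = 0.3,
    baseline: float = 8.0,
    null_sd: float = 1.0,
    flank: int = 500_000,
    rng: np.random.Generator | None = None,
) -> FeatureMatrix:
    """log2 expression matrix with TSS coordinates inside probe windows.

    Planted transcripts follow expr = baseline + b·cn + N(0, noise_sd²);
    null transcripts are N(baseline, null_sd²), independent of copy number,
    and pass the expression filter by construction.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 2)
    if cn is None:
        cn = truth.true_cn
    planted = dict(planted_effects or [])
    sample_ids = list(cn.columns)
    n = len(sample_ids)

    rows: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for probe in truth.probes:
        if probe.probe_class != "test" or not probe.alignments:
            continue
        aln = probe.alignments[0]
        for j in range(n_null_per_probe):
            tid = f"{probe.probe_id}_tx{j + 1:02d}"
            rows[tid] = baseline + null_sd * rng.standard_normal(n)
            tss = int(rng.integers(max(0, aln.start - flank + 1000), aln.end + flank - 1000))
            meta_rows.append({"feature_id": tid, "chrom": aln.chrom, "pos": tss})
        if probe.probe_id in planted:
            b = planted[probe.probe_id]
            tid = f"{probe.probe_id}_tx_planted"
            cn_vec = cn.loc[probe.probe_id].to_numpy(dtype=float)
            rows[tid] = baseline + b * (cn_vec - cn_vec.mean()) + noise_sd * rng.standard_normal(n)
            meta_rows.append(
                {"feature_id": tid, "chrom": aln.chrom, "pos": int(aln.end + 10_000)}
            )
            truth.planted_expr_effects.append(
                {"probe_id": probe.probe_id, "transcript_id": tid, "slope": b}
            )
    coords = pd.DataFrame(meta_rows).set_index("feature_id")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids).loc[
        coords.index
    ]
    return FeatureMatrix(values, coords)


def simulate_methylation(
    truth: SimTruth,
    cn: pd.DataFrame | None = None,
    n_null_per_probe: int = 20,
    planted_effects: list[tuple[str, float]] | None = None,
    noise_sd: float = 0.05,
    base_beta: float = 0.3,
    null_beta_sd: float = 0.15,
    pool_size: int = 2000,
    flank: int = 500_000,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """CpG beta-value matrix plus an independent genome-wide autosomal pool.

    A planted effect with target normalized slope ν uses per-copy slope
    ν / (max cn − min cn), so the normalized-slope statistic recovers ν at
    zero noise.  Betas are clipped to [0, 1].  The pool contains only null
    CpGs (coordinates far from every probe) and feeds the resampling
    permutation null.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 3)
    if cn is None:
        cn = truth.true_cn
    planted = dict(planted_effects or [])
    sample_ids = list(cn.columns)
    n = len(sample_ids)

    def null_beta() -> np.ndarray:
        return np.clip(0.5 + null_beta_sd * rng.standard_normal(n), 0.0, 1.0)

    rows: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for probe in truth.probes:
        if probe.probe_class != "test" or not probe.alignments:
            continue
        aln = probe.alignments[0]
        for j in range(n_null_per_probe):
            cid = f"{probe.probe_id}_cg{j + 1:03d}"
            rows[cid] = null_beta()
            pos = int(rng.integers(max(0, aln.start - flank + 1000), aln.end + flank - 1000))
            meta_rows.append({"feature_id": cid, "chrom": aln.chrom, "pos": pos})
        if probe.probe_id in planted:
            nu = planted[probe.probe_id]
            cid = f"{probe.probe_id}_cg_planted"
            cn_vec = cn.loc[probe.probe_id].to_numpy(dtype=float)
            cn_range = float(np.ptp(cn_vec))
            if cn_range == 0:
                raise ValidationError(
                    f"cannot plant a methylation effect on invariant probe {probe.probe_id}"
                )
            slope = nu / cn_range
            beta = base_beta + slope * (cn_vec - cn_vec.min()) + noise_sd * rng.standard_normal(n)
            rows[cid] = np.clip(beta, 0.0, 1.0)
            meta_rows.append(
                {"feature_id": cid, "chrom": aln.chrom, "pos": int(aln.end + 20_000)}
            )
            truth.planted_meth_effects.append(
                {"probe_id": probe.probe_id, "cpg_id": cid, "normalized_slope": nu}
            )
    coords = pd.DataFrame(meta_rows).set_index("feature_id")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids).loc[
        coords.index
    ]
    meth = FeatureMatrix(values, coords)

    pool_rows = {f"pool_cg{j + 1:06d}": null_beta() for j in range(pool_size)}
    pool_coords = pd.DataFrame(
        {
            "feature_id": list(pool_rows),
            "chrom": "chr21",
            "pos": np.arange(len(pool_rows)) * 500 + 1_000_000,
        }
    ).set_index("feature_id")
    pool = FeatureMatrix(
        pd.DataFrame.from_dict(pool_rows, orient="index", columns=sample_ids),
        pool_coords,
    )
    return meth, pool


# ---------------------------------------------------------------------------
# read depth & primates


def simulate_readdepth(
    truth: SimTruth,
    noise_cv: float = 0.05,
    duplicate_fraction: float = 0.0,
    sample_subset: list[str] | None = None,
    probe_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-form read-depth CN records: rd = cn × exp(σz), optional duplicates.

    Duplicate cells are emitted as a symmetric pair (×1.1, ×0.9) whose mean
    is the undduplicated value.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 4)
    if probe_ids is None:
        probe_ids = truth.probe_ids("test")
    if sample_subset is None:
        sample_subset = list(truth.true_cn.columns)
    rows = []
    for pid in probe_ids:
        for s in sample_subset:
            rd = float(truth.true_cn.loc[pid, s]) * math.exp(
                noise_cv * rng.standard_normal()
            )
            if rng.uniform() < duplicate_fraction:
                rows.append({"probe_id": pid, "sample_id": s, "cn": rd * 1.1})
                rows.append({"probe_id": pid, "sample_id": s, "cn": rd * 0.9})
            else:
                rows.append({"probe_id": pid, "sample_id": s, "cn": rd})
    return pd.DataFrame(rows)


def attenuation(percent_identity: float | np.ndarray, base: float = 0.97) -> np.ndarray:
    """Binding-efficiency attenuation from probe/target divergence.

    Monotone non-decreasing in identity with attenuation(100) = 1.
    """
    return np.power(base, 100.0 - np.asarray(percent_identity, dtype=float))


def simulate_primate(
    truth: SimTruth,
    species_cn: pd.DataFrame,
    identity: pd.DataFrame,
    sigma: float = DEFAULT_SIGMA,
    species_scale: pd.Series | None = None,
    attenuation_base: float = 0.97,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Primate raw counts with identity-attenuated binding efficiency.

    ``species_cn``: test probes × species samples true copy number;
    ``identity``: probe × species percent identity (invariant/negative
    controls default to 100 if absent).  Returns raw counts over test,
    negative and invariant probes plus the completed identity table.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 5)
    species = list(species_cn.columns)
    if species_scale is None:
        species_scale = pd.Series(1.0, index=species)
    all_ids = truth.probe_ids("test") + truth.probe_ids("negative") + truth.probe_ids("invariant")
    ident = identity.reindex(index=all_ids, columns=species).fillna(100.0)

    cn = pd.DataFrame(0.0, index=all_ids, columns=species)
    for pid in truth.probe_ids("test"):
        if pid in species_cn.index:
            cn.loc[pid] = species_cn.loc[pid]
    for pid in truth.probe_ids("invariant"):
        cn.loc[pid] = 2.0

    eff = truth.probe_efficiency.reindex(all_ids).fillna(1.0).to_numpy()[:, None]
    att = attenuation(ident.to_numpy(), attenuation_base)
    scale = species_scale[species].to_numpy()[None, :]
    noise = np.exp(sigma * rng.standard_normal((len(all_ids), len(species))))
    raw = scale * (truth.count_gain * eff * att * cn.to_numpy() + truth.background_mean) * noise
    return FeatureMatrix(pd.DataFrame(raw, index=all_ids, columns=species)), ident
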