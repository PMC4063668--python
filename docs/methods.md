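# Methods

## Count model and normalization

A multiplexed digital count assay reports, for probe *p* in sample *s*, a
count proportional to the diploid copy number of the probe's target:

    raw(p, s) = scale_s · (gain · eff_p · cn(p, s) + bg) · exp(σ·z)

where `eff_p` is a probe-specific binding efficiency (unknown, so counts are
only *relatively* quantitative per probe), `scale_s` a sample-level technical
factor (input DNA, hybridisation efficiency), `bg` a nonspecific background
shared by all probes, and the noise multiplicative log-normal with CV σ
(counts are positive and heteroscedastic; σ defaults to 0.05). Negative
controls target artificial sequences (cn = 0), invariant controls copy-2
autosomal loci, gender controls SRY (1/0 copies in males/females) and an
invariant X locus (1/2).

Processing order is fixed: **background** (subtract each sample's mean
negative-control count; clamped at 0 — the source description is silent on
negatives), **normalization factors** from the invariant controls,
**scaling**, **low-count exclusion** (mean < 100 across samples), then
**variability classification**. A factor defined as sample invariant mean ÷
grand mean would *amplify* sample-level intensity differences, so the default
implements the corrective reciprocal grand/sample — the only direction under
which invariant probes end up invariant, which everything downstream assumes;
`literal=True` computes the sample/grand ratio instead for comparability with
conventions stated that way. Note the corrective factor leaves a global constant free
(the grand mean moves with any rescaled sample), so normalized values are
defined up to one multiplicative constant — irrelevant to every downstream
statistic, all of which are per-probe scale-free.

The variability rule (CV ≥ 0.1, or counts ≥ 30% above/below the cohort mean
in ≥ 2 individuals) uses the n−1 sample standard deviation and takes the reference mean over the
full analyzed cohort rather than per ancestry group; both choices are
configurable.
Variability is assessed on normalized counts.

## Calibration to absolute copy number

Counts become absolute diploid copy numbers through read-depth estimates
available for a calibration subset shared between assays:

    CN(p, s) = count(p, s) / median_shared(count(p, ·)) · median_shared(rd_cn(p, ·))

Duplicate read-depth entries are averaged first; medians are taken over the
shared subset only (≥ 3 complete samples per probe, configurable) and the
conversion then applies to *all* samples. Dividing by the median *count* (not
the median read-depth CN) is the dimensionally consistent form: it maps the
sample whose count sits at the probe's median exactly onto the median
read-depth copy number, making that pair the calibration point. Copy numbers
stay continuous — no integer rounding, as fractional population mean copy
numbers are meaningful for multi-allelic loci. Medians give 50%-breakdown
robustness: gross outliers in a minority of calibration samples that stay on
their side of the median leave every clean sample's CN untouched. Calibration
is exactly invariant to probe efficiency and strictly monotone in counts.

## V_ST

For values y over populations k with sizes n_k:

    V_total  = Var(y)                    (n−1 denominator)
    V_within = Σ_k n_k·Var_k / Σ_k n_k   (each Var_k with n−1)
    V_ST     = (V_total − V_within) / V_total

The size weighting of within-group variances is the standard continuous-CNV
form and keeps the statistic in [0, 1]. Sampling noise can push the raw
value slightly negative; reported values floor at 0 with the raw value
retained. V_ST is invariant to shifting and scaling the values, so it can be
computed on normalized counts or calibrated CN interchangeably. X-linked loci
are computed within each sex and the two statistics averaged (chrY: males
only); a locus where one sex's statistic is undefined reports the other with
a flag.

## Association scans

SNP dosages use the 0/1/2 coding with the alphabetically first observed
allele as 0 — orientation only flips the sign of r and cannot affect R².
Hardy–Weinberg is tested by the 1-df chi-square on expected genotype counts
without continuity correction. The basic SNP
filter removes MAF < 0.1, HWE p < 0.05 and tri-allelic sites; the stringent
filter additionally drops sites flagged (as inputs) multi-mapped over a 51-bp
window, inside segmental duplications, or inside known CNV regions.

Correlations are Pearson r (LD, expression) or Spearman rho with average
ranks (methylation), pairwise-complete, ≥ 3 pairs, with the OLS slope of the
feature on copy number. Permutation p-values are two-tailed with a strict
inequality — the fraction of null |stat| *exceeding* |observed| — and p = 0 is
reported with a below-resolution flag rather than a pseudo-count. Two null
schemes: **shuffle_samples** permutes the probe vector (equivalent to
permuting either side; used for LD and expression, default 10,000 rounds) and
**resample_features** draws replacement feature vectors from a genome-wide
pool (the methylation null, default 1,000 draws, without replacement while
the pool lasts; smaller pools fall back to replacement with a warning).

The tag-SNP scan reports, per population set (each population plus combined;
per-sex strata for X/Y loci), the in-window SNP with maximal R², ties broken
by smaller nominal p then genomic position. Windows are ±250 kb around each ≥ 95%-identity alignment, merged
per chromosome; expression and methylation use ±500 kb (methylation windows
exclude chrY and unplaced `_random` scaffolds). The expression filter (mean
log2 < 6 or IQR < 0.25 removed) runs before windowing; records where the
transcript is the probe's own target gene are flagged as auto-correlations.

The methylation pipeline is a strict five-stage funnel with per-stage counts
logged: (1) Spearman rho for every probe × in-window CpG on the combined
populations; (2) retain the top 2% by |rho| — implemented as the empirical
98th-percentile cutoff of the run itself, so the numeric threshold emerges
from the data rather than being hard-coded; (3) |normalized slope| > 0.1,
where the **normalized slope** is the OLS slope times the observed CN range,
i.e. the predicted beta-value difference between the lowest and highest
observed copy number; (4) resampling permutation p < 0.01; (5) nominal
p < 0.05 in each population separately. The chrX analysis runs on males only
(combined populations, to avoid X-inactivation as a confounder) and skips the
per-population stage. The ChIP utility computes total-count-normalized
chip/input ratios in 170-bp windows sliding by 85 bp
(⌊(L−170)/85⌋+1 windows); zero-input windows are missing unless a
pseudo-count ε is supplied.

## Primate comparison and dN/dS

Each species is normalized with only those invariant controls whose share of
the invariant-probe total differs < 20% from the human relative mean (≥ 3
passing controls required). Fold change is the species' normalized signal
over the (sex-matched, for X/Y loci) human mean; because probe/target
mismatches depress binding, records are retained only when the probe's
identity in that species is ≥ 95% for gains and ≥ 98% for losses (an
apparent loss with a diverged probe is indistinguishable from poor binding),
and retained records with fold ≥ 3 or ≤ 1/3 are flagged. dN/dS distributions
of multicopy vs background genes are compared by a two-sample
Kolmogorov–Smirnov test (scipy, exact method for small samples) after
excluding orthologs with < 80% amino-acid identity.

## Synthetic-data generator

The generator emulates the study's data-generating structure, not any real
dataset: a 60 + 60 + 45 three-population cohort (CEU/YRI/CHB, sexes
balanced), 40 test probes of which 60% are truly copy-number variable
(per-probe baseline uniform on [2, 60] copies, per-sample log-normal spread
of CV 0.2, matching 5–10-fold population ranges at high copy number), 4 loci
with planted per-population multipliers (1.0/1.5/0.7) for genuine
differentiation, 8 negative and 10 invariant controls, efficiencies uniform
on [0.5, 2], sample scale factors on [0.7, 1.4], background 15 counts, gain
100 counts per copy, σ = 0.05.

Tag SNPs of chosen r² are planted by thresholding a latent Gaussian
u = a·x + √(1−a²)·e (x the normal scores of the CN vector) at the
Hardy–Weinberg quantiles of the chosen allele frequency, with the mixing
weight a solved in closed form from the genotype–latent correlation; targets
above the discretisation ceiling saturate at a = 1 (genotype a deterministic
monotone function of CN). The realized r² is recorded next to the target.
Planted expression effects are linear on the log2 scale; planted methylation
effects use per-copy slope ν/(max cn − min cn) so the normalized-slope
statistic recovers ν exactly at zero noise, betas clipped to [0, 1].
Read-depth anchors carry log-normal noise with optional duplicate records;
primate counts attenuate binding efficiency by 0.97^(100−identity)
(monotone, 1 at full identity).

What the generator does **not** emulate: realistic LD block structure (each
tag is a single planted SNP), spatially correlated methylation, expression
covariance structure, cell-type effects, batch effects beyond a scalar
per-sample factor, or genome-assembly artifacts. Passing recovery tests
therefore demonstrates the correctness and calibration of the *procedures*
under the stated noise model, not performance on real cohort data.

## Problem sizes and numerical choices

The recovery suite runs at the cohort's full sample sizes but moderate
feature counts chosen for a single-CPU run: calibration recovery at 200
probes × 165 samples, permutation calibration with 1,000 tests × 1,000
rounds, planted-effect recovery over 100 replicates each (the methylation
replicates use the 118-sample two-population subset with a 2,000-CpG pool).
Oracle-equivalence checks (V_ST, window arithmetic) use 1,000 random
fixtures at 1e-12 tolerance. Degenerate inputs are never silently imputed:
zero-variance vectors raise, probes with zero medians or too few shared
samples are emitted as missing with a recorded reason, V_ST with zero total
variance is undefined rather than 0, and p = 0 permutation results carry a
resolution flag. Multiple testing is permutation-based only — no FDR layer
is added beyond the staged filters described above.

## Known limitations

Absolute copy numbers inherit any bias of the read-depth anchor; the
pipeline treats it as ground truth. The multicopy-gene discovery rule uses
earliest-end greedy interval scheduling, which maximises the count of
mutually non-overlapping records deterministically but, like the original
rule, cannot distinguish collapsed assemblies from true copies. The
best-tag-SNP R² is a maximum over many correlated tests and is biased upward
at small n; the permutation p of the best SNP accounts for its own test but
not for the selection across SNPs, mirroring the scan it reproduces.
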