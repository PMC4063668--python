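# tandemcnv

Analysis pipeline for **digital copy-number genotyping of macrosatellites and
multicopy genes**: tandem repeats with unit sizes from ~100 bp to tens of kb
whose diploid copy number can run into the hundreds, far beyond what arrays or
naive read counting resolve. Multiplexed digital count assays measure these
loci directly — each probe returns a count proportional to target copy number —
but the raw counts need background correction, per-sample normalization and
calibration to an absolute scale before any population or functional analysis
is meaningful.

The package implements, as reusable library code plus numbered analysis
drivers, the full chain:

1. **Counts** — subtract the per-sample mean of the negative-control probes,
   scale each sample by an invariant-control normalization factor, drop probes
   with mean counts < 100, and call a locus *copy-number variable* when its
   coefficient of variation is ≥ 0.1 or ≥ 2 individuals deviate ≥ 30% from the
   cohort mean. Gender-control probes (SRY and an invariant X locus) flag
   sample swaps.
2. **Calibration** — anchor counts to read-depth copy-number estimates on the
   shared sample subset: CN(p,s) = count(p,s) / median(count(p,·)) ×
   median(CN_rd(p,·)), medians over the shared subset only.
3. **Population differentiation** — the ANOVA analogue of F_ST for a
   continuous trait, **V_ST = (V_total − V_within)/V_total**, with V_within the
   sample-size-weighted mean of within-population variances; V_ST > 0.2 flags
   strongly differentiated loci. Sex-chromosome loci are computed per sex and
   averaged.
4. **Tag-SNP LD** — for each variable locus, Pearson R² between 0/1/2 SNP
   dosages (MAF ≥ 0.1, HWE p ≥ 0.05, biallelic) and copy number within
   ±250 kb of every probe alignment (≥ 95% identity), per population and
   combined, with a 10,000-round shuffle-permutation p for the best SNP.
5. **Cis expression / methylation** — Pearson correlation with filtered
   transcripts (mean log2 ≥ 6, IQR ≥ 0.25) within ±500 kb; and the five-stage
   methylation filter: Spearman rho for all in-window CpGs → top 2% |rho| →
   |normalized slope| > 0.1 (the predicted beta-value change across the
   observed CN range) → resampling-permutation p < 0.01 against a genome-wide
   CpG pool → replication at p < 0.05 in each population. ChrX runs on males
   only.
6. **Primate comparison & selective constraint** — per-species invariant-probe
   renormalization (controls within 20% of the human relative mean), fold
   change over the (sex-matched) human mean with identity thresholds of 95%
   for gains and 98% for losses and a ≥ 3-fold flag; two-sample
   Kolmogorov–Smirnov comparison of dN/dS between multicopy and background
   genes (records < 80% amino-acid identity excluded).

No external data are required: `tandemcnv.synthetic_data` generates every
input with known planted truth (probe efficiencies, sample scale factors,
background, tag SNPs of chosen r² via a latent-threshold construction, cis
effects of chosen slope), so every stage is testable end to end.

## Worked example

Run the numbered drivers in order (each prints what it found and writes its
tables under `results/`):

```sh
python analysis/01_simulate_study.py
python analysis/02_normalize_and_calibrate.py
python analysis/03_population_differentiation.py
python analysis/04_tag_snp_ld.py
python analysis/05_expression_methylation.py
python analysis/06_primates_and_dnds.py
```

Typical output (seed 1):

```
called variable: 24/40 (60%); truth: 24 (60%)
  sensitivity 24/24, false calls 0
...
4 loci exceed V_ST > 0.2 (['P001', 'P002', 'P003', 'P004'])
...
median best R2 across 24 variable loci: 0.126
planted tag probe P001: best R2 = 0.474 (target r2 = 0.5)
loci with a tag SNP at R2 >= 0.8: 0 (most loci lack an informative tag)
...
methylation funnel: {'tested_pairs': 481, ..., 'after_replication': 1}
  P003 ~ P003_cg_planted: rho = 0.726, normalized slope = 0.261, p_perm = 0.0000
...
  P001 in chimp: fold = 3.08 (gain, identity 96.0%)
dN/dS KS: D = 0.286, p = 9.51e-07; fraction dN/dS > 1: multicopy 14.4% vs background 2.9%
```

Reading it: the variability classifier recovers exactly the 24 loci generated
as copy-number variable; V_ST flags exactly the four loci planted with
population-specific copy-number shifts; the LD scan finds the one planted tag
SNP near its target r² while the median best R² across the mostly-untagged
loci stays low — multi-allelic tandem-repeat variation is largely invisible to
flanking SNPs; the methylation funnel's sole survivor is the planted CpG; the
primate rules flag the planted ≥ 3-fold changes and correctly drop an apparent
loss measured with a diverged probe.

`tandemcnv.pipeline.run_all(RunConfig(...), outdir)` runs the same chain in
one call with every threshold in one config object, a per-stage funnel log and
full determinism under a fixed seed.

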