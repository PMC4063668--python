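#!/usr/bin/env python
"""Generate the synthetic study: cohort, probes, counts and every downstream input.

Emulates a multiplexed count assay over a three-population cohort (60 CEU,
60 YRI, 45 CHB; sexes balanced) with 40 probes (60% truly copy-number
variable, 4 with planted population differentiation), 8 negative and 10
invariant controls, gender controls, a SNP panel with one planted tag SNP
(target r² = 0.5), planted cis expression (slope −0.05 log2/copy) and
methylation (normalized slope 0.3) effects, and read-depth calibration
anchors.  Writes all inputs plus the ground truth under results/study/.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tandemcnv import synthetic_data as sd
from tandemcnv.io_formats import write_count_matrix, write_probe_bed, write_sample_table

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = sd.default_truth(SEED, n_test_probes=40)
    rng = np.random.default_rng(SEED)

    planted_tag = (truth.variable_probes[0], 0.5)
    planted_expr = (truth.variable_probes[1], -0.05)
    planted_meth = (truth.variable_probes[2], 0.3)

    raw = sd.simulate_counts(truth, rng)
    panel = sd.simulate_snps(truth, planted_tags=[planted_tag], rng=rng)
    expr = sd.simulate_expression(truth, planted_effects=[planted_expr], rng=rng)
    meth, pool = sd.simulate_methylation(truth, planted_effects=[planted_meth], rng=rng)
    rd = sd.simulate_readdepth(truth, duplicate_fraction=0.1, rng=rng)

    write_count_matrix(raw, OUT / "raw_counts.tsv")
    write_probe_bed(truth.probes, OUT / "probes.bed", OUT / "probe_classes.tsv")
    write_sample_table(truth.samples, OUT / "samples.tsv")
    panel.calls.to_csv(OUT / "genotype_calls.tsv", sep="\t", na_rep="NA")
    panel.meta[["chrom", "pos"]].to_csv(OUT / "snp_meta.tsv", sep="\t")
    write_count_matrix(expr, OUT / "expression.tsv")
    expr.coords.to_csv(OUT / "expression_coords.tsv", sep="\t")
    write_count_matrix(meth, OUT / "methylation.tsv")
    meth.coords.to_csv(OUT / "methylation_coords.tsv", sep="\t")
    write_count_matrix(pool, OUT / "methylation_pool.tsv")
    rd.to_csv(OUT / "readdepth.tsv", sep="\t", index=False)

    truth_out = {
        "seed": SEED,
        "variable_probes": truth.variable_probes,
        "planted_tags": truth.planted_tags,
        "planted_expr_effects": truth.planted_expr_effects,
        "planted_meth_effects": truth.planted_meth_effects,
        "sample_scale": truth.sample_scale.round(4).to_dict(),
    }
    (OUT / "truth.json").write_text(json.dumps(truth_out, indent=2))

    print(f"wrote study to {OUT}")
    print(f"  probes: {len(truth.probes)} ({len(truth.variable_probes)} truly variable)")
    print(f"  samples: {len(truth.samples.sample_ids)}")
    print(f"  SNPs: {len(panel.snp_ids)} (planted tag on {planted_tag[0]}, "
          f"realized r2 = {truth.planted_tags[0]['realized_r2']:.3f})")
    print(f"  transcripts: {len(expr.feature_ids)}, CpGs: {len(meth.feature_ids)} "
          f"(+{len(pool.feature_ids)} pool)")


if __name__ == "__main__":
    main()
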