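#!/usr/bin/env python
"""Normalize raw counts, call variable loci, and calibrate to absolute copy number.

Reads the study written by 01_simulate_study.py, subtracts the
negative-control background, scales each sample by its invariant-probe
factor, drops low-count probes (mean < 100), classifies copy-number
variability (CV >= 0.1 or >= 30% deviation in >= 2 individuals), anchors
counts to read-depth copy number via shared-subset medians, and reports how
the calls compare with the planted truth.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tandemcnv import calibration, counts
from tandemcnv.io_formats import read_count_matrix, read_probe_bed, write_count_matrix

BASE = Path(__file__).resolve().parents[1] / "results"
STUDY = BASE / "study"


def main() -> None:
    raw = read_count_matrix(STUDY / "raw_counts.tsv")
    probes = read_probe_bed(STUDY / "probes.bed", STUDY / "probe_classes.tsv")
    truth = json.loads((STUDY / "truth.json").read_text())
    by_class = {}
    for p in probes:
        by_class.setdefault(p.probe_class, []).append(p.probe_id)

    corrected, background = counts.background_correct(raw, by_class["negative"])
    factors = counts.normalization_factors(corrected, by_class["invariant"])
    norm = counts.normalize(corrected, factors, background)
    kept, dropped = counts.exclude_low_count_probes(norm)
    test_ids = [p for p in by_class["test"] if p in kept.feature_ids]
    calls = counts.classify_variability(kept, probe_ids=test_ids)
    variable = sorted(c.probe_id for c in calls if c.is_variable)

    rd = calibration.collapse_readdepth(pd.read_csv(STUDY / "readdepth.tsv", sep="\t"))
    est = calibration.calibrate(kept.subset_features(test_ids), rd)

    write_count_matrix(norm.matrix, BASE / "normalized_counts.tsv")
    write_count_matrix(est.matrix, BASE / "copy_number.tsv")
    pd.DataFrame(
        [c.__dict__ for c in calls]
    ).to_csv(BASE / "variability_calls.tsv", sep="\t", index=False)
    (BASE / "variable_probes.json").write_text(json.dumps(variable))

    truly = set(truth["variable_probes"])
    called = set(variable)
    print(f"probes dropped for low counts: {dropped}")
    print(f"called variable: {len(called)}/{len(test_ids)} "
          f"({100 * len(called) / len(test_ids):.0f}%); "
          f"truth: {len(truly)} ({100 * len(truly) / len(test_ids):.0f}%)")
    print(f"  sensitivity {len(called & truly)}/{len(truly)}, "
          f"false calls {len(called - truly)}")
    print(f"calibrated probes: {int(est.n_calibration_samples.gt(0).sum())}; "
          f"uncalibratable: {est.uncalibratable or 'none'}")


if __name__ == "__main__":
    main()
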