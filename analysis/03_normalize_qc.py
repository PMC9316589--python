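#!/usr/bin/env python
"""Median-normalize the screen and check inter-sample uniformity.

Size factors should sit near 1 (equal simulated depths), vehicle samples
should correlate strongly on log counts, and the Gini index should reflect
the mild log-normal spread of guide representation.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from chronoscreen.normalize import (
    median_normalize,
    qc_report,
    write_normalized,
    write_size_factors,
)

from common import RESULTS, SCRATCH, study_screen

cm, _ = study_screen()
norm = median_normalize(cm, method="median_scaling")

screen_dir = SCRATCH / "screen"
screen_dir.mkdir(parents=True, exist_ok=True)
write_normalized(norm, screen_dir / "normalized.tsv")

RESULTS.mkdir(parents=True, exist_ok=True)
write_size_factors(norm, RESULTS / "03_size_factors.tsv")
report = qc_report(norm)
report.sample_stats.to_csv(RESULTS / "03_qc_samples.tsv", sep="\t",
                           index_label="sample")
report.correlations_long().to_csv(RESULTS / "03_qc_correlations.tsv", sep="\t",
                                  index=False)

print("size factors:")
print(norm.size_factors.round(4).to_string())
print("\nvehicle-vehicle Pearson r (log2):",
      round(float(report.pearson.loc["ZT16_vehicle", "ZT28_vehicle"]), 4))
print("per-sample Gini:", report.sample_stats["gini"].round(3).to_dict())
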