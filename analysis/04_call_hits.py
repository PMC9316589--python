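#!/usr/bin/env python
"""Run the A1..D4 set algebra and score recovery of the planted genes.

ZT16-specific resistance genes should surface in B4 (called at ZT16, not at
ZT28), ZT28-specific genes in D4, shared genes in the B3-and-D3
intersection, and no nontargeting label anywhere.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import json

from chronoscreen.hitcall import run_hitcall
from chronoscreen.library import NONTARGETING_LABEL
from chronoscreen.normalize import median_normalize

from common import RESULTS, SCRATCH, study_screen

cm, truth = study_screen()
ledger = run_hitcall(median_normalize(cm))

ledger.write(SCRATCH / "screen", prefix="ledger")
RESULTS.mkdir(parents=True, exist_ok=True)

sets = {name: sorted(ledger.gene_set(name))
        for name in ("A3", "B3", "C3", "D3", "A4", "B4", "C4", "D4")}
sets["B3_and_D3"] = sorted(ledger.shared_resistance)
with open(RESULTS / "04_gene_sets.json", "w") as fh:
    json.dump(sets, fh, indent=1, sort_keys=True)
    fh.write("\n")

b4, d4 = ledger.gene_set("B4"), ledger.gene_set("D4")
rec16 = len(truth.zt16_specific & b4) / len(truth.zt16_specific)
rec28 = len(truth.zt28_specific & d4) / len(truth.zt28_specific)
rec_shared = len(truth.shared & ledger.shared_resistance) / len(truth.shared)
summary = {
    "B4_size": len(b4),
    "D4_size": len(d4),
    "zt16_recovery_in_B4": rec16,
    "zt28_recovery_in_D4": rec28,
    "shared_recovery_in_B3_and_D3": rec_shared,
    "false_B4": len(b4 - truth.zt16_specific),
    "false_D4": len(d4 - truth.zt28_specific),
    "nontargeting_in_outputs": NONTARGETING_LABEL in set(ledger.gene_table.index),
}
with open(RESULTS / "04_recovery.json", "w") as fh:
    json.dump(summary, fh, indent=1, sort_keys=True)
    fh.write("\n")

for key, value in summary.items():
    print(f"{key}: {value}")
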