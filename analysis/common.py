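"""Shared study conditions for the analysis scripts.

One desk-scale screen stands in for the genome-wide experiment: a
2,000-gene, 3-guides-per-gene library with 1,000 nontargeting controls at
~300x coverage, with an 8-fold drug-fitness effect planted in 20 ZT16-only,
20 ZT28-only and 10 shared genes.  Every script regenerates what it needs
from these fixed seeds, so each can be run on its own; bulky per-guide
matrices go to scratch/, small summary tables to results/.
"""
from __future__ import annotations

from pathlib import Path

from chronoscreen.library import scaled_profile
from chronoscreen.simulate import SimulationConfig, simulate_counts

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

LIBRARY_SEED = 42
SCREEN_SEED = 42


def study_library():
    return scaled_profile(n_genes=2_000, n_nontargeting=1_000, seed=LIBRARY_SEED)


def study_config(**overrides) -> SimulationConfig:
    defaults = dict(
        library=overrides.pop("library", None) or study_library(),
        mean_coverage=300.0,
        n_zt16_specific=20,
        n_zt28_specific=20,
        n_shared=10,
        effect_multiplier=8.0,
        seed=SCREEN_SEED,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def study_screen():
    """The default simulated screen and its planted truth."""
    return simulate_counts(study_config())
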