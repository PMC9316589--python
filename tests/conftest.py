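from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from chronoscreen.counting import CountMatrix
from chronoscreen.library import NONTARGETING_LABEL
from chronoscreen.normalize import NormalizedMatrix

SCREEN_DESIGN = pd.DataFrame(
    {
        "timepoint": ["ZT16", "ZT16", "ZT28", "ZT28"],
        "treatment": ["vehicle", "drug", "vehicle", "drug"],
        "role": ["screen"] * 4,
    },
    index=pd.Index(["ZT16_vehicle", "ZT16_drug", "ZT28_vehicle", "ZT28_drug"],
                   name="sample"),
)


def make_normalized(values: pd.DataFrame, genes: pd.Series) -> NormalizedMatrix:
    """Wrap a guide x 4-sample value table as an already-normalized matrix."""
    design = SCREEN_DESIGN.loc[list(values.columns)]
    return NormalizedMatrix(
        values=values.astype(float),
        genes=genes,
        design=design,
        size_factors=pd.Series(1.0, index=values.columns, name="size_factor"),
        method="median_scaling",
    )


@pytest.fixture
def toy_screen() -> CountMatrix:
    """Three genes x three guides; the worked example traced by hand.

    All vehicle counts are 10 at both timepoints.  At ZT16 the drug counts
    are g1 = (40, 25, 10), g2 = (60, 10, 10), g3 = (4, 3, 10); at ZT28 they
    are g1 = (40, 25, 10), g2 = (10, 10, 10), g3 = (1, 10, 10).
    """
    guides = [f"g{i}_{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
    genes = pd.Series([g.split("_")[0] for g in guides],
                      index=pd.Index(guides, name="guide_id"), name="gene")
    counts = pd.DataFrame(
        {
            "ZT16_vehicle": [10] * 9,
            "ZT16_drug": [40, 25, 10, 60, 10, 10, 4, 3, 10],
            "ZT28_vehicle": [10] * 9,
            "ZT28_drug": [40, 25, 10, 10, 10, 10, 1, 10, 10],
        },
        index=genes.index,
    )
    return CountMatrix(counts, genes, SCREEN_DESIGN)


def random_screen_values(rng: np.random.Generator, max_guides: int = 60):
    """Random small normalized matrix (with zeros and NTC guides) for
    oracle-equivalence checks.  Returns (values, genes)."""
    n_genes = rng.integers(2, max(3, max_guides // 3))
    guides, genes = [], []
    for gi in range(n_genes):
        gene = f"G{gi}"
        for j in range(rng.integers(1, 5)):
            guides.append(f"{gene}_{j}")
            genes.append(gene)
    for j in range(rng.integers(0, 4)):
        guides.append(f"ntc_{j}")
        genes.append(NONTARGETING_LABEL)
    guides = guides[:max_guides]
    genes = genes[:max_guides]
    n = len(guides)
    values = rng.integers(0, 60, size=(n, 4)).astype(float)
    # sprinkle non-integer normalized values and extra zeros
    values[rng.random(size=values.shape) < 0.15] = 0.0
    values += rng.random(size=values.shape) * (rng.random(size=(n, 1)) < 0.5)
    frame = pd.DataFrame(
        values,
        index=pd.Index(guides, name="guide_id"),
        columns=["ZT16_vehicle", "ZT16_drug", "ZT28_vehicle", "ZT28_drug"],
    )
    return frame, pd.Series(genes, index=frame.index, name="gene")
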