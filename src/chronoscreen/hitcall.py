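"""Time-specific drug sensitivity/resistance calling by fold-change set algebra.

The screen has four analysed samples, one per cell of the (administration
time x treatment) factorial, labelled:

    A = ZT16 vehicle    B = ZT16 drug    C = ZT28 vehicle    D = ZT28 drug

Hit calling is deliberately rule-based at the guide level (guide-to-guide
variability in knockout efficacy makes gene-level averaging unreliable):

1.  A1..D1 — from the normalized matrix, drop nontargeting guides and guides
    failing the zero filter, then add a pseudocount (default 1) to every
    remaining value; all four datasets share one guide index.
2.  A2/B2 (and C2/D2) — per-guide drug/vehicle ratios r16 = B1/A1 and
    r28 = D1/C1 are gated: depleted if ratio < 0.5 (strict), enriched if
    ratio >= 2 (inclusive).
3.  Gene level: a primed set (e.g. B2') collects genes with at least
    ``min_concordant_guides`` distinct guides in the gated set; a
    double-primed set (e.g. B2'') rescues genes with a single strong guide
    (ratio >= 5, or < 0.2 on the depletion side).  Their union is the
    per-timepoint call (B3 = B2' | B2'', etc.).
4.  Time-specific sets are set differences: B4 = B3 \\ D3 (ZT16-specific
    resistance), D4 = D3 \\ B3, and A4/C4 likewise on the depletion side;
    the intersections B3 & D3 and A3 & C3 are reported separately.

Every intermediate is retained in a :class:`DatasetLedger` so each gene call
is traceable to the rule that admitted it.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .library import NONTARGETING_LABEL
from .normalize import NormalizedMatrix

#: Dataset letter -> (timepoint, treatment) of the sample it denotes.
DATASET_CELLS = {
    "A": ("ZT16", "vehicle"),
    "B": ("ZT16", "drug"),
    "C": ("ZT28", "vehicle"),
    "D": ("ZT28", "drug"),
}

GENE_SET_NAMES = (
    "A2_primed", "B2_primed", "C2_primed", "D2_primed",
    "A2_strong", "B2_strong", "C2_strong", "D2_strong",
    "A3", "B3", "C3", "D3", "A4", "B4", "C4", "D4",
)

# Normalized values are rounded to this many decimal places before ratios
# are formed, so gate membership is stable across platforms.
RATIO_DECIMALS = 12


class HitcallError(ValueError):
    pass


@dataclasses.dataclass
class HitcallParams:
    """Gate thresholds and filtering rules for the set-algebra hit caller.

    Threshold inclusivity follows the procedure exactly: the enrichment
    gates (>= 2, >= 5) are inclusive, the depletion gates (< 0.5, < 0.2)
    strict.
    """

    up_threshold: float = 2.0
    down_threshold: float = 0.5
    strong_up: float = 5.0
    strong_down: float = 0.2
    min_concordant_guides: int = 2
    pseudocount: float = 1.0
    zero_filter_scope: str = "any_sample"

    def __post_init__(self) -> None:
        if not (0 < self.strong_down < self.down_threshold < 1 < self.up_threshold <= self.strong_up):
            raise HitcallError(
                "thresholds must satisfy 0 < strong_down < down_threshold < 1 "
                "< up_threshold <= strong_up"
            )
        if self.min_concordant_guides < 2:
            raise HitcallError("min_concordant_guides must be >= 2")
        if self.pseudocount <= 0:
            raise HitcallError("pseudocount must be > 0")
        if self.zero_filter_scope not in ("any_sample", "all_samples"):
            raise HitcallError(f"unknown zero_filter_scope {self.zero_filter_scope!r}")


@dataclasses.dataclass
class DatasetLedger:
    """Full provenance of one hit-calling run.

    ``guide_table`` (index guide_id): gene, a1..d1, r16, r28 and gate flags
    in_a2..in_d2.  ``gene_table`` (index gene): membership flags for every
    primed/strong/per-timepoint/time-specific set plus the rule that
    admitted each gene into its A3..D3 call.
    """

    guide_table: pd.DataFrame
    gene_table: pd.DataFrame
    params: HitcallParams

    def guide_set(self, name: str) -> frozenset[str]:
        """Guide ids in A2/B2/C2/D2."""
        col = f"in_{name.lower()}"
        if col not in self.guide_table.columns:
            raise KeyError(f"unknown guide set {name!r}")
        return frozenset(self.guide_table.index[self.guide_table[col]])

    def gene_set(self, name: str) -> frozenset[str]:
        """Genes in any of A2_primed..D2_strong, A3..D4."""
        col = name.lower()
        if col not in self.gene_table.columns:
            raise KeyError(f"unknown gene set {name!r}")
        return frozenset(self.gene_table.index[self.gene_table[col]])

    @property
    def shared_resistance(self) -> frozenset[str]:
        """B3 & D3: resistance called at both timepoints."""
        return self.gene_set("B3") & self.gene_set("D3")

    @property
    def shared_sensitivity(self) -> frozenset[str]:
        """A3 & C3: depletion called at both timepoints."""
        return self.gene_set("A3") & self.gene_set("C3")

    def write(self, out_dir: str | Path, prefix: str = "ledger") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "guides": out_dir / f"{prefix}_guides.tsv",
            "genes": out_dir / f"{prefix}_genes.tsv",
            "params": out_dir / f"{prefix}_params.yaml",
        }
        self.guide_table.to_csv(paths["guides"], sep="\t", index_label="guide_id")
        self.gene_table.to_csv(paths["genes"], sep="\t", index_label="gene")
        with open(paths["params"], "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self.params), fh, sort_keys=True)
        return paths


def _cell_samples(design: pd.DataFrame) -> dict[str, str]:
    """Map each dataset letter to the unique screen sample for its cell."""
    out = {}
    screen = design.loc[design["role"] == "screen"]
    for letter, (tp, tx) in DATASET_CELLS.items():
        match = screen.index[(screen["timepoint"] == tp) & (screen["treatment"] == tx)]
        if len(match) != 1:
            raise HitcallError(
                f"design must contain exactly one screen sample for "
                f"{tp} x {tx} (dataset {letter}); found {list(match)}"
            )
        out[letter] = match[0]
    return out


def prepare_datasets(norm: NormalizedMatrix, params: HitcallParams) -> pd.DataFrame:
    """Build the shared-index A1..D1 guide table.

    Nontargeting guides are removed; guides with a zero normalized value in
    any (or, under ``all_samples`` scope, every) screen sample are removed;
    the pseudocount is then added to every remaining value.
    """
    cells = _cell_samples(norm.design)
    values = norm.values[[cells[c] for c in "ABCD"]].copy()
    values.columns = ["a1", "b1", "c1", "d1"]
    targeting = norm.genes != NONTARGETING_LABEL
    values = values.loc[targeting]
    arr = values.to_numpy()
    if params.zero_filter_scope == "any_sample":
        keep = (arr > 0).all(axis=1)
    else:
        keep = (arr > 0).any(axis=1)
    values = values.loc[keep]
    if values.empty:
        raise HitcallError("no guides remain after nontargeting/zero filtering")
    # Python round() (exact decimal, half-even) rather than np.round's
    # scale-multiply approximation, so gate membership is platform-stable.
    prepared = (values + params.pseudocount).map(lambda v: round(v, RATIO_DECIMALS))
    prepared.insert(0, "gene", norm.genes.loc[prepared.index])
    return prepared


def guide_gates(prepared: pd.DataFrame, params: HitcallParams) -> pd.DataFrame:
    """Attach per-guide ratios and gate memberships A2/B2/C2/D2."""
    gated = prepared.copy()
    gated["r16"] = gated["b1"] / gated["a1"]
    gated["r28"] = gated["d1"] / gated["c1"]
    gated["in_b2"] = gated["r16"] >= params.up_threshold
    gated["in_a2"] = gated["r16"] < params.down_threshold
    gated["in_d2"] = gated["r28"] >= params.up_threshold
    gated["in_c2"] = gated["r28"] < params.down_threshold
    return gated


_SIDES = {
    # gene set letter -> (gate flag column, ratio column, strong comparator)
    "a": ("in_a2", "r16", "down"),
    "b": ("in_b2", "r16", "up"),
    "c": ("in_c2", "r28", "down"),
    "d": ("in_d2", "r28", "up"),
}


def gene_calls(gated: pd.DataFrame, params: HitcallParams) -> pd.DataFrame:
    """Collapse guide gates to per-timepoint gene calls A3..D3.

    For each side X: X2' (primed) = genes with >= min_concordant_guides
    guides in X2; X2'' (strong) = genes with >= 1 guide past the strong
    threshold; X3 = X2' | X2''.  The admitting rule per gene is recorded.
    """
    by_gene = gated.groupby("gene", sort=True)
    table = pd.DataFrame(index=by_gene.size().index.rename("gene"))
    for letter, (flag_col, ratio_col, side) in _SIDES.items():
        if side == "up":
            strong = gated[ratio_col] >= params.strong_up
        else:
            strong = gated[ratio_col] < params.strong_down
        n_gated = gated[flag_col].groupby(gated["gene"]).sum()
        n_strong = strong.groupby(gated["gene"]).sum()
        primed = n_gated >= params.min_concordant_guides
        has_strong = n_strong >= 1
        table[f"{letter}2_primed"] = primed
        table[f"{letter}2_strong"] = has_strong
        table[f"{letter}3"] = primed | has_strong
        table[f"{letter}3_rule"] = np.select(
            [primed & has_strong, primed, has_strong],
            ["concordant+strong", "concordant", "strong"],
            default="",
        )
    return table


def time_specific_sets(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Add the set differences A4..D4 and the shared intersections."""
    table = gene_table.copy()
    table["b4"] = table["b3"] & ~table["d3"]
    table["d4"] = table["d3"] & ~table["b3"]
    table["a4"] = table["a3"] & ~table["c3"]
    table["c4"] = table["c3"] & ~table["a3"]
    table["shared_bd"] = table["b3"] & table["d3"]
    table["shared_ac"] = table["a3"] & table["c3"]
    return table


def run_hitcall(norm: NormalizedMatrix, params: HitcallParams | None = None) -> DatasetLedger:
    """Full algebra: prepare -> gate -> gene calls -> time-specific sets."""
    params = params or HitcallParams()
    prepared = prepare_datasets(norm, params)
    gated = guide_gates(prepared, params)
    gene_table = time_specific_sets(gene_calls(gated, params))
    return DatasetLedger(guide_table=gated, gene_table=gene_table, params=params)
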