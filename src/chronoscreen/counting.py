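"""Guide quantification from FASTQ by exact spacer matching, plus mapping QC.

Reads are assigned to guides by exact (zero-mismatch) dictionary lookup of
the spacer, either by sliding a spacer-length window over each read (``scan``
mode, robust to unknown read layout) or by extracting a fixed offset
(``fixed_offset`` mode, faster when the amplicon structure is known).  Reads
matching spacers of two or more distinct guides are counted as ambiguous and
assigned to neither; integer counts are required downstream, so ambiguous
reads are never split fractionally.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .library import NONTARGETING_LABEL, GuideLibrary

logger = logging.getLogger(__name__)

TIMEPOINTS = ("ZT16", "ZT28", "none")
TREATMENTS = ("drug", "vehicle", "none")
ROLES = ("screen", "baseline")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class DesignError(ValueError):
    """Raised when a sample design table violates its invariants."""


class FastqParseError(ValueError):
    """Raised when a FASTQ record cannot be parsed."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a design table (index sample; timepoint, treatment, role)."""
    for col in ("timepoint", "treatment", "role"):
        if col not in design.columns:
            raise DesignError(f"design missing column {col!r}")
    bad_tp = set(design["timepoint"]) - set(TIMEPOINTS)
    bad_tx = set(design["treatment"]) - set(TREATMENTS)
    bad_role = set(design["role"]) - set(ROLES)
    if bad_tp or bad_tx or bad_role:
        raise DesignError(
            f"unknown design values: timepoint={bad_tp or '{}'} "
            f"treatment={bad_tx or '{}'} role={bad_role or '{}'}"
        )
    screen = design.loc[design["role"] == "screen"]
    unset = screen.loc[(screen["timepoint"] == "none") | (screen["treatment"] == "none")]
    if len(unset):
        raise DesignError(
            f"screen samples must set timepoint and treatment: {list(unset.index)}"
        )
    if design.index.duplicated().any():
        raise DesignError("duplicate sample names in design")
    return design


def infer_design(samples: list[str]) -> pd.DataFrame:
    """Guess a design from sample names like ``ZT16_drug`` or ``baseline``."""
    rows = []
    for name in samples:
        parts = name.split("_")
        if name.lower() == "baseline":
            rows.append(("none", "none", "baseline"))
        elif len(parts) == 2 and parts[0] in TIMEPOINTS and parts[1] in TREATMENTS:
            rows.append((parts[0], parts[1], "screen"))
        else:
            raise DesignError(
                f"cannot infer design for sample {name!r}; supply a design table"
            )
    return pd.DataFrame(
        rows, index=pd.Index(samples, name="sample"),
        columns=["timepoint", "treatment", "role"],
    )


@dataclasses.dataclass
class CountMatrix:
    """Nonnegative integer guide x sample counts with a sample design.

    ``counts`` is indexed by guide_id with one column per sample; ``genes``
    maps guide_id to gene symbol (:data:`NONTARGETING_LABEL` for controls);
    ``design`` is indexed by sample with columns timepoint / treatment / role.
    """

    counts: pd.DataFrame
    genes: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.counts.index.equals(self.genes.index):
            self.genes = self.genes.reindex(self.counts.index)
            if self.genes.isna().any():
                raise ValueError("genes missing for some guides")
        validate_design(self.design)
        if list(self.design.index) != list(self.counts.columns):
            raise DesignError("design samples do not match count columns")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclasses.dataclass
class MappingStats:
    """Per-sample read-assignment and representation statistics."""

    per_sample: pd.DataFrame  # indexed by sample

    def mapping_rate(self, sample: str) -> float:
        return float(self.per_sample.loc[sample, "mapping_rate"])


def gini_index(values: np.ndarray) -> float:
    """Gini inequality index of a nonnegative vector (0 = uniform)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    total = x.sum()
    if n == 0 or total == 0:
        return 0.0
    ranks = np.arange(1, n + 1)
    return float(2.0 * (ranks @ x) / (n * total) - (n + 1) / n)


def _sample_stats(counts: np.ndarray, total: int, mapped: int, ambiguous: int) -> dict:
    return {
        "total_reads": total,
        "mapped_reads": mapped,
        "ambiguous_reads": ambiguous,
        "unmapped_reads": total - mapped - ambiguous,
        "mapping_rate": 100.0 * mapped / total if total else 0.0,
        "coverage_mean": float(counts.mean()),
        "coverage_median": float(np.median(counts)),
        "zero_fraction": float((counts == 0).mean()),
        "gini": gini_index(counts),
    }


def _count_one_fastq(
    path: Path,
    spacer_to_row: dict[str, int],
    n_guides: int,
    spacer_length: int,
    mode: str,
    offset: int | None,
    revcomp: bool,
) -> tuple[np.ndarray, int, int, int]:
    counts = np.zeros(n_guides, dtype=np.int64)
    total = mapped = ambiguous = 0
    L = spacer_length
    get = spacer_to_row.get
    if path.stat().st_size == 0:
        logger.warning("empty FASTQ %s: sample will have all-zero counts", path)
        return counts, 0, 0, 0
    record_index = -1
    try:
        with pysam.FastxFile(str(path)) as fh:
            for record_index, read in enumerate(fh):
                total += 1
                seq = read.sequence.upper()
                queries = (seq, reverse_complement(seq)) if revcomp else (seq,)
                hit: int | None = None
                multi = False
                for q in queries:
                    if mode == "fixed_offset":
                        windows = (q[offset : offset + L],) if offset + L <= len(q) else ()
                    else:
                        windows = (q[i : i + L] for i in range(len(q) - L + 1))
                    for w in windows:
                        row = get(w)
                        if row is None:
                            continue
                        if hit is None:
                            hit = row
                        elif row != hit:
                            multi = True
                            break
                    if multi:
                        break
                if multi:
                    ambiguous += 1
                elif hit is not None:
                    counts[hit] += 1
                    mapped += 1
    except OSError as exc:
        raise FastqParseError(
            f"{path}: malformed FASTQ near record {record_index + 1}: {exc}"
        ) from exc
    return counts, total, mapped, ambiguous


def count_reads(
    lib: GuideLibrary,
    fastq_paths: Mapping[str, str | Path],
    design: pd.DataFrame | None = None,
    mode: str = "scan",
    offset: int | None = None,
    revcomp: bool = False,
) -> tuple[CountMatrix, MappingStats]:
    """Quantify guides per sample by exact spacer matching.

    Each read contributes to at most one guide.  A read whose windows hit
    spacers of two distinct guides is counted ambiguous and assigned to
    neither; mapped + ambiguous + unmapped = total per sample.
    """
    if mode not in ("scan", "fixed_offset"):
        raise ValueError(f"unknown counting mode {mode!r}")
    if mode == "fixed_offset" and offset is None:
        raise ValueError("fixed_offset mode requires an offset")
    samples = list(fastq_paths)
    if design is None:
        design = infer_design(samples)
    spacer_to_row = lib.spacer_index()
    per_guide = {}
    stat_rows = {}
    for sample in samples:
        counts, total, mapped, ambiguous = _count_one_fastq(
            Path(fastq_paths[sample]),
            spacer_to_row,
            len(lib),
            lib.spacer_length,
            mode,
            offset,
            revcomp,
        )
        per_guide[sample] = counts
        stat_rows[sample] = _sample_stats(counts, total, mapped, ambiguous)
    counts_df = pd.DataFrame(per_guide, index=pd.Index(lib.guide_ids, name="guide_id"))
    stats = MappingStats(pd.DataFrame(stat_rows).T.rename_axis("sample"))
    return CountMatrix(counts_df, lib.genes, design.loc[samples]), stats


def mapping_report(
    stats: MappingStats,
    threshold_pct: float = 75.0,
    coverage_band: tuple[float, float] = (100.0, 300.0),
) -> pd.DataFrame:
    """Per-sample QC verdict: mapping-rate pass/fail and coverage-band check."""
    lo, hi = coverage_band
    report = stats.per_sample.copy()
    report["mapping_pass"] = report["mapping_rate"] >= threshold_pct
    report["coverage_in_band"] = (report["coverage_median"] >= lo) & (
        report["coverage_median"] <= hi
    )
    return report


# ---------------------------------------------------------------------------
# Tab-separated interchange formats


def write_counts(cm: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = cm.counts.copy()
    out.insert(0, "gene", cm.genes)
    out.to_csv(path, sep="\t", index=True, index_label="guide_id")
    return path


def read_counts(path: str | Path, design: pd.DataFrame) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="guide_id", keep_default_na=False)
    genes = frame.pop("gene")
    return CountMatrix(frame, genes, design.loc[list(frame.columns)])


def write_design(design: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    design.to_csv(path, sep="\t", index=True, index_label="sample")
    return path


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col="sample", keep_default_na=False)
    return validate_design(design)


def write_mapping_stats(stats: MappingStats, path: str | Path) -> Path:
    path = Path(path)
    stats.per_sample.to_csv(path, sep="\t", index=True, index_label="sample")
    return path
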