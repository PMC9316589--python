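"""Median normalization of screen counts and inter-sample QC.

Sequencing depth differs between samples, so raw guide counts are rescaled
before fold changes are formed.  The default ``median_scaling`` method is the
literal reading of median normalization: each sample is divided by a size
factor equal to its median guide count over the global reference median (the
median of per-sample medians), so every sample's median guide value ends up
equal to that reference.  ``median_ratio`` is the robust alternative
(DESeq-style median-of-ratios against a geometric-mean pseudo-reference).
Nontargeting guides take part in size-factor computation — they are part of
the sequenced library and are only removed later, at hit calling.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import CountMatrix, gini_index

logger = logging.getLogger(__name__)

METHODS = ("median_scaling", "median_ratio")


class NormalizationError(ValueError):
    pass


@dataclasses.dataclass
class NormalizedMatrix:
    """Counts divided by per-sample size factors, with provenance."""

    values: pd.DataFrame  # float, index guide_id, columns samples
    genes: pd.Series
    design: pd.DataFrame
    size_factors: pd.Series
    method: str

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def median_normalize(counts: CountMatrix, method: str = "median_scaling") -> NormalizedMatrix:
    """Rescale each sample by a median-based size factor.

    median_scaling: size factor = sample median / median of per-sample
    medians, so post-normalization medians agree across samples.
    median_ratio: size factor = median over all-sample-positive guides of
    the guide's count over its geometric mean across samples.
    """
    if method not in METHODS:
        raise NormalizationError(f"unknown method {method!r}")
    raw = counts.counts.astype(float)
    if method == "median_scaling":
        medians = raw.median(axis=0)
        if (medians <= 0).any():
            zeroed = list(medians.index[medians <= 0])
            raise NormalizationError(
                f"zero median count in samples {zeroed}; consider method="
                "'median_ratio' or prefiltering low-count guides"
            )
        reference = float(medians.median())
        size_factors = medians / reference
    else:
        positive = (raw > 0).all(axis=1)
        if not positive.any():
            raise NormalizationError(
                "no guide is positive in every sample; median_ratio undefined"
            )
        log_ref = np.log(raw.loc[positive]).mean(axis=1)
        ratios = np.log(raw.loc[positive]).sub(log_ref, axis=0)
        size_factors = np.exp(ratios.median(axis=0))
    size_factors.name = "size_factor"
    return NormalizedMatrix(
        values=raw.div(size_factors, axis=1),
        genes=counts.genes,
        design=counts.design,
        size_factors=size_factors,
        method=method,
    )


@dataclasses.dataclass
class QCReport:
    """Inter-sample uniformity and correlation summary."""

    sample_stats: pd.DataFrame        # gini, zero_fraction, mean, median, total
    pearson: pd.DataFrame | None      # sample x sample, on log2(value + 1)
    spearman: pd.DataFrame | None

    def correlations_long(self) -> pd.DataFrame | None:
        if self.pearson is None:
            return None
        rows = []
        samples = list(self.pearson.index)
        for i, a in enumerate(samples):
            for b in samples[i + 1 :]:
                rows.append(
                    (a, b, self.pearson.loc[a, b], self.spearman.loc[a, b])
                )
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "pearson", "spearman"])


def qc_report(norm: NormalizedMatrix) -> QCReport:
    """Pairwise correlations on log2(value+1) plus per-sample summaries."""
    values = norm.values
    stats_rows = {
        s: {
            "gini": gini_index(values[s].to_numpy()),
            "zero_fraction": float((values[s] == 0).mean()),
            "mean": float(values[s].mean()),
            "median": float(values[s].median()),
            "total": float(values[s].sum()),
        }
        for s in norm.samples
    }
    sample_stats = pd.DataFrame(stats_rows).T.rename_axis("sample")
    if len(norm.samples) < 2:
        logger.warning("QC correlations need >= 2 samples; reporting stats only")
        return QCReport(sample_stats, None, None)
    logged = np.log2(values + 1.0)
    pearson = logged.corr(method="pearson")
    spearman = logged.corr(method="spearman")
    return QCReport(sample_stats, pearson, spearman)


def correlation_heatmap(report: QCReport, path: str | Path) -> Path | None:
    """Optional pairwise-Pearson heatmap (PNG); returns None if <2 samples."""
    if report.pearson is None:
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(report.pearson.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ticks = range(len(report.pearson))
    ax.set_xticks(ticks, report.pearson.columns, rotation=45, ha="right")
    ax.set_yticks(ticks, report.pearson.index)
    fig.colorbar(im, ax=ax, label="Pearson r (log2 counts)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def write_normalized(norm: NormalizedMatrix, path: str | Path) -> Path:
    """Normalized TSV: guide_id, gene, one 6-decimal column per sample."""
    path = Path(path)
    out = norm.values.round(6)
    out.insert(0, "gene", norm.genes)
    out.to_csv(path, sep="\t", index=True, index_label="guide_id", float_format="%.6f")
    return path


def read_normalized(
    path: str | Path, design: pd.DataFrame, size_factors: pd.Series | None = None,
    method: str = "median_scaling",
) -> NormalizedMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="guide_id", keep_default_na=False)
    genes = frame.pop("gene")
    values = frame.astype(float)
    if size_factors is None:
        size_factors = pd.Series(1.0, index=values.columns, name="size_factor")
    return NormalizedMatrix(values, genes, design.loc[list(values.columns)],
                            size_factors, method)


def write_size_factors(norm: NormalizedMatrix, path: str | Path) -> Path:
    path = Path(path)
    frame = norm.size_factors.to_frame()
    frame["method"] = norm.method
    frame.to_csv(path, sep="\t", index=True, index_label="sample")
    return path
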