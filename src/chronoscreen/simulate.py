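"""Synthetic pooled-screen generator with planted chrono-specific drug effects.

The generator emulates a five-sample screen — baseline, then a 2x2 factorial
of administration time (ZT16 / ZT28, hours after serum-shock synchronisation)
by treatment (drug / vehicle) — over a guide library.  Guide abundances are
log-normal (uneven plasmid representation); counts are negative binomial
around abundance x coverage; a chosen set of genes carries a multiplicative
drug-fitness effect in the drugged sample of one or both timepoints.  The
planted per-gene multipliers are returned as ground truth for recovery
scoring.  A FASTQ writer embeds each counted spacer in fixed vector flanks so
the exact-match counter can be exercised end to end, with an optional
off-library contaminant read fraction.
"""
from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import CountMatrix
from .library import GuideLibrary, _BASES

#: Fixed sample order produced by :func:`simulate_counts`.
SAMPLES = ("baseline", "ZT16_vehicle", "ZT16_drug", "ZT28_vehicle", "ZT28_drug")

# Fixed amplicon context around the spacer in simulated reads (lentiviral
# vector sequence immediately up/downstream of the cloning site).
UPSTREAM_FLANK = "TATCTTGTGGAAAGGACGAAACACCG"
DOWNSTREAM_FLANK = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTG"


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Defaults reproduce a high-quality screen: ~300x coverage, mild negative
    binomial overdispersion, and a strong (8-fold) drug-fitness effect on
    20 + 20 + 10 planted genes (ZT16-only, ZT28-only, both timepoints).
    """

    library: GuideLibrary
    mean_coverage: float = 300.0
    dispersion: float = 0.005
    baseline_abundance_sdlog: float = 0.4
    n_zt16_specific: int = 20
    n_zt28_specific: int = 20
    n_shared: int = 10
    effect_multiplier: float = 8.0
    effective_guide_fraction: float = 1.0
    contaminant_fraction: float = 0.0
    seed: int = 0
    read_length: int = 50
    spacer_offset: int = 10

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise SimulationError("mean_coverage must be > 0")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be > 0")
        if self.baseline_abundance_sdlog < 0:
            raise SimulationError("baseline_abundance_sdlog must be >= 0")
        if self.effect_multiplier <= 0:
            raise SimulationError("effect_multiplier must be > 0")
        if not 0 < self.effective_guide_fraction <= 1:
            raise SimulationError("effective_guide_fraction must be in (0, 1]")
        if not 0 <= self.contaminant_fraction < 1:
            raise SimulationError("contaminant_fraction must be in [0, 1)")
        for field in ("n_zt16_specific", "n_zt28_specific", "n_shared"):
            if getattr(self, field) < 0:
                raise SimulationError(f"{field} must be >= 0")
        L = self.library.spacer_length
        if self.spacer_offset < 0 or self.spacer_offset + L > self.read_length:
            raise SimulationError("spacer must fit in the read at spacer_offset")


@dataclasses.dataclass
class SimulationTruth:
    """Planted per-gene drug-fitness multipliers per timepoint.

    Genes absent from ``table`` implicitly have multiplier 1 in both cells.
    """

    table: pd.DataFrame  # index gene; columns zt16_multiplier, zt28_multiplier

    def multiplier(self, gene: str, timepoint: str) -> float:
        col = {"ZT16": "zt16_multiplier", "ZT28": "zt28_multiplier"}[timepoint]
        if gene in self.table.index:
            return float(self.table.loc[gene, col])
        return 1.0

    def _where(self, zt16: bool, zt28: bool) -> frozenset[str]:
        m16 = self.table["zt16_multiplier"] != 1.0
        m28 = self.table["zt28_multiplier"] != 1.0
        return frozenset(self.table.index[(m16 == zt16) & (m28 == zt28)])

    @property
    def zt16_specific(self) -> frozenset[str]:
        return self._where(True, False)

    @property
    def zt28_specific(self) -> frozenset[str]:
        return self._where(False, True)

    @property
    def shared(self) -> frozenset[str]:
        return self._where(True, True)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, SimulationTruth]:
    """Draw the five-sample count matrix and its planted ground truth.

    Each guide's count is negative binomial with mean
    abundance x coverage x multiplier, where the multiplier differs from 1
    only in the drugged sample of a timepoint at which the guide's gene
    carries a planted effect (and only for the gene's effective guides).
    Runs are reproducible given the config seed.
    """
    lib = config.library
    rng = np.random.default_rng(config.seed)
    frame = lib.to_frame()
    n_guides = len(lib)

    genes = lib.targeting_genes
    n_planted = config.n_zt16_specific + config.n_zt28_specific + config.n_shared
    if n_planted > len(genes):
        raise SimulationError("more planted genes requested than targeting genes")
    chosen = rng.choice(np.array(genes, dtype=object), size=n_planted, replace=False)
    zt16_genes = list(chosen[: config.n_zt16_specific])
    zt28_genes = list(
        chosen[config.n_zt16_specific : config.n_zt16_specific + config.n_zt28_specific]
    )
    shared_genes = list(chosen[config.n_zt16_specific + config.n_zt28_specific :])

    m = config.effect_multiplier
    mult16 = np.ones(n_guides)
    mult28 = np.ones(n_guides)
    gene_rows = frame.groupby("gene", sort=False).indices
    for gene_list, targets in (
        (zt16_genes + shared_genes, mult16),
        (zt28_genes + shared_genes, mult28),
    ):
        for gene in gene_list:
            rows = np.asarray(gene_rows[gene])
            k = max(1, int(round(config.effective_guide_fraction * len(rows))))
            eff = rng.choice(rows, size=k, replace=False)
            targets[eff] = m

    sdlog = config.baseline_abundance_sdlog
    # mean-1 log-normal so mean_coverage is the expected per-guide count
    abundance = rng.lognormal(-0.5 * sdlog**2, sdlog, size=n_guides)
    base_mu = abundance * config.mean_coverage

    shape = 1.0 / config.dispersion  # var = mu + dispersion * mu^2
    per_sample = {}
    for sample in SAMPLES:
        mu = base_mu.copy()
        if sample == "ZT16_drug":
            mu *= mult16
        elif sample == "ZT28_drug":
            mu *= mult28
        p = shape / (shape + mu)
        per_sample[sample] = rng.negative_binomial(shape, p)

    counts = pd.DataFrame(
        per_sample, index=pd.Index(lib.guide_ids, name="guide_id")
    )
    design = pd.DataFrame(
        {
            "timepoint": ["none", "ZT16", "ZT16", "ZT28", "ZT28"],
            "treatment": ["none", "vehicle", "drug", "vehicle", "drug"],
            "role": ["baseline", "screen", "screen", "screen", "screen"],
        },
        index=pd.Index(SAMPLES, name="sample"),
    )
    truth = SimulationTruth(
        pd.DataFrame(
            {
                "zt16_multiplier": [m] * len(zt16_genes)
                + [1.0] * len(zt28_genes)
                + [m] * len(shared_genes),
                "zt28_multiplier": [1.0] * len(zt16_genes)
                + [m] * len(zt28_genes)
                + [m] * len(shared_genes),
            },
            index=pd.Index(zt16_genes + zt28_genes + shared_genes, name="gene"),
        )
    )
    return CountMatrix(counts, lib.genes, design), truth


def contaminant_read_count(n_on_library: int, contaminant_fraction: float) -> int:
    """Contaminant reads to add so contaminants make up the requested fraction.

    ``round(n_on_library * f / (1 - f))`` with banker-free half-up rounding.
    """
    f = contaminant_fraction
    return int(np.floor(n_on_library * f / (1.0 - f) + 0.5))


def _random_reads(n: int, length: int, rng: np.random.Generator) -> list[str]:
    if n == 0:
        return []
    arr = rng.integers(0, 4, size=(n, length), dtype=np.int8)
    return [w.decode() for w in _BASES[arr].view(f"S{length}").ravel()]


def simulate_fastq(
    config: SimulationConfig,
    counts: CountMatrix,
    out_dir: str | Path,
    compress: bool = True,
) -> dict[str, Path]:
    """Write per-sample FASTQ files whose on-library reads realise ``counts``.

    Read layout: ``read_length`` nt, spacer at ``spacer_offset`` inside fixed
    vector flanks, constant quality 'I'.  Contaminant reads (uniform random
    sequence) are added so they form ``contaminant_fraction`` of each file.
    The on-library read multiset per sample equals the count matrix exactly.
    """
    lib = config.library
    if list(counts.counts.index) != lib.guide_ids:
        raise SimulationError("count matrix guides do not match the library")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))

    L = lib.spacer_length
    left = UPSTREAM_FLANK[-config.spacer_offset :] if config.spacer_offset else ""
    right_len = config.read_length - config.spacer_offset - L
    right = (DOWNSTREAM_FLANK * (right_len // len(DOWNSTREAM_FLANK) + 1))[:right_len]
    spacers = np.array([r.spacer for r in lib.records], dtype=object)
    quality = "I" * config.read_length

    paths: dict[str, Path] = {}
    for sample in counts.samples:
        col = counts.counts[sample].to_numpy()
        guide_idx = np.repeat(np.arange(len(lib)), col)
        on_reads = [left + s + right for s in spacers[guide_idx]]
        n_contam = contaminant_read_count(len(on_reads), config.contaminant_fraction)
        reads = on_reads + _random_reads(n_contam, config.read_length, rng)
        order = rng.permutation(len(reads))
        name = f"{sample}.fastq.gz" if compress else f"{sample}.fastq"
        path = out_dir / name
        opener = gzip.open if compress else open
        with opener(path, "wt") as fh:
            for i, j in enumerate(order):
                fh.write(f"@{sample}:{i}\n{reads[j]}\n+\n{quality}\n")
        paths[sample] = path
    return paths


def write_truth(truth: SimulationTruth, path: str | Path) -> Path:
    path = Path(path)
    truth.table.to_csv(path, sep="\t", index=True, index_label="gene")
    return path


def read_truth(path: str | Path) -> SimulationTruth:
    return SimulationTruth(pd.read_csv(path, sep="\t", index_col="gene"))
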