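"""Pipeline configuration and the end-to-end run_all orchestration.

A run is described by one YAML config (paths + stage parameters + seed).
``run_all`` executes count -> normalize -> QC -> hitcall -> enrich, writing
every stage's output to the output directory and reading it back before the
next stage, so a run is exactly equivalent to invoking the stages one at a
time on each other's files.  A manifest with input/output checksums and the
full parameter echo is written last; reruns with identical config and inputs
are bit-identical (no timestamps enter any output).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import counting, enrichment, hitcall, normalize
from .library import read_library

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    library: Path
    out_dir: Path
    design: Path
    counts: Path | None = None
    fastq: dict[str, Path] | None = None
    gmt: Path | None = None
    spacer_length: int = 20
    counting_mode: str = "scan"
    counting_offset: int | None = None
    normalization: str = "median_scaling"
    hitcall_params: hitcall.HitcallParams = dataclasses.field(
        default_factory=hitcall.HitcallParams
    )
    enrich_sets: tuple[str, ...] = ("C4", "D4")
    q_cut: float = 0.25
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _path(key):
            return (base / raw[key]).resolve() if raw.get(key) else None

        fastq = None
        if raw.get("fastq"):
            fastq = {s: (base / p).resolve() for s, p in raw["fastq"].items()}
        hp = hitcall.HitcallParams(**(raw.get("hitcall") or {}))
        return cls(
            library=_path("library"),
            out_dir=(base / raw["out_dir"]).resolve(),
            design=_path("design"),
            counts=_path("counts"),
            fastq=fastq,
            gmt=_path("gmt"),
            spacer_length=int(raw.get("spacer_length", 20)),
            counting_mode=raw.get("counting_mode", "scan"),
            counting_offset=raw.get("counting_offset"),
            normalization=raw.get("normalization", "median_scaling"),
            hitcall_params=hp,
            enrich_sets=tuple(raw.get("enrich_sets", ("C4", "D4"))),
            q_cut=float(raw.get("q_cut", 0.25)),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
        )

    def validate(self) -> None:
        if self.library is None or not Path(self.library).exists():
            raise ConfigError(f"library file not found: {self.library}")
        if self.design is None or not Path(self.design).exists():
            raise ConfigError(f"design file not found: {self.design}")
        if self.counts is None and not self.fastq:
            raise ConfigError("config must provide either counts or fastq inputs")
        if self.counts is not None and not Path(self.counts).exists():
            raise ConfigError(f"counts file not found: {self.counts}")
        for sample, path in (self.fastq or {}).items():
            if not Path(path).exists():
                raise ConfigError(f"FASTQ for sample {sample!r} not found: {path}")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise ConfigError(f"GMT file not found: {self.gmt}")

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("library", "out_dir", "design", "counts", "gmt"):
            if out[key] is not None:
                out[key] = str(out[key])
        if out["fastq"]:
            out["fastq"] = {s: str(p) for s, p in out["fastq"].items()}
        out["enrich_sets"] = list(out["enrich_sets"])
        return out


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage, file-mediated, into ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        lib = read_library(config.library, spacer_length=config.spacer_length)
        design = counting.read_design(config.design)

        stage = "count"
        if config.fastq:
            cm, stats = counting.count_reads(
                lib,
                config.fastq,
                design=design,
                mode=config.counting_mode,
                offset=config.counting_offset,
            )
            outputs["counts"] = counting.write_counts(cm, out / "counts.tsv")
            outputs["mapping_stats"] = counting.write_mapping_stats(
                stats, out / "mapping_stats.tsv"
            )
            report = counting.mapping_report(stats)
            outputs["mapping_report"] = out / "mapping_report.tsv"
            report.to_csv(outputs["mapping_report"], sep="\t", index_label="sample")
        else:
            cm = counting.read_counts(config.counts, design)
            outputs["counts"] = counting.write_counts(cm, out / "counts.tsv")
        cm = counting.read_counts(outputs["counts"], design)

        stage = "normalize"
        norm = normalize.median_normalize(cm, method=config.normalization)
        outputs["normalized"] = normalize.write_normalized(norm, out / "normalized.tsv")
        outputs["size_factors"] = normalize.write_size_factors(
            norm, out / "size_factors.tsv"
        )
        norm = normalize.read_normalized(
            outputs["normalized"], design, norm.size_factors, norm.method
        )

        stage = "qc"
        qc = normalize.qc_report(norm)
        outputs["qc_samples"] = out / "qc_samples.tsv"
        qc.sample_stats.to_csv(outputs["qc_samples"], sep="\t", index_label="sample")
        corr = qc.correlations_long()
        if corr is not None:
            outputs["qc_correlations"] = out / "qc_correlations.tsv"
            corr.to_csv(outputs["qc_correlations"], sep="\t", index=False)

        stage = "hitcall"
        ledger = hitcall.run_hitcall(norm, config.hitcall_params)
        outputs.update(
            {f"ledger_{k}": v for k, v in ledger.write(out, prefix="ledger").items()}
        )
        gene_sets = {
            name: sorted(ledger.gene_set(name))
            for name in ("A3", "B3", "C3", "D3", "A4", "B4", "C4", "D4")
        }
        gene_sets["B3_and_D3"] = sorted(ledger.shared_resistance)
        gene_sets["A3_and_C3"] = sorted(ledger.shared_sensitivity)
        outputs["gene_sets"] = out / "gene_sets.json"
        with open(outputs["gene_sets"], "w") as fh:
            json.dump(gene_sets, fh, indent=1, sort_keys=True)
            fh.write("\n")

        if config.gmt is not None:
            stage = "enrich"
            universe = set(lib.targeting_genes)
            collection = enrichment.read_gmt(config.gmt, universe=universe)
            for set_name in config.enrich_sets:
                query = ledger.gene_set(set_name)
                key = f"enrichment_{set_name}"
                outputs[key] = out / f"enrichment_{set_name}.tsv"
                if not query & collection.universe:
                    logger.warning(
                        "no %s genes in the enrichment universe; writing empty table",
                        set_name,
                    )
                    pd.DataFrame(
                        columns=["set_name", "k", "K", "n", "N", "ratio", "p", "q"]
                    ).to_csv(outputs[key], sep="\t", index=False)
                    continue
                table = enrichment.enrich(query, collection)
                table.to_csv(outputs[key], sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "status": "complete",
            "chronoscreen_version": __version__,
            "parameters": config.echo(),
            "inputs": {
                name: {"path": str(p), "sha256": _sha256(Path(p))}
                for name, p in _input_paths(config).items()
            },
            "outputs": {
                name: {"path": p.name, "sha256": _sha256(p)}
                for name, p in sorted(outputs.items())
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        incomplete = {
            "status": "incomplete",
            "failed_stage": stage,
            "error": str(exc),
            "outputs_written": sorted(k for k in outputs),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(incomplete, fh, indent=1, sort_keys=True)
            fh.write("\n")
        raise StageError(stage, exc) from exc
    return out


def _input_paths(config: PipelineConfig) -> dict[str, Path]:
    paths = {"library": config.library, "design": config.design}
    if config.counts is not None:
        paths["counts"] = config.counts
    for sample, p in (config.fastq or {}).items():
        paths[f"fastq:{sample}"] = p
    if config.gmt is not None:
        paths["gmt"] = config.gmt
    return {k: Path(v) for k, v in paths.items()}
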