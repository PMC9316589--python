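"""sgRNA library model and I/O.

A pooled CRISPR knockout screen is quantified against a fixed catalogue of
guides.  This module models that catalogue: each guide has a stable id, a
target gene (or the reserved nontargeting label), and a fixed-length DNA
spacer used for exact-match read assignment.  A seeded synthetic preset
emulating a genome-wide GeCKO-B-style human knockout library (58,028 guides,
three per gene, 1,000 nontargeting controls) is provided for simulation work.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Gene label reserved for nontargeting control guides.
NONTARGETING_LABEL = "non-targeting"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_VALID_SPACER = frozenset("ACGT")


class LibraryError(ValueError):
    """Raised when a guide library violates its invariants."""


@dataclasses.dataclass(frozen=True)
class SgRNARecord:
    """One guide: id, target gene, spacer sequence, nontargeting flag.

    ``gene`` is :data:`NONTARGETING_LABEL` exactly when ``is_nontargeting``
    is true; the spacer is an upper-case string over A/C/G/T.
    """

    guide_id: str
    gene: str
    spacer: str
    is_nontargeting: bool


class GuideLibrary:
    """Validated, ordered collection of :class:`SgRNARecord`.

    Invariants enforced on construction: unique guide ids, unique spacers
    (required for unambiguous exact-match counting), spacers over A/C/G/T of
    the declared length, and consistency of the nontargeting flag with the
    reserved gene label.
    """

    def __init__(self, records: Iterable[SgRNARecord], spacer_length: int = 20):
        self.records: tuple[SgRNARecord, ...] = tuple(records)
        self.spacer_length = int(spacer_length)
        if self.spacer_length <= 0:
            raise LibraryError("spacer_length must be positive")
        if not self.records:
            raise LibraryError("library has no records")
        self._validate()

    def _validate(self) -> None:
        frame = self.to_frame()
        dup_ids = frame.loc[frame["guide_id"].duplicated(keep=False), "guide_id"]
        if len(dup_ids):
            raise LibraryError(
                f"duplicate guide_id values: {sorted(set(dup_ids))[:5]} "
                f"(rows {list(dup_ids.index[:5])})"
            )
        dup_sp = frame.loc[frame["spacer"].duplicated(keep=False)]
        if len(dup_sp):
            raise LibraryError(
                f"duplicate spacers shared by guides {list(dup_sp['guide_id'][:6])} "
                f"(rows {list(dup_sp.index[:6])})"
            )
        bad_len = frame.loc[frame["spacer"].str.len() != self.spacer_length]
        if len(bad_len):
            raise LibraryError(
                f"spacers with length != {self.spacer_length}: "
                f"{list(bad_len['guide_id'][:5])}"
            )
        bad_chars = [
            r.guide_id for r in self.records if not _VALID_SPACER.issuperset(r.spacer)
        ]
        if bad_chars:
            raise LibraryError(f"non-ACGT characters in spacers of {bad_chars[:5]}")
        flag_vs_label = frame["is_nontargeting"] != (frame["gene"] == NONTARGETING_LABEL)
        if flag_vs_label.any():
            bad = list(frame.loc[flag_vs_label, "guide_id"][:5])
            raise LibraryError(
                f"is_nontargeting flag inconsistent with gene label for {bad}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GuideLibrary)
            and self.spacer_length == other.spacer_length
            and self.records == other.records
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [r.guide_id for r in self.records],
                "gene": [r.gene for r in self.records],
                "spacer": [r.spacer for r in self.records],
                "is_nontargeting": [r.is_nontargeting for r in self.records],
            }
        )

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    @property
    def genes(self) -> pd.Series:
        """Gene per guide, indexed by guide_id."""
        return pd.Series(
            [r.gene for r in self.records],
            index=self.guide_ids,
            name="gene",
        )

    @property
    def targeting_genes(self) -> list[str]:
        """Unique targeted gene symbols, first-occurrence order."""
        seen: dict[str, None] = {}
        for r in self.records:
            if not r.is_nontargeting:
                seen.setdefault(r.gene)
        return list(seen)

    @property
    def n_nontargeting(self) -> int:
        return sum(r.is_nontargeting for r in self.records)

    def spacer_index(self) -> dict[str, int]:
        """spacer -> row position, for exact-match counting."""
        return {r.spacer: i for i, r in enumerate(self.records)}


def _parse_bool(column: pd.Series, path: Path) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    lowered = column.astype(str).str.strip().str.lower()
    unknown = lowered.loc[~lowered.isin(mapping)]
    if len(unknown):
        raise LibraryError(
            f"{path}: unparseable is_nontargeting values {sorted(set(unknown))[:3]}"
        )
    return lowered.map(mapping)


def read_library(path: str | Path, spacer_length: int = 20) -> GuideLibrary:
    """Read a tab-separated guide table (guide_id, gene, spacer, is_nontargeting).

    Row order is preserved.  Nontargeting rows may leave the gene column
    empty; it is coerced to :data:`NONTARGETING_LABEL`.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["guide_id", "gene", "spacer", "is_nontargeting"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise LibraryError(f"{path}: missing columns {missing}")
    ntc = _parse_bool(frame["is_nontargeting"], path)
    genes = frame["gene"].where(~(ntc & (frame["gene"] == "")), NONTARGETING_LABEL)
    records = [
        SgRNARecord(gid, gene, spacer.upper(), bool(flag))
        for gid, gene, spacer, flag in zip(
            frame["guide_id"], genes, frame["spacer"], ntc
        )
    ]
    return GuideLibrary(records, spacer_length=spacer_length)


def write_library(lib: GuideLibrary, path: str | Path) -> Path:
    """Write the library as the tab-separated dialect read_library accepts."""
    path = Path(path)
    frame = lib.to_frame()
    frame["is_nontargeting"] = np.where(frame["is_nontargeting"], "true", "false")
    frame.to_csv(path, sep="\t", index=False)
    return path


def _random_unique_spacers(
    n: int, length: int, rng: np.random.Generator
) -> list[str]:
    """Draw n distinct random DNA words of the given length."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        m = n - len(out) + 16
        arr = rng.integers(0, 4, size=(m, length), dtype=np.int8)
        words = _BASES[arr].view(f"S{length}").ravel()
        for w in words:
            s = w.decode()
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


def make_library(
    n_genes: int,
    n_nontargeting: int,
    guides_per_gene: int = 3,
    spacer_length: int = 20,
    seed: int = 0,
    extra_guides: int = 0,
) -> GuideLibrary:
    """Build a synthetic library with seeded random unique spacers.

    ``extra_guides`` appends that many additional guides to the first genes
    (one each), which lets a preset hit an exact total guide count that is
    not a multiple of ``guides_per_gene``.
    """
    if extra_guides > n_genes:
        raise LibraryError("extra_guides cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    gene_width = max(5, len(str(n_genes)))
    genes = [f"GENE{i + 1:0{gene_width}d}" for i in range(n_genes)]
    n_targeting = n_genes * guides_per_gene + extra_guides
    spacers = _random_unique_spacers(n_targeting + n_nontargeting, spacer_length, rng)
    records: list[SgRNARecord] = []
    pos = 0
    for gi, gene in enumerate(genes):
        k = guides_per_gene + (1 if gi < extra_guides else 0)
        for j in range(k):
            records.append(SgRNARecord(f"{gene}_{j + 1}", gene, spacers[pos], False))
            pos += 1
    for j in range(n_nontargeting):
        records.append(
            SgRNARecord(f"NTC_{j + 1:05d}", NONTARGETING_LABEL, spacers[pos], True)
        )
        pos += 1
    return GuideLibrary(records, spacer_length=spacer_length)


def gecko_b_profile(seed: int = 0) -> GuideLibrary:
    """Synthetic stand-in for the screened GeCKO-B-style human library.

    58,028 guides total: 1,000 nontargeting controls and 57,028 targeting
    guides.  Since 57,028 = 3 x 19,009 + 1, the preset assigns three guides
    to each of 19,009 synthetic genes and a fourth guide to the first gene,
    honouring every published count simultaneously.  Spacers are seeded
    random unique 20-mers (the real vendor sequences are not needed for any
    computation here).
    """
    return make_library(
        n_genes=19_009,
        n_nontargeting=1_000,
        guides_per_gene=3,
        spacer_length=20,
        seed=seed,
        extra_guides=1,
    )


def scaled_profile(
    n_genes: int = 2_000, n_nontargeting: int = 1_000, seed: int = 0
) -> GuideLibrary:
    """Desk-scale library with the same 3-guides-per-gene + NTC structure."""
    return make_library(
        n_genes=n_genes,
        n_nontargeting=n_nontargeting,
        guides_per_gene=3,
        spacer_length=20,
        seed=seed,
    )


def export_spacers_fasta(lib: GuideLibrary, path: str | Path) -> Path:
    """Write one FASTA record per guide (header = guide_id, seq = spacer)."""
    path = Path(path)
    records = (
        SeqRecord(Seq(r.spacer), id=r.guide_id, description="") for r in lib.records
    )
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
    return path
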