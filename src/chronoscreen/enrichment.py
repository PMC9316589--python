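"""Hypergeometric over-representation of hit gene sets in pathway collections.

Given a query gene set (e.g. the ZT28-specific sensitivity genes from the
hit caller) and a GMT collection of pathways, each pathway is scored with
the upper-tail hypergeometric probability of observing at least k query
genes among the pathway's K members, drawing n query genes from a universe
of N background genes.  The background defaults to the genes screened (hits
can only come from screened genes), not the whole genome.
Benjamini-Hochberg adjustment is applied across the collection per query;
raw p-values are retained alongside.  A Venn-style intersection of two
enriched-pathway lists supports cross-assay comparison (e.g. CRISPR screen
versus expression profiling).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise EnrichmentError("universe is empty")
        empty = [n for n, s in self.sets.items() if not (s & self.universe)]
        if empty:
            raise EnrichmentError(
                f"gene sets with no member in the universe: {empty[:5]}"
            )

    def restricted(self) -> dict[str, frozenset[str]]:
        return {name: s & self.universe for name, s in self.sets.items()}


def read_gmt(path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> member...) per line.

    Duplicate members within a line are collapsed; duplicate set names are
    an error, as are lines with fewer than three fields.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EnrichmentError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member (got {len(fields)} fields)"
                )
            name = fields[0]
            if name in sets:
                raise EnrichmentError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise EnrichmentError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
    return path


def enrich(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in every set.

    Returns one row per set with overlap k, set size K and query size n
    (both within the universe), universe size N, enrichment ratio k/n,
    upper-tail p = P(X >= k), and BH-adjusted q; sorted by p.
    """
    universe = collection.universe
    query_in = frozenset(query) & universe
    if not query_in:
        raise EnrichmentError("query has no genes in the universe")
    N = len(universe)
    n = len(query_in)
    rows = []
    for name, members in collection.restricted().items():
        K = len(members)
        k = len(members & query_in)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, k / n, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "ratio", "p"]
    )
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)


@dataclasses.dataclass
class VennPartition:
    """Intersection of two significant-pathway lists at a q cutoff."""

    shared: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]


def intersect_enrichments(
    rows_a: pd.DataFrame, rows_b: pd.DataFrame, q_cut: float
) -> VennPartition:
    """Pathways significant (q < q_cut) in both, or only one, of two queries.

    Both tables must come from the same collection (identical set names).
    """
    names_a = set(rows_a["set_name"])
    names_b = set(rows_b["set_name"])
    if names_a != names_b:
        raise EnrichmentError(
            "enrichment tables were not computed against the same collection"
        )
    sig_a = set(rows_a.loc[rows_a["q"] < q_cut, "set_name"])
    sig_b = set(rows_b.loc[rows_b["q"] < q_cut, "set_name"])
    return VennPartition(
        shared=frozenset(sig_a & sig_b),
        only_a=frozenset(sig_a - sig_b),
        only_b=frozenset(sig_b - sig_a),
    )


def plot_enrichment_bars(table: pd.DataFrame, path: str | Path, top: int = 10) -> Path:
    """Horizontal bars of enrichment ratio, annotated with raw p (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = table.nsmallest(top, "p").iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(shown) + 1.2))
    ax.barh(shown["set_name"], shown["ratio"], color="#3b6ea5")
    for y, (ratio, p) in enumerate(zip(shown["ratio"], shown["p"])):
        ax.text(ratio, y, f" {ratio:.2f} ({p:.2e})", va="center", fontsize=8)
    ax.set_xlabel("ratio of enriched hits (k/n)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
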