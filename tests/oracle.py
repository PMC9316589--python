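"""Independent brute-force oracles used only by the test suite.

These re-implement the operations under test in the most literal way
possible (plain loops, dicts and exact rational arithmetic) and share no
code with the package paths they check.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

NONTARGETING = "non-targeting"


def naive_hitcall(guides, params):
    """Straight-line re-implementation of the fold-change set algebra.

    ``guides``: list of (guide_id, gene, a, b, c, d) tuples of normalized
    values, nontargeting guides carrying gene == "non-targeting".
    ``params``: object with the hit-caller's threshold attributes.

    Returns a dict with the pseudocounted datasets, per-guide ratios, the
    guide gate sets and every gene-level set.
    """
    pc = params.pseudocount

    kept = []
    for guide_id, gene, a, b, c, d in guides:
        if gene == NONTARGETING:
            continue
        values = (a, b, c, d)
        if params.zero_filter_scope == "any_sample":
            if any(v <= 0 for v in values):
                continue
        else:
            if all(v <= 0 for v in values):
                continue
        kept.append((guide_id, gene, a, b, c, d))

    a1, b1, c1, d1, r16, r28, gene_of = {}, {}, {}, {}, {}, {}, {}
    for guide_id, gene, a, b, c, d in kept:
        a1[guide_id] = round(a + pc, 12)
        b1[guide_id] = round(b + pc, 12)
        c1[guide_id] = round(c + pc, 12)
        d1[guide_id] = round(d + pc, 12)
        r16[guide_id] = b1[guide_id] / a1[guide_id]
        r28[guide_id] = d1[guide_id] / c1[guide_id]
        gene_of[guide_id] = gene

    sets = {"A2": set(), "B2": set(), "C2": set(), "D2": set()}
    for guide_id in a1:
        if r16[guide_id] >= params.up_threshold:
            sets["B2"].add(guide_id)
        if r16[guide_id] < params.down_threshold:
            sets["A2"].add(guide_id)
        if r28[guide_id] >= params.up_threshold:
            sets["D2"].add(guide_id)
        if r28[guide_id] < params.down_threshold:
            sets["C2"].add(guide_id)

    def primed(guide_set):
        per_gene = {}
        for guide_id in guide_set:
            per_gene.setdefault(gene_of[guide_id], set()).add(guide_id)
        return {g for g, gs in per_gene.items()
                if len(gs) >= params.min_concordant_guides}

    def strong(ratio, up):
        out = set()
        for guide_id, r in ratio.items():
            hit = r >= params.strong_up if up else r < params.strong_down
            if hit:
                out.add(gene_of[guide_id])
        return out

    gene_sets = {
        "A2_primed": primed(sets["A2"]),
        "B2_primed": primed(sets["B2"]),
        "C2_primed": primed(sets["C2"]),
        "D2_primed": primed(sets["D2"]),
        "A2_strong": strong(r16, up=False),
        "B2_strong": strong(r16, up=True),
        "C2_strong": strong(r28, up=False),
        "D2_strong": strong(r28, up=True),
    }
    for letter in "ABCD":
        gene_sets[f"{letter}3"] = (
            gene_sets[f"{letter}2_primed"] | gene_sets[f"{letter}2_strong"]
        )
    gene_sets["B4"] = gene_sets["B3"] - gene_sets["D3"]
    gene_sets["D4"] = gene_sets["D3"] - gene_sets["B3"]
    gene_sets["A4"] = gene_sets["A3"] - gene_sets["C3"]
    gene_sets["C4"] = gene_sets["C3"] - gene_sets["A3"]

    return {
        "index": set(a1),
        "a1": a1, "b1": b1, "c1": c1, "d1": d1,
        "r16": r16, "r28": r28,
        "guide_sets": sets,
        "gene_sets": gene_sets,
    }


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact P(X >= k) for a hypergeometric(N, K, n) by combinatorial sum."""
    denom = comb(N, n)
    total = 0
    for i in range(max(k, 0), min(K, n) + 1):
        if n - i <= N - K:
            total += comb(K, i) * comb(N - K, n - i)
    return Fraction(total, denom)


def bh_adjust(pvalues):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * m / rank)
        adjusted[i] = running_min
    return adjusted
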