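"""GO-term enrichment between two gene sets by Fisher's exact test.

Compares term frequencies in a test set against a reference set, with the
exact two-sided p-value (hypergeometric tail summation over tables at least
as improbable as the observed one) and optional Benjamini-Hochberg
adjustment.  Terms are used flat, as annotated (no GO-graph propagation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .errors import ArgumentError


def _term_sets(annotation: pd.DataFrame) -> dict:
    out = {}
    for gene, terms in zip(annotation["probe_id"], annotation["go_terms"].fillna("")):
        out[gene] = set(t for t in str(terms).split(";") if t)
    return out


def fisher_term_enrichment(
    test_genes,
    reference_genes,
    annotation: pd.DataFrame,
    adjust: str = "benjamini_hochberg",
) -> pd.DataFrame:
    """Per-term 2x2 Fisher's exact test, test set vs reference set.

    Odds ratios use the Haldane 0.5 correction when any cell is zero.  Terms
    annotated in neither set produce no row.
    """
    test_genes = sorted(set(test_genes))
    reference_genes = sorted(set(reference_genes))
    if not test_genes or not reference_genes:
        raise ArgumentError("test and reference gene sets must be non-empty")
    overlap = set(test_genes) & set(reference_genes)
    if overlap:
        raise ArgumentError(f"gene sets must be disjoint; shared: {sorted(overlap)[:5]}")
    terms_of = _term_sets(annotation)
    all_terms = sorted(
        set().union(*(terms_of.get(g, set()) for g in test_genes + reference_genes))
    )
    rows = []
    for term in all_terms:
        a = sum(term in terms_of.get(g, set()) for g in test_genes)
        b = len(test_genes) - a
        c = sum(term in terms_of.get(g, set()) for g in reference_genes)
        d = len(reference_genes) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append((term, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows,
        columns=["term", "test_with", "test_without", "ref_with", "ref_without",
                 "odds_ratio", "p"],
    ).set_index("term")
    if len(out):
        out["p_adjusted"] = adjust_pvalues(out["p"].to_numpy(), method=adjust)
    else:
        out["p_adjusted"] = []
    return out


ADJUST_METHODS = ("none", "benjamini_hochberg")


def adjust_pvalues(p, method: str = "benjamini_hochberg") -> np.ndarray:
    """BH step-up adjustment (monotone non-decreasing in rank)."""
    if method not in ADJUST_METHODS:
        raise ArgumentError(f"unknown adjustment method: {method!r}")
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ArgumentError("p-values must lie in [0, 1]")
    if method == "none" or p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
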