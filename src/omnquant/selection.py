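"""Transcriptomic candidate selection: DE filter, GO over-representation,
single-cell QC gate, and spatial expression-pattern summaries.

The bulk differential-expression filter keeps genes with fold change
strictly greater than 2 (|log2FC| > 1) and adjusted p strictly below
0.01, routed by the sign of the fold change into early-born vs late-born
candidate lists.  GO over-representation uses a one-sided binomial test
(upper tail) per term against the background term frequency, Bonferroni-
corrected across the terms actually tested.  The single-cell QC gate
excludes cells with < 1,100 or > 15,000 detected genes or > 4%
mitochondrial counts — exclusions are strict, so boundary cells are
retained.  Pattern summaries partition validated genes over the seven
non-empty subsets of {dorsal nIII, ventral nIII, nIV}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "de_filter",
    "go_overrepresentation",
    "sc_qc_filter",
    "pattern_summary",
    "QC_MIN_GENES",
    "QC_MAX_GENES",
    "QC_MAX_PCT_MITO",
    "PATTERN_REGIONS",
]

QC_MIN_GENES = 1_100
QC_MAX_GENES = 15_000
QC_MAX_PCT_MITO = 4.0

PATTERN_REGIONS = ("dorsal_nIII", "ventral_nIII", "nIV")

#: Which expression regions are consistent with each predicted category.
#: A call agrees if its expressed_in set intersects the mapped regions.
DEFAULT_CATEGORY_REGIONS: dict[str, frozenset[str]] = {
    "early": frozenset({"dorsal_nIII"}),
    "late": frozenset({"ventral_nIII", "nIV"}),
    "cluster0": frozenset({"ventral_nIII", "nIV"}),
    "cluster1": frozenset({"nIV"}),
    "cluster2": frozenset({"dorsal_nIII"}),
}


def de_filter(table: pd.DataFrame, fc_threshold: float = 2.0,
              padj_threshold: float = 0.01) -> dict[str, list[str]]:
    """Split a DE table into early- and late-enriched candidate lists.

    A gene passes iff |log2 fold change| > log2(fc_threshold) AND
    adjusted p < padj_threshold, both strict; positive log2FC routes to
    the early list, negative to late.  Genes with a missing adjusted p
    are excluded with a warning, never passed silently.
    """
    if fc_threshold <= 1 or not 0 < padj_threshold <= 1:
        raise ValueError("fc_threshold must be > 1 and padj_threshold in (0, 1]")
    lfc = table["log2_fold_change"].to_numpy(float)
    padj = table["adjusted_p"].to_numpy(float)
    missing = ~np.isfinite(padj)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} genes lack an adjusted p-value "
                      "and were excluded from the DE filter", stacklevel=2)
    passing = (~missing & (np.abs(lfc) > np.log2(fc_threshold))
               & (padj < padj_threshold))
    genes = table["gene_id"].to_numpy(object)
    return {
        "early_candidates": list(genes[passing & (lfc > 0)]),
        "late_candidates": list(genes[passing & (lfc < 0)]),
    }


@dataclass(frozen=True)
class GOTermResult:
    term_id: str
    k: int              # selected genes carrying the term
    n: int              # selected genes
    K: int              # background genes carrying the term
    N: int              # background genes
    p_binomial: float
    p_bonferroni: float


def go_overrepresentation(selected, background,
                          annotation: dict[str, set[str]]
                          ) -> list[GOTermResult]:
    """One-sided binomial GO over-representation test with Bonferroni.

    Per term with at least one selected gene: with background frequency
    q = K/N, p = P(X >= k) for X ~ Binomial(n, q).  Genes absent from the
    annotation count as term-free.  Terms annotating no background gene
    are skipped with a warning.  The Bonferroni denominator is the number
    of terms actually tested (k >= 1).  Results sorted by p.
    """
    selected = set(selected)
    background = set(background)
    if not selected:
        raise ValueError("selected gene set is empty")
    if not selected <= background:
        extra = sorted(selected - background)[:5]
        raise ValueError(f"selected genes not in background, e.g. {extra}")
    n, N = len(selected), len(background)

    term_selected: dict[str, int] = {}
    term_background: dict[str, int] = {}
    for gene in background:
        for term in annotation.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in selected:
                term_selected[term] = term_selected.get(term, 0) + 1
    orphans = {t for g, ts in annotation.items() if g not in background
               for t in ts} - set(term_background)
    if orphans:
        warnings.warn(f"{len(orphans)} annotation terms have no background "
                      "gene and were skipped", stacklevel=2)

    tested = sorted(term_selected)  # k >= 1 by construction
    m = len(tested)
    results = []
    for term in tested:
        k, K = term_selected[term], term_background[term]
        p = float(binom.sf(k - 1, n, K / N))  # upper tail P(X >= k)
        results.append(GOTermResult(term_id=term, k=k, n=n, K=K, N=N,
                                    p_binomial=p,
                                    p_bonferroni=min(1.0, p * m)))
    return sorted(results, key=lambda r: r.p_binomial)


def sc_qc_filter(cells: pd.DataFrame) -> pd.DataFrame:
    """Apply the single-cell exclusion gate; returns retained rows.

    Excluded: < 1,100 detected genes, > 15,000 detected genes, or > 4%
    mitochondrial counts.  All exclusions are strict inequalities, so
    cells exactly on a boundary are retained.  Idempotent.
    """
    genes = cells["n_genes_detected"].to_numpy()
    mito = cells["pct_mito"].to_numpy(float)
    if np.any(genes < 0):
        raise ValueError("n_genes_detected must be >= 0")
    if np.any((mito < 0) | (mito > 100)):
        raise ValueError("pct_mito must lie in [0, 100]")
    keep = ((genes >= QC_MIN_GENES) & (genes <= QC_MAX_GENES)
            & (mito <= QC_MAX_PCT_MITO))
    return cells.loc[keep].copy()


def _subset_key(regions: frozenset[str]) -> str:
    return "+".join(r for r in PATTERN_REGIONS if r in regions)


def pattern_summary(calls: pd.DataFrame,
                    category_regions: dict[str, frozenset[str]] | None = None,
                    ) -> tuple[dict[str, int], pd.DataFrame]:
    """Venn-region counts and prediction-agreement table for probe calls.

    ``calls`` has columns gene_id, expressed_in (an iterable or a
    '+'-joined string of region names), predicted_category.  Each gene
    lands in exactly one of the 7 non-empty subsets of the region set, so
    the Venn counts always sum to the number of genes.  A gene agrees
    with its predicted category when its expression set intersects the
    regions mapped to that category.
    """
    mapping = category_regions or DEFAULT_CATEGORY_REGIONS
    venn = {_subset_key(frozenset(sub)): 0
            for r in range(1, len(PATTERN_REGIONS) + 1)
            for sub in combinations(PATTERN_REGIONS, r)}
    rows = []
    for rec in calls.itertuples(index=False):
        raw = rec.expressed_in
        regions = frozenset(raw.split("+")) if isinstance(raw, str) \
            else frozenset(raw)
        if not regions:
            raise ValueError(f"gene {rec.gene_id!r} has empty expressed_in")
        unknown = regions - set(PATTERN_REGIONS)
        if unknown:
            raise ValueError(f"gene {rec.gene_id!r} names unknown regions "
                             f"{sorted(unknown)}")
        venn[_subset_key(regions)] += 1
        expected = mapping.get(rec.predicted_category)
        if expected is None:
            raise ValueError(
                f"no region mapping for category {rec.predicted_category!r}")
        rows.append({"gene_id": rec.gene_id,
                     "predicted_category": rec.predicted_category,
                     "expressed_in": _subset_key(regions),
                     "agrees": bool(regions & expected)})
    return venn, pd.DataFrame(rows)
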