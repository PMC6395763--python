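"""Intersect gene lists with GWAS-catalog trait categories.

Catalog associations are grouped into named trait categories by exact
(normalized) trait-string match; each matching record contributes the union
of its reported and mapped gene symbols to the category's gene set.  Query
gene lists — adipose-specific/enhanced genes or depot DEGs — are then
matched case-insensitively against those sets.  A generic hypergeometric
over-representation test covers pathway/GO-style gene-set enrichment with
user-supplied sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from ._stats import bh_adjust
from .config import AnalysisConfig
from .io_formats import GWASCatalogRecord, TraitCategoryMap

__all__ = [
    "AssociationResult",
    "extract_catalog_genes",
    "match_genes",
    "category_counts",
    "overrepresentation_test",
    "associations_to_frame",
]


@dataclass
class AssociationResult:
    """One query gene matched to at least one trait category."""

    symbol: str
    categories: set[str]
    source_list: str = ""          # e.g. adipose_specific_enhanced | depot_deg
    depot_or_direction: str = ""

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("an AssociationResult must carry >= 1 category")


def extract_catalog_genes(
    records: Iterable[GWASCatalogRecord], categories: TraitCategoryMap
) -> dict[str, set[str]]:
    """Per-category union of reported + mapped gene symbols.

    A record contributes to a category iff its normalized trait string
    exactly matches one of the category's trait strings; records with
    unmatched traits are ignored.  Symbols are deduplicated
    case-insensitively, keeping the first spelling seen.
    """
    canonical: dict[str, dict[str, str]] = {name: {} for name in categories.names}
    for rec in records:
        hit = categories.categories_of(rec.trait)
        if not hit:
            continue
        for cat in hit:
            pool = canonical[cat]
            for symbol in rec.reported_genes + rec.mapped_genes:
                pool.setdefault(symbol.casefold(), symbol)
    return {cat: set(pool.values()) for cat, pool in canonical.items()}


def match_genes(
    query: Sequence[str],
    catalog_sets: Mapping[str, set[str]],
    source_list: str = "",
    depot_of: Mapping[str, str] | None = None,
) -> list[AssociationResult]:
    """Match query gene symbols against category gene sets, case-insensitively.

    One result per distinct query gene hitting at least one category; genes
    in no category are absent from the output.  Idempotent and independent
    of query order (output is sorted by symbol).
    """
    folded_sets = {
        cat: {g.casefold() for g in genes} for cat, genes in catalog_sets.items()
    }
    seen: dict[str, str] = {}
    for symbol in query:
        seen.setdefault(symbol.casefold(), symbol)
    results = []
    for key, symbol in seen.items():
        cats = {cat for cat, genes in folded_sets.items() if key in genes}
        if cats:
            results.append(
                AssociationResult(
                    symbol=symbol,
                    categories=cats,
                    source_list=source_list,
                    depot_or_direction=(depot_of or {}).get(symbol, ""),
                )
            )
    results.sort(key=lambda r: r.symbol)
    return results


def category_counts(
    results: Iterable[AssociationResult],
) -> tuple[dict[str, int], dict[int, int]]:
    """Distinct-gene count per category plus a category-cardinality histogram.

    A gene hitting several categories counts once in each; the histogram
    maps "number of categories hit" to "number of genes".
    """
    per_category: Counter[str] = Counter()
    cardinality: Counter[int] = Counter()
    for res in results:
        for cat in res.categories:
            per_category[cat] += 1
        cardinality[len(res.categories)] += 1
    return dict(per_category), dict(cardinality)


def overrepresentation_test(
    query: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    universe: Iterable[str],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    With universe size N, set size K (after intersecting with the universe),
    query size n and overlap k, p = P(X >= k) for X hypergeometric(N, K, n).
    q-values are BH across sets; rows passing q < ``ora_fdr`` are flagged.
    """
    config = config or AnalysisConfig()
    uni = {g.casefold() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    qset = {g.casefold() for g in query}
    if not qset <= uni:
        raise ValueError("query genes outside the universe")
    N, n = len(uni), len(qset)
    rows = []
    for name in sorted(gene_sets):
        members = {g.casefold() for g in gene_sets[name]} & uni
        K = len(members)
        k = len(members & qset)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < config.ora_fdr
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def associations_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results for TSV export."""
    rows = [
        {
            "gene": r.symbol,
            "categories": ";".join(sorted(r.categories)),
            "n_categories": len(r.categories),
            "source": r.source_list,
            "depot_or_direction": r.depot_or_direction,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["gene", "categories", "n_categories", "source", "depot_or_direction"]
    )
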