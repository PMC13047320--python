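"""Hypergeometric over-representation analysis (ORA) and functional
category grouping.

For a query of n genes drawn from a universe of N genes and a term of K
universe genes overlapping the query in k genes, the enrichment p-value is
the upper hypergeometric tail P(X >= k), X ~ Hypergeometric(N, K, n)
(one-sided over-representation). BH correction is applied within each
source collection. Significant terms can then be grouped into curated
functional categories (e.g. cell cycle regulation, oxygen response), and
per-gene category membership derived from the significant terms' overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import GeneSetCollection
from .nbglm import bh_adjust


@dataclass
class CategoryMap:
    """Curated category name -> list of term_ids."""

    categories: dict[str, list[str]] = field(default_factory=dict)

    def validate_against(self, collections: list[GeneSetCollection]) -> None:
        known = set()
        for coll in collections:
            known |= set(coll.sets)
        offenders = [
            t for terms in self.categories.values() for t in terms if t not in known
        ]
        if offenders:
            raise ValueError(
                f"category map references unknown term_ids: {sorted(set(offenders))}"
            )


def hypergeometric_enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """One-sided ORA of ``query`` against every set of ``collection``.

    Sets are intersected with the universe before testing; the query must
    be a subset of the universe. BH adjustment is computed within this
    collection.
    """
    if not query:
        raise ValueError("empty query")
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(
            f"query genes outside the universe: {sorted(stray)[:5]}..."
            if len(stray) > 5 else
            f"query genes outside the universe: {sorted(stray)}"
        )
    N = len(universe)
    n = len(query)
    rows = []
    for term_id, (term_name, members) in collection.sets.items():
        eligible = members & universe
        K = len(eligible)
        if K == 0:
            continue
        overlap = sorted(eligible & query)
        k = len(overlap)
        # P(X >= k) = survival function at k-1
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "source": collection.source,
                "term_name": term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": min(p, 1.0),
                "overlap_symbols": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    else:
        df["padj"] = pd.Series(dtype=float)
    return df


def enrich_collections(
    query: set[str],
    collections: list[GeneSetCollection],
    universe: set[str],
) -> pd.DataFrame:
    """ORA across several collections, BH within each source."""
    return pd.concat(
        [hypergeometric_enrich(query, c, universe) for c in collections],
        ignore_index=True,
    )


def assign_categories(
    results: pd.DataFrame,
    category_map: CategoryMap,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group significant terms into categories; derive gene membership.

    Returns ``(term_table, gene_table)``: the significant terms of each
    category, and per-gene category membership where a gene belongs to a
    category iff it overlaps at least one significant term mapped to it.
    Genes in two or more categories are flagged ``multi_category``.
    """
    known_terms = set(results["term_id"]) if not results.empty else set()
    offenders = [
        t
        for terms in category_map.categories.values()
        for t in terms
        if t not in known_terms
    ]
    if offenders:
        raise ValueError(
            f"category map references terms absent from results: {sorted(set(offenders))}"
        )
    sig = results[(results["padj"] < alpha).fillna(False)]
    term_rows = []
    gene_categories: dict[str, set[str]] = {}
    for category, terms in category_map.categories.items():
        hits = sig[sig["term_id"].isin(terms)]
        for row in hits.itertuples():
            term_rows.append(
                {
                    "category": category,
                    "term_id": row.term_id,
                    "source": row.source,
                    "term_name": row.term_name,
                    "padj": row.padj,
                }
            )
            for g in row.overlap_symbols.split(","):
                if g:
                    gene_categories.setdefault(g, set()).add(category)
    gene_rows = [
        {
            "gene": g,
            "categories": ";".join(sorted(cats)),
            "n_categories": len(cats),
            "multi_category": len(cats) >= 2,
        }
        for g, cats in sorted(gene_categories.items())
    ]
    return pd.DataFrame(term_rows), pd.DataFrame(gene_rows)
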