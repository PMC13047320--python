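"""Four-source aging-evidence integration and regulon overlay.

A DEG is an aging-related DEG (AR-DEG) if supported by ANY of:

1. prior annotation in an aging gene database (flat gene list input);
2. proximity (span distance <= 500 kb, inclusive) to a GWAS variant at
   genome-wide significance (p < 5e-8);
3. membership in an aging-related functional category among the
   significantly enriched terms (the curated category map stands in for
   the manual aging-relevance call);
4. an annotated interaction with an antioxidant / anti-inflammatory drug
   (curated two-column drug-gene table input).

Regulons are overlaid by filtering a graded TF->target table (grade A
highest) to edges whose TF and target are both in the supplied gene set.
Distances are anchored to the gene span (strand-ignored); a TSS-anchored
mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, GwasSummary

GWAS_WINDOW = 500_000
GWS_P = 5e-8

CONFIDENCE_GRADES = ("A", "B", "C", "D", "E")  # A = highest


@dataclass
class EvidenceRecord:
    """Per-gene evidence booleans; is_ardeg is their OR by construction."""

    gene_id: str
    in_aging_db: bool
    near_gwas_locus: bool
    in_aging_pathway: bool
    has_drug_interaction: bool
    gwas_best_variant: str = ""
    gwas_distance: int | None = None
    drugs: tuple[str, ...] = ()

    @property
    def is_ardeg(self) -> bool:
        return (
            self.in_aging_db
            or self.near_gwas_locus
            or self.in_aging_pathway
            or self.has_drug_interaction
        )


@dataclass(frozen=True)
class RegulonEdge:
    tf_symbol: str
    target_symbol: str
    confidence: str


def gwas_proximity(
    gene: GeneAnnotation,
    gwas: list[GwasSummary],
    window: int = GWAS_WINDOW,
    p_threshold: float = GWS_P,
    anchor: str = "span",
) -> tuple[bool, str, int | None]:
    """Is the gene within ``window`` bp of a genome-wide-significant variant?

    Distance is 0 for a variant inside the gene span, else the distance
    to the nearer span boundary (``anchor='tss'`` measures from the TSS
    instead). Strand is ignored for the span anchor. Ties on distance are
    broken by the smaller p-value. Returns (flag, best variant id,
    distance); without a qualifying variant the best variant is the
    nearest significant one regardless of window (or '' if none).
    """
    best: tuple[int, float, str] | None = None
    for v in gwas:
        if v.pvalue >= p_threshold or v.chrom != gene.chrom:
            continue
        if anchor == "span":
            if gene.start <= v.pos <= gene.end:
                d = 0
            else:
                d = min(abs(v.pos - gene.start), abs(v.pos - gene.end))
        elif anchor == "tss":
            d = abs(v.pos - gene.tss)
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        cand = (d, v.pvalue, v.variant_id)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return False, "", None
    d, _, vid = best
    return d <= window, vid, d


def integrate_evidence(
    deg_symbols: list[str],
    aging_genes: set[str],
    gwas: list[GwasSummary],
    pathway_members: set[str],
    drug_table: pd.DataFrame,
    annotation: dict[str, GeneAnnotation],
    window: int = GWAS_WINDOW,
    p_threshold: float = GWS_P,
) -> list[EvidenceRecord]:
    """Build the per-DEG evidence vector and AR-DEG verdicts.

    ``drug_table`` has columns ``gene`` and ``drug`` (already restricted
    to antioxidant / anti-inflammatory agents by the curator);
    ``pathway_members`` is the set of genes in aging-related enriched
    categories (from :func:`enrichment.assign_categories`). Symbols match
    case-sensitively.
    """
    drugs_by_gene: dict[str, list[str]] = {}
    if len(drug_table):
        for row in drug_table.itertuples():
            drugs_by_gene.setdefault(str(row.gene), []).append(str(row.drug))
    records = []
    for sym in deg_symbols:
        ann = annotation.get(sym)
        if ann is not None:
            near, best, dist = gwas_proximity(ann, gwas, window, p_threshold)
        else:
            near, best, dist = False, "", None
        drugs = tuple(sorted(set(drugs_by_gene.get(sym, ()))))
        records.append(
            EvidenceRecord(
                gene_id=sym,
                in_aging_db=sym in aging_genes,
                near_gwas_locus=near,
                in_aging_pathway=sym in pathway_members,
                has_drug_interaction=bool(drugs),
                gwas_best_variant=best,
                gwas_distance=dist,
                drugs=drugs,
            )
        )
    return records


def evidence_to_frame(records: list[EvidenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "in_aging_db": r.in_aging_db,
                "near_gwas_locus": r.near_gwas_locus,
                "in_aging_pathway": r.in_aging_pathway,
                "has_drug_interaction": r.has_drug_interaction,
                "is_ardeg": r.is_ardeg,
                "gwas_best_variant": r.gwas_best_variant,
                "gwas_distance": -1 if r.gwas_distance is None else r.gwas_distance,
                "drugs": ",".join(r.drugs),
            }
            for r in records
        ]
    )


def build_regulons(
    gene_symbols: set[str],
    tf_target_table: pd.DataFrame,
    log2fc: dict[str, float] | None = None,
    min_confidence: str = "A",
) -> tuple[list[RegulonEdge], pd.DataFrame]:
    """Filter a graded TF->target table to edges inside ``gene_symbols``.

    ``tf_target_table`` needs columns tf, target, confidence (grades A-E,
    A highest). An edge is kept iff its grade is at least
    ``min_confidence`` and both endpoints are in the gene set. The
    concordance summary reports, per TF, the fraction of its retained
    targets whose log2FC sign matches the TF's own log2FC sign - a
    reporting heuristic only (the table carries no mode-of-regulation
    sign).
    """
    if min_confidence not in CONFIDENCE_GRADES:
        raise ValueError(f"unknown confidence grade {min_confidence!r}")
    admitted = set(CONFIDENCE_GRADES[: CONFIDENCE_GRADES.index(min_confidence) + 1])
    edges = []
    for row in tf_target_table.itertuples():
        grade = str(row.confidence)
        if grade not in CONFIDENCE_GRADES:
            raise ValueError(f"unknown confidence grade {grade!r} in table")
        if grade not in admitted:
            continue
        tf, target = str(row.tf), str(row.target)
        if tf in gene_symbols and target in gene_symbols:
            edges.append(RegulonEdge(tf, target, grade))
    rows = []
    by_tf: dict[str, list[RegulonEdge]] = {}
    for e in edges:
        by_tf.setdefault(e.tf_symbol, []).append(e)
    for tf, tf_edges in sorted(by_tf.items()):
        if log2fc and tf in log2fc:
            tf_sign = np.sign(log2fc[tf])
            signs = [
                np.sign(log2fc[e.target_symbol])
                for e in tf_edges
                if e.target_symbol in log2fc
            ]
            concord = (
                float(np.mean([s == tf_sign for s in signs])) if signs else np.nan
            )
        else:
            concord = np.nan
        rows.append(
            {
                "tf": tf,
                "n_targets": len(tf_edges),
                "targets": ",".join(sorted(e.target_symbol for e in tf_edges)),
                "sign_concordance": concord,
            }
        )
    return edges, pd.DataFrame(rows)
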