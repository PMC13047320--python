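"""DEG tier assignment and CMap-style directional rescue.

Tiers per contrast, strict inequalities exactly as thresholds are stated:

* significant: padj < 0.05 and |log2FC| > 1
* suggestive:  padj < 0.05 and 0.585 < |log2FC| <= 1
* rescued:     suggestive and supported by external CMap-style ModZ
  evidence with consistent directionality
* none otherwise (a failed p-gate overrides any fold change)

CMap support at any dose means sign(ModZ) = sign(log2FC) and either
(1) |log2FC| > 1 and |ModZ| > 1.67, or (2) |log2FC| > 0.585 and
|ModZ| > 2. Criterion (1) cannot fire for a suggestive gene
(|log2FC| <= 1), so suggestive-gene rescue in practice requires
|ModZ| > 2; both criteria are evaluated generically so that significant
genes can also be annotated with CMap support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DegCall:
    gene_id: str
    cell_type: str
    treatment: str
    tier: str  # significant | suggestive | rescued | none
    log2fc_shrunk: float
    padj: float
    cmap_criterion: str = ""  # "1", "2", "1,2" or ""


def assign_tier(
    padj: float, log2fc: float,
    alpha: float = 0.05, lfc: float = 1.0, lfc_suggestive: float = 0.585,
) -> str:
    """Pure tier function of (padj, |log2FC|); strict inequalities."""
    if not np.isfinite(padj) or not (padj < alpha):
        return "none"
    a = abs(log2fc)
    if a > lfc:
        return "significant"
    if a > lfc_suggestive:
        return "suggestive"
    return "none"


def call_degs(
    de_table: pd.DataFrame,
    cell_type: str,
    treatment: str,
    alpha: float = 0.05,
    lfc: float = 1.0,
    lfc_suggestive: float = 0.585,
) -> list[DegCall]:
    """Tier every gene of one contrast's DE table."""
    calls = []
    for row in de_table.itertuples():
        calls.append(
            DegCall(
                gene_id=row.gene_id,
                cell_type=cell_type,
                treatment=treatment,
                tier=assign_tier(row.padj, row.log2fc_shrunk, alpha, lfc, lfc_suggestive),
                log2fc_shrunk=float(row.log2fc_shrunk),
                padj=float(row.padj),
            )
        )
    return calls


def cmap_support(
    log2fc: float,
    modz_values: np.ndarray,
    dose_rule: str = "any",
    thresholds: tuple[tuple[float, float], tuple[float, float]] = (
        (1.0, 1.67),
        (0.585, 2.0),
    ),
) -> str:
    """Which CMap criteria a gene satisfies ('', '1', '2' or '1,2').

    A dose supports the gene iff its ModZ has the sign of log2fc and one
    of the (|log2FC|, |ModZ|) dual thresholds is strictly exceeded.
    ``dose_rule='any'`` requires one such dose, ``'all'`` every dose.
    """
    if dose_rule not in ("any", "all"):
        raise ValueError(f"unknown dose rule {dose_rule!r}")
    modz = np.asarray(modz_values, dtype=float)
    modz = modz[np.isfinite(modz)]
    if modz.size == 0:
        return ""
    agg = np.any if dose_rule == "any" else np.all
    hit = []
    for label, (lfc_t, modz_t) in zip(("1", "2"), thresholds):
        per_dose = (
            (np.sign(modz) == np.sign(log2fc))
            & (abs(log2fc) > lfc_t)
            & (np.abs(modz) > modz_t)
        )
        if agg(per_dose):
            hit.append(label)
    return ",".join(hit)


def cmap_rescue(
    calls: list[DegCall],
    modz: pd.DataFrame,
    dose_rule: str = "any",
) -> list[DegCall]:
    """Annotate CMap support and promote supported suggestive genes.

    ``modz`` is a gene-indexed table with one column per dose. Genes
    absent from the table are never rescued (logged). Returns a new call
    list where supported suggestive genes get tier ``rescued``.
    """
    out = []
    for call in calls:
        if call.tier == "none":
            out.append(call)
            continue
        if call.gene_id not in modz.index:
            logger.info("gene %s absent from ModZ table; not rescued", call.gene_id)
            out.append(call)
            continue
        crit = cmap_support(
            call.log2fc_shrunk, modz.loc[call.gene_id].to_numpy(), dose_rule
        )
        tier = "rescued" if (call.tier == "suggestive" and crit) else call.tier
        out.append(
            DegCall(
                gene_id=call.gene_id,
                cell_type=call.cell_type,
                treatment=call.treatment,
                tier=tier,
                log2fc_shrunk=call.log2fc_shrunk,
                padj=call.padj,
                cmap_criterion=crit,
            )
        )
    return out


def round_percent(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, round-half-even, as a float."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator in percentage")
    frac = Fraction(numerator * 1000, denominator)
    # round-half-even at the first decimal of the percentage
    return round(frac) / 10.0


def summarize_deg_overlap(calls: list[DegCall]) -> pd.DataFrame:
    """Treatment-specificity summary over the DEG union of a run.

    A gene is a DEG if any contrast tiers it significant or rescued; per
    gene the set of responsive treatments is collected, and counts plus
    percentages (one decimal, round-half-even, raw ratio alongside) are
    reported for every observed treatment combination.
    """
    deg_treatments: dict[str, set[str]] = {}
    for c in calls:
        if c.tier in ("significant", "rescued"):
            deg_treatments.setdefault(c.gene_id, set()).add(c.treatment)
    total = len(deg_treatments)
    combos: dict[str, int] = {}
    per_treatment: dict[str, int] = {}
    for trts in deg_treatments.values():
        key = "+".join(sorted(trts))
        combos[key] = combos.get(key, 0) + 1
        for t in trts:
            per_treatment[t] = per_treatment.get(t, 0) + 1
    rows = []
    for key, n in sorted(combos.items()):
        rows.append(
            {
                "subset": key,
                "kind": "exclusive",
                "n_degs": n,
                "percent": round_percent(n, total) if total else 0.0,
                "raw_ratio": n / total if total else 0.0,
            }
        )
    for t, n in sorted(per_treatment.items()):
        rows.append(
            {
                "subset": t,
                "kind": "responsive",
                "n_degs": n,
                "percent": round_percent(n, total) if total else 0.0,
                "raw_ratio": n / total if total else 0.0,
            }
        )
    rows.append(
        {
            "subset": "total",
            "kind": "total",
            "n_degs": total,
            "percent": 100.0 if total else 0.0,
            "raw_ratio": 1.0 if total else 0.0,
        }
    )
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[DegCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "cell_type": c.cell_type,
                "treatment": c.treatment,
                "tier": c.tier,
                "log2fc_shrunk": c.log2fc_shrunk,
                "padj": c.padj,
                "cmap_criterion": c.cmap_criterion,
            }
            for c in calls
        ]
    )
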