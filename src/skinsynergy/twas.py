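"""Targeted transcriptome-wide association (TWAS).

Per gene, the eQTL-weighted association statistic is

    Z_TWAS = w' z / sqrt(w' S w)

with eQTL weight vector w, GWAS z-scores z aligned to the model's
variants, and LD matrix S. The two-sided p-value is 2 Phi(-|Z|), BH
correction is applied within each (tissue, trait) test group, and a
gene-trait mapping is called *reliable* when the top cis-eQTL's Z-score
and the GWAS Z of the same variant both exceed 3 (signed comparison by
default; an absolute-value mode is provided because effect signs depend
on arbitrary allele coding).

Variant alignment (same ids, same order, same effect alleles) is the
caller's contract; allele flips are applied upstream by sign negation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import EqtlModel, GwasSummary
from .nbglm import bh_adjust

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """GWAS z-vector does not match the model's variants."""


def twas_z(model: EqtlModel, gwas_z: np.ndarray) -> float:
    """The eQTL-weighted statistic w'z / sqrt(w' LD w).

    Returns NaN (with a log entry) when the weight quadratic form is not
    positive (w' LD w <= 1e-12); such genes are skipped downstream.
    """
    z = np.asarray(gwas_z, dtype=float)
    if z.shape != model.weights.shape:
        raise AlignmentError(
            f"gene {model.gene_id!r}: z length {z.shape} != "
            f"weights {model.weights.shape}"
        )
    denom = float(model.weights @ model.ld @ model.weights)
    if denom <= 1e-12:
        logger.warning(
            "gene %s: w'LDw <= 1e-12, statistic undefined", model.gene_id
        )
        return float("nan")
    return float(model.weights @ z) / float(np.sqrt(denom))


def reliability_filter(
    model: EqtlModel,
    gwas_z_by_variant: dict[str, float],
    z_threshold: float = 3.0,
    mode: str = "signed",
) -> bool | None:
    """Dual-Z reliability: top cis-eQTL Z and its GWAS Z both > threshold.

    The top cis-eQTL is the variant with the largest |eqtl_z|. In
    ``signed`` mode both z-scores must literally exceed the threshold; in
    ``abs`` mode |z| > threshold for both with concordant signs. Returns
    None (flagged undefined) when the model carries no eqtl_z column or
    the top variant has no GWAS z.
    """
    if model.eqtl_z is None:
        logger.debug("gene %s: no eqtl_z column; reliability undefined", model.gene_id)
        return None
    top = int(np.argmax(np.abs(model.eqtl_z)))
    ez = float(model.eqtl_z[top])
    gz = gwas_z_by_variant.get(model.variant_ids[top])
    if gz is None:
        logger.debug(
            "gene %s: top eQTL %s has no GWAS z; reliability undefined",
            model.gene_id, model.variant_ids[top],
        )
        return None
    if mode == "signed":
        return bool(ez > z_threshold and gz > z_threshold)
    if mode == "abs":
        return bool(
            abs(ez) > z_threshold
            and abs(gz) > z_threshold
            and np.sign(ez) == np.sign(gz)
        )
    raise ValueError(f"unknown reliability mode {mode!r}")


@dataclass
class TwasGroup:
    """One (tissue, trait) test group: models plus that trait's GWAS."""

    tissue: str
    trait: str
    models: list[EqtlModel]
    gwas: list[GwasSummary]


def run_targeted_twas(
    groups: list[TwasGroup],
    alpha: float = 0.05,
    z_threshold: float = 3.0,
    reliability_mode: str = "signed",
) -> pd.DataFrame:
    """TWAS over several (tissue, trait) groups with per-group BH.

    Genes whose variants are absent from the group's GWAS (or whose
    statistic is undefined) are skipped and counted in the ``skipped``
    attribute of the returned frame (``df.attrs['skipped']``).
    """
    rows = []
    skipped: list[tuple[str, str, str]] = []
    for grp in groups:
        zmap = {
            g.variant_id: g.zscore for g in grp.gwas if g.zscore is not None
        }
        group_rows = []
        for model in grp.models:
            try:
                z = np.array([zmap[v] for v in model.variant_ids], dtype=float)
            except KeyError:
                skipped.append((grp.tissue, grp.trait, model.gene_id))
                continue
            stat = twas_z(model, z)
            if not np.isfinite(stat):
                skipped.append((grp.tissue, grp.trait, model.gene_id))
                continue
            top = (
                int(np.argmax(np.abs(model.eqtl_z)))
                if model.eqtl_z is not None
                else -1
            )
            reliable = reliability_filter(
                model, zmap, z_threshold, reliability_mode
            )
            group_rows.append(
                {
                    "gene_id": model.gene_id,
                    "tissue": grp.tissue,
                    "trait": grp.trait,
                    "z_twas": stat,
                    "pvalue": float(2.0 * norm.sf(abs(stat))),
                    "top_eqtl_z": float(model.eqtl_z[top]) if top >= 0 else np.nan,
                    "top_eqtl_gwas_z": (
                        zmap.get(model.variant_ids[top], np.nan) if top >= 0 else np.nan
                    ),
                    "reliable": reliable,
                }
            )
        if not group_rows:
            continue
        gdf = pd.DataFrame(group_rows)
        gdf["padj"] = bh_adjust(gdf["pvalue"].to_numpy())
        gdf["significant"] = gdf["padj"] < alpha
        rows.append(gdf)
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "gene_id", "tissue", "trait", "z_twas", "pvalue",
                "top_eqtl_z", "top_eqtl_gwas_z", "reliable", "padj",
                "significant",
            ]
        )
    )
    out.attrs["skipped"] = skipped
    return out
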