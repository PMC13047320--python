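"""Two-factor interaction model and deviation-from-additivity synergy test.

For each gene i and sample j of one cell type the engine fits

    log q_ij = b0 + bC C_j + bT T_j + bCT C_j T_j

with C = 1 for CGA or CGA+Tau exposure and T = 1 for taurine or CGA+Tau
exposure. The interaction coefficient bCT measures the deviation of the
combined treatment from additivity; on the log2 scale it satisfies the
exact reparameterization identity

    bCT / ln2 = log2FC_combined - (log2FC_CGA + log2FC_Tau)

when all fold changes are unshrunk. A gene shows *potential* synergy when
the two-sided Wald test of H0: bCT = 0 reaches nominal p < 0.05 and the
combined (shrunk) fold change exceeds the additive sum with concordant
direction; *significant* synergy additionally requires BH-adjusted
p_interaction < 0.1 (interaction tests are under-powered at 3 replicates
per arm, hence the relaxed FDR threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nbglm
from .io_formats import CountExperiment, SampleInfo

LN2 = float(np.log(2.0))

INTERACTION_COLUMNS = ["intercept", "C", "T", "CxT"]


def build_interaction_design(samples: list[SampleInfo]) -> nbglm.DesignMatrix:
    """Design [1, C, T, C*T] for one cell type's samples.

    Requires all four conditions (otherwise the matrix is rank-deficient
    and the interaction is not identified).
    """
    present = {s.treatment for s in samples}
    missing = {"control", "CGA", "Tau", "CGA_Tau"} - present
    if missing:
        raise ValueError(
            f"interaction design needs all four conditions; missing {sorted(missing)}"
        )
    C = np.array([1.0 if s.treatment in ("CGA", "CGA_Tau") else 0.0 for s in samples])
    T = np.array([1.0 if s.treatment in ("Tau", "CGA_Tau") else 0.0 for s in samples])
    X = np.column_stack([np.ones(len(samples)), C, T, C * T])
    design = nbglm.DesignMatrix(matrix=X, columns=list(INTERACTION_COLUMNS))
    design.require_full_rank()
    return design


def additivity_deviation(
    lfc_combined: float | np.ndarray,
    lfc_cga: float | np.ndarray,
    lfc_tau: float | np.ndarray,
) -> float | np.ndarray:
    """Deviation from additivity: combined - (CGA + Tau), log2 scale."""
    return lfc_combined - (lfc_cga + lfc_tau)


def fit_interaction(
    expt: CountExperiment,
    sf: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    shrink: bool = True,
) -> pd.DataFrame:
    """Fit the interaction model for one cell type's samples.

    Returns a per-gene table with the interaction estimate on the log2
    scale (raw and, when ``shrink``, Cauchy-prior shrunk), its SE, the
    Wald p-value of H0: bCT = 0 and the BH-adjusted p across the genes of
    this cell type.
    """
    design = build_interaction_design(expt.samples)
    res = nbglm.run_de(
        expt.counts, expt.gene_ids, design, coef="CxT",
        sf=sf, alpha=alpha, shrink=shrink,
    ).table
    return res.rename(
        columns={
            "log2fc_raw": "beta_ct_log2_raw",
            "log2fc_shrunk": "beta_ct_log2",
            "se": "se_ct",
            "pvalue": "p_interaction",
            "padj": "padj_interaction",
        }
    )


def _exceeds_additive(
    lfc_combined: float, additive: float, rule: str
) -> bool:
    if rule == "mirrored":
        # excess over additivity in the direction of the (concordant) effect
        if np.sign(lfc_combined) != np.sign(additive) and additive != 0.0:
            return False
        if lfc_combined >= 0:
            return lfc_combined > additive
        return lfc_combined < additive
    if rule == "literal":
        return lfc_combined > additive
    raise ValueError(f"unknown synergy direction rule {rule!r}")


def classify_synergy(
    table: pd.DataFrame,
    alpha_nominal: float = 0.05,
    alpha_adj: float = 0.1,
    direction_rule: str = "mirrored",
) -> pd.DataFrame:
    """Flag potential / significant synergy.

    ``table`` needs columns p_interaction, padj_interaction, lfc_combined,
    lfc_cga, lfc_tau (shrunk, log2). ``direction_rule='mirrored'`` applies
    the excess-over-additivity inequality in the direction of the effect
    (for negative concordant effects the mirrored '<' inequality);
    ``'literal'`` applies the printed one-sided '>' as-is.
    """
    out = table.copy()
    additive = out["lfc_cga"] + out["lfc_tau"]
    out["additivity_deviation"] = additivity_deviation(
        out["lfc_combined"], out["lfc_cga"], out["lfc_tau"]
    )
    exceeds = np.array(
        [
            _exceeds_additive(c, a, direction_rule)
            for c, a in zip(out["lfc_combined"], additive)
        ]
    )
    out["potential_synergy"] = (
        (out["p_interaction"] < alpha_nominal).fillna(False) & exceeds
    )
    out["significant_synergy"] = out["potential_synergy"] & (
        out["padj_interaction"] < alpha_adj
    ).fillna(False)
    return out


@dataclass
class SynergyRun:
    """Joined interaction fit + marginal contrasts for one cell type."""

    table: pd.DataFrame


def run_synergy(
    expt: CountExperiment,
    de_tables: dict[str, pd.DataFrame],
    alpha_nominal: float = 0.05,
    alpha_adj: float = 0.1,
    direction_rule: str = "mirrored",
    shrink: bool = True,
    sf: np.ndarray | None = None,
    dispersion: np.ndarray | None = None,
) -> SynergyRun:
    """Full synergy analysis for one cell type.

    ``de_tables`` maps treatment -> per-contrast DE table (from
    :func:`nbglm.run_de`) supplying the shrunk marginal log2FCs used by
    the magnitude criterion; the interaction p-value comes from the
    jointly fitted four-condition model (unshrunk Wald test). When the
    marginal contrasts were fitted with a shared dispersion vector, pass
    it as ``dispersion`` (and the shared size factors as ``sf``): the
    unshrunk estimates then satisfy the reparameterization identity
    beta_ct_log2 = lfc_combined - lfc_cga - lfc_tau exactly.
    """
    inter = fit_interaction(expt, sf=sf, alpha=dispersion, shrink=shrink)
    merged = inter.merge(
        de_tables["CGA_Tau"][["gene_id", "log2fc_shrunk"]].rename(
            columns={"log2fc_shrunk": "lfc_combined"}
        ),
        on="gene_id",
    ).merge(
        de_tables["CGA"][["gene_id", "log2fc_shrunk"]].rename(
            columns={"log2fc_shrunk": "lfc_cga"}
        ),
        on="gene_id",
    ).merge(
        de_tables["Tau"][["gene_id", "log2fc_shrunk"]].rename(
            columns={"log2fc_shrunk": "lfc_tau"}
        ),
        on="gene_id",
    )
    return SynergyRun(
        table=classify_synergy(merged, alpha_nominal, alpha_adj, direction_rule)
    )
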