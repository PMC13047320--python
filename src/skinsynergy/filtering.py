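"""Gene-level QC: biotype exclusion, minimum-count filter, and the
leave-one-out within-group heterogeneity filter.

The within-group filter runs, for every (cell type x treatment) group, a
one-vs-rest NB differential-expression contrast for each sample of the
group; genes called DE in any such comparison (BH-adjusted p below alpha
and |shrunk log2FC| above the suggestive threshold) are treated as
replicate-heterogeneity outliers and removed for that cell type.
Filter stages attribute exclusions disjointly in the fixed order
biotype -> min-count -> within-group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nbglm
from .io_formats import CountExperiment, GeneAnnotation

#: GENCODE biotypes excluded by default: pseudogenes, spike-ins,
#: unconfirmed (TEC) and artifactual annotation classes.
DEFAULT_EXCLUDE_BIOTYPES = frozenset(
    {
        "pseudogene",
        "processed_pseudogene",
        "unprocessed_pseudogene",
        "transcribed_processed_pseudogene",
        "transcribed_unprocessed_pseudogene",
        "unitary_pseudogene",
        "polymorphic_pseudogene",
        "IG_pseudogene",
        "TR_pseudogene",
        "rRNA_pseudogene",
        "TEC",
        "artifact",
        "spike_in",
    }
)


@dataclass
class FilterReport:
    """Per-stage exclusions; stages are disjoint and ordered."""

    excluded_biotype: list[str] = field(default_factory=list)
    excluded_min_count: dict[str, list[str]] = field(default_factory=dict)
    excluded_within_group: dict[str, list[str]] = field(default_factory=dict)
    surviving: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "excluded_biotype": sorted(self.excluded_biotype),
            "excluded_min_count": {
                k: sorted(v) for k, v in self.excluded_min_count.items()
            },
            "excluded_within_group": {
                k: sorted(v) for k, v in self.excluded_within_group.items()
            },
            "surviving": self.surviving,
        }


def filter_biotype(
    annotation: dict[str, GeneAnnotation],
    gene_ids: list[str],
    exclude_biotypes: frozenset[str] | set[str] = DEFAULT_EXCLUDE_BIOTYPES,
) -> np.ndarray:
    """Keep-mask over ``gene_ids``: True iff biotype not excluded."""
    return np.array(
        [annotation[g].biotype not in exclude_biotypes for g in gene_ids],
        dtype=bool,
    )


def filter_min_count(counts: np.ndarray, min_count: int = 10) -> np.ndarray:
    """Keep-mask: gene kept iff every sample count >= min_count.

    ``counts`` must already be restricted to one cell type's samples
    ("read counts less than ten in at least one sample" excludes).
    """
    return np.all(np.asarray(counts) >= min_count, axis=1)


def within_group_deg_filter(
    expt: CountExperiment,
    lfc_thresh: float = 0.585,
    alpha: float = 0.05,
    shared_dispersion: float | None = None,
) -> dict[str, set[str]]:
    """Leave-one-out heterogeneity filter, per cell type.

    For every (cell type x treatment) group, each sample is contrasted
    against the remaining samples of the same group with the NB engine; a
    gene is a within-group DEG if any comparison gives BH-adjusted
    p < ``alpha`` and |shrunk log2FC| > ``lfc_thresh``. The union over all
    groups of one cell type is that cell type's exclusion set.

    Dispersion is shared across genes of the cell type (a single scalar,
    the median of gene-wise estimates from the full factorial design)
    because per-gene estimates from 3-replicate groups are unstable;
    ``shared_dispersion`` overrides the estimate.
    """
    excluded: dict[str, set[str]] = {}
    for ct in expt.cell_types:
        sub = expt.for_cell_type(ct)
        sf_all = nbglm.size_factors(sub.counts)
        if shared_dispersion is None:
            design = _factorial_or_group_design(sub)
            disp, _ = nbglm.estimate_dispersion(sub.counts, design, sf_all)
            shared = float(np.median(disp))
        else:
            shared = float(shared_dispersion)
        bad: set[str] = set()
        treatments = sorted({s.treatment for s in sub.samples})
        for trt in treatments:
            idx = [i for i, s in enumerate(sub.samples) if s.treatment == trt]
            if len(idx) < 3:
                raise ValueError(
                    f"group ({ct}, {trt}) has {len(idx)} samples; "
                    "the leave-one-out contrast needs >= 3"
                )
            counts = sub.counts[:, idx]
            sf = sf_all[idx]
            for pos in range(len(idx)):
                indicator = np.zeros(len(idx))
                indicator[pos] = 1.0
                design = nbglm.two_group_design(indicator)
                res = nbglm.run_de(
                    counts, sub.gene_ids, design, coef="group",
                    sf=sf, alpha=np.full(sub.n_genes, shared),
                ).table
                hit = (res["padj"] < alpha) & (
                    res["log2fc_shrunk"].abs() > lfc_thresh
                )
                bad.update(res.loc[hit.fillna(False), "gene_id"])
        excluded[ct] = bad
    return excluded


def _factorial_or_group_design(expt: CountExperiment) -> nbglm.DesignMatrix:
    """One-hot treatment design (reference = first level) for dispersion
    estimation over a single cell type."""
    treatments = sorted({s.treatment for s in expt.samples})
    cols = [np.ones(expt.n_samples)]
    names = ["intercept"]
    for trt in treatments[1:]:
        cols.append(
            np.array([1.0 if s.treatment == trt else 0.0 for s in expt.samples])
        )
        names.append(f"treatment_{trt}")
    return nbglm.DesignMatrix(matrix=np.column_stack(cols), columns=names)


def apply_qc(
    expt: CountExperiment,
    annotation: dict[str, GeneAnnotation],
    exclude_biotypes: frozenset[str] | set[str] = DEFAULT_EXCLUDE_BIOTYPES,
    min_count: int = 10,
    lfc_thresh: float = 0.585,
    alpha: float = 0.05,
    run_within_group: bool = True,
) -> tuple[dict[str, CountExperiment], FilterReport]:
    """Run the full QC cascade and return per-cell-type experiments.

    The min-count and within-group stages are cell-type specific, so the
    result is one filtered experiment per cell type.
    """
    report = FilterReport()
    keep_bio = filter_biotype(annotation, expt.gene_ids, exclude_biotypes)
    report.excluded_biotype = [
        g for g, k in zip(expt.gene_ids, keep_bio) if not k
    ]
    base = expt.subset_genes(keep_bio)
    out: dict[str, CountExperiment] = {}
    for ct in expt.cell_types:
        sub = base.for_cell_type(ct)
        keep_mc = filter_min_count(sub.counts, min_count)
        report.excluded_min_count[ct] = [
            g for g, k in zip(sub.gene_ids, keep_mc) if not k
        ]
        sub = sub.subset_genes(keep_mc)
        if run_within_group:
            excl = within_group_deg_filter(sub, lfc_thresh, alpha)[ct]
        else:
            excl = set()
        report.excluded_within_group[ct] = sorted(excl)
        keep = np.array([g not in excl for g in sub.gene_ids], dtype=bool)
        sub = sub.subset_genes(keep)
        report.surviving[ct] = sub.n_genes
        out[ct] = sub
    return out, report
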