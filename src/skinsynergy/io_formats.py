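"""Readers, writers and validated in-memory containers for every table the
pipeline touches.

All genomic coordinates are 1-based inclusive (GTF convention). Counts
arrive either as a TSV (first column ``gene_id``, one column per sample) or
as a MatrixMarket triplet with ``.rows``/``.cols`` sidecar name files.
Every reader validates its input before any computation module runs
(fail-fast contract) and raises :class:`ValidationError` naming the
offending record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

#: Treatment arms of the two-compound factorial design.
TREATMENTS = ("control", "CGA", "Tau", "CGA_Tau")

#: Cell types of the reference design (extensible: validation only checks
#: that all samples of one experiment use a consistent label set).
DEFAULT_CELL_TYPES = ("keratinocyte", "melanocyte", "fibroblast")


class ValidationError(ValueError):
    """An input table violated one of its declared invariants."""


@dataclass(frozen=True)
class SampleInfo:
    """One RNA-seq sample: cell type x treatment x replicate."""

    sample_id: str
    cell_type: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: treatment {self.treatment!r} "
                f"not in {TREATMENTS}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )


@dataclass
class CountExperiment:
    """Gene x sample count matrix plus sample metadata.

    Invariants: counts are non-negative integers, gene ids are unique and
    the number of columns equals the number of samples.
    """

    counts: np.ndarray
    gene_ids: list[str]
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample column {bad[1]}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            g = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g[0]]!r}, "
                f"sample column {g[1]}"
            )
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValidationError("gene_ids length does not match counts rows")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            for gid in self.gene_ids:
                if gid in seen:
                    raise ValidationError(f"duplicate gene_id {gid!r}")
                seen.add(gid)
        if len(self.samples) != self.counts.shape[1]:
            raise ValidationError(
                f"{self.counts.shape[1]} count columns but "
                f"{len(self.samples)} design records"
            )
        keys = [(s.cell_type, s.treatment, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValidationError(
                "(cell_type, treatment, replicate) not unique across samples"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_types(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.cell_type not in out:
                out.append(s.cell_type)
        return out

    def subset_samples(self, mask: Sequence[bool]) -> "CountExperiment":
        mask = np.asarray(mask, dtype=bool)
        return CountExperiment(
            counts=self.counts[:, mask],
            gene_ids=list(self.gene_ids),
            samples=[s for s, m in zip(self.samples, mask) if m],
        )

    def subset_genes(self, mask: Sequence[bool]) -> "CountExperiment":
        mask = np.asarray(mask, dtype=bool)
        return CountExperiment(
            counts=self.counts[mask, :],
            gene_ids=[g for g, m in zip(self.gene_ids, mask) if m],
            samples=list(self.samples),
        )

    def for_cell_type(self, cell_type: str) -> "CountExperiment":
        return self.subset_samples(
            [s.cell_type == cell_type for s in self.samples]
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene coordinates and biotype, 1-based inclusive span."""

    gene_id: str
    symbol: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if not self.biotype:
            raise ValidationError(f"gene {self.gene_id!r}: empty biotype")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-'"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end of the span given the strand."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GwasSummary:
    """One GWAS summary-statistics record (1-based position)."""

    variant_id: str
    chrom: str
    pos: int
    pvalue: float
    zscore: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(
                f"variant {self.variant_id!r}: pvalue {self.pvalue} "
                "outside (0, 1]"
            )
        if self.zscore is not None and np.isfinite(self.zscore):
            # per-record two-sided consistency p ~ 2*Phi(-|z|)
            from scipy.stats import norm

            implied = 2.0 * norm.sf(abs(self.zscore))
            if implied > 0 and abs(np.log10(implied) - np.log10(self.pvalue)) > 0.5:
                raise ValidationError(
                    f"variant {self.variant_id!r}: pvalue {self.pvalue:.3g} "
                    f"inconsistent with zscore {self.zscore:.3g} "
                    f"(implies p={implied:.3g})"
                )


@dataclass
class EqtlModel:
    """Per-gene eQTL weights with an LD matrix for the TWAS statistic."""

    gene_id: str
    variant_ids: list[str]
    weights: np.ndarray
    ld: np.ndarray
    eqtl_z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.ld = np.asarray(self.ld, dtype=float)
        k = len(self.variant_ids)
        if self.weights.shape != (k,):
            raise ValidationError(
                f"gene {self.gene_id!r}: weights length != n variants"
            )
        if self.ld.shape != (k, k):
            raise ValidationError(f"gene {self.gene_id!r}: LD shape != (k, k)")
        if not np.allclose(self.ld, self.ld.T, atol=1e-8):
            raise ValidationError(f"gene {self.gene_id!r}: LD not symmetric")
        if not np.allclose(np.diag(self.ld), 1.0, atol=1e-8):
            raise ValidationError(
                f"gene {self.gene_id!r}: LD diagonal not unit"
            )
        if not np.any(self.weights != 0):
            raise ValidationError(f"gene {self.gene_id!r}: all weights zero")
        if self.eqtl_z is not None:
            self.eqtl_z = np.asarray(self.eqtl_z, dtype=float)
            if self.eqtl_z.shape != (k,):
                raise ValidationError(
                    f"gene {self.gene_id!r}: eqtl_z length != n variants"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets from one source (e.g. KEGG, GO:BP)."""

    source: str
    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"term {term_id!r}: empty member list")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers


def _read_design(design_path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(design_path, sep="\t", dtype=str)
    required = {"sample_id", "cell_type", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"design file missing columns {sorted(missing)}")
    return [
        SampleInfo(
            sample_id=row.sample_id,
            cell_type=row.cell_type,
            treatment=row.treatment,
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def read_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a pre-tabulated (GTF-derived) gene annotation TSV.

    Columns: gene_id, symbol, biotype, chrom, start, end, strand with
    1-based inclusive coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples():
        if row.gene_id in out:
            raise ValidationError(f"duplicate gene_id {row.gene_id!r} in annotation")
        out[row.gene_id] = GeneAnnotation(
            gene_id=row.gene_id,
            symbol=row.symbol,
            biotype=row.biotype,
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
        )
    return out


def read_counts(
    path: str | Path,
    design_path: str | Path,
    annotation_path: str | Path | None = None,
) -> tuple[CountExperiment, dict[str, GeneAnnotation] | None]:
    """Read a counts table (TSV or MatrixMarket) plus its design table.

    The returned sample order matches the design file order. With a
    MatrixMarket file, ``path`` names the ``.mtx`` and sidecar files
    ``<stem>.rows`` / ``<stem>.cols`` supply gene and sample names.
    """
    samples = _read_design(design_path)
    path = Path(path)
    if path.suffix == ".mtx":
        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
        gene_ids = path.with_suffix(".rows").read_text().split()
        col_ids = path.with_suffix(".cols").read_text().split()
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = [str(g) for g in df.index]
        col_ids = [str(c) for c in df.columns]
        mat = df.to_numpy()
    design_ids = [s.sample_id for s in samples]
    unknown = set(col_ids) - set(design_ids)
    if unknown:
        raise ValidationError(
            f"samples in counts header absent from design: {sorted(unknown)}"
        )
    missing = set(design_ids) - set(col_ids)
    if missing:
        raise ValidationError(
            f"design samples absent from counts: {sorted(missing)}"
        )
    order = [col_ids.index(sid) for sid in design_ids]
    expt = CountExperiment(counts=mat[:, order], gene_ids=gene_ids, samples=samples)
    ann = read_annotation(annotation_path) if annotation_path else None
    if ann is not None:
        # annotation may cover a superset of the counted genes
        absent = [g for g in gene_ids if g not in ann]
        if absent:
            raise ValidationError(
                f"{len(absent)} counted genes missing from annotation, "
                f"first: {absent[0]!r}"
            )
    return expt, ann


def write_counts(expt: CountExperiment, path: str | Path) -> None:
    df = pd.DataFrame(
        expt.counts, index=pd.Index(expt.gene_ids, name="gene_id"),
        columns=expt.sample_ids,
    )
    df.to_csv(path, sep="\t")


def write_design(samples: Iterable[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "cell_type": s.cell_type,
                "treatment": s.treatment,
                "replicate": s.replicate,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def write_annotation(ann: Mapping[str, GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "symbol": a.symbol,
                "biotype": a.biotype,
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "strand": a.strand,
            }
            for a in ann.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file: term_id TAB description TAB member..."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path.name}:{lineno}: GMT line has {len(fields)} fields, "
                "need >= 3 (term, description, members...)"
            )
        term_id, desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise ValidationError(f"{path.name}:{lineno}: set {term_id!r} empty")
        if term_id in sets:
            raise ValidationError(
                f"{path.name}:{lineno}: duplicate term_id {term_id!r}"
            )
        if len(set(members)) != len(members):
            logger.warning(
                "GMT set %s: duplicate members deduplicated", term_id
            )
        sets[term_id] = (desc, frozenset(members))
    return GeneSetCollection(source=source or path.stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([term_id, desc, *sorted(members)])
        for term_id, (desc, members) in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gwas(path: str | Path) -> list[GwasSummary]:
    """Read GWAS summary statistics: variant_id, chrom, pos, pvalue[, zscore]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"variant_id", "chrom", "pos", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"GWAS file missing columns {sorted(missing)}")
    has_z = "zscore" in df.columns
    out = []
    for row in df.itertuples():
        z = float(row.zscore) if has_z and pd.notna(row.zscore) else None
        out.append(
            GwasSummary(
                variant_id=row.variant_id,
                chrom=str(row.chrom),
                pos=int(row.pos),
                pvalue=float(row.pvalue),
                zscore=z,
            )
        )
    return out


def write_gwas(records: Iterable[GwasSummary], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "pvalue": r.pvalue,
                "zscore": "" if r.zscore is None else r.zscore,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_eqtl_model(weights_path: str | Path, ld_path: str | Path) -> EqtlModel:
    """Read one gene's eQTL model: a weights TSV and a dense-text LD matrix.

    Weights TSV columns: gene_id, variant_id, weight[, eqtl_z]; the LD file
    is whitespace-separated dense text, k x k, variant order matching the
    weights file.
    """
    df = pd.read_csv(weights_path, sep="\t")
    gene_ids = df["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ValidationError(
            f"{weights_path}: expected one gene per model file, got {len(gene_ids)}"
        )
    ld = np.loadtxt(ld_path, ndmin=2)
    return EqtlModel(
        gene_id=str(gene_ids[0]),
        variant_ids=[str(v) for v in df["variant_id"]],
        weights=df["weight"].to_numpy(dtype=float),
        ld=ld,
        eqtl_z=df["eqtl_z"].to_numpy(dtype=float) if "eqtl_z" in df.columns else None,
    )


def write_eqtl_model(model: EqtlModel, weights_path: str | Path, ld_path: str | Path) -> None:
    data = {
        "gene_id": [model.gene_id] * len(model.variant_ids),
        "variant_id": model.variant_ids,
        "weight": model.weights,
    }
    if model.eqtl_z is not None:
        data["eqtl_z"] = model.eqtl_z
    pd.DataFrame(data).to_csv(weights_path, sep="\t", index=False, float_format="%.17g")
    np.savetxt(ld_path, model.ld, fmt="%.17g")


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
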