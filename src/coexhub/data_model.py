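"""Domain types and tabular I/O for the target-enrichment pipeline.

The pipeline's primary input is a raw gene x sample count matrix with a
separate sample-metadata table, plus a per-gene annotation table carrying a
secretion score in [0, 1] (signal-peptide prediction confidence), a KOG
functional category and a free-text domain note.  All files are
tab-separated UTF-8 text with a header line.

Gene identifiers are opaque strings (JGI-style numeric protein IDs are
common) and every tie-break in the package compares them lexicographically
as text, which keeps results deterministic and locale-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("treatment", "control")

#: Default KOG focus categories for the radar-style DEG summaries.  KOG
#: nomenclature varies between annotation dumps, so these are configurable.
DEFAULT_KOG_FOCUS = (
    "signal transduction mechanisms",
    "carbohydrate transport and metabolism",
    "secondary metabolites biosynthesis/transport/catabolism",
    "defense mechanisms",
    "lipid transport and metabolism",
    "energy production and conversion",
    "general function prediction only",
    "function unknown",
)


class DataModelError(ValueError):
    """Raised for malformed inputs (bad counts, scores, metadata)."""


@dataclass(frozen=True)
class SampleInfo:
    """Design metadata for one RNA-seq library.

    ``condition`` distinguishes the biological contrast of interest
    (``treatment`` = fungus interacting with the plant host, ``control`` =
    fungus cultivated alone); ``strain`` holds the genotype (e.g. ``WT``,
    ``dSm1``, ``dSir1``); ``timepoint_h`` is hours post inoculation.
    """

    sample_id: str
    condition: str
    strain: str
    timepoint_h: float
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DataModelError(
                f"sample {self.sample_id!r}: condition must be one of "
                f"{CONDITIONS}, got {self.condition!r}"
            )
        if self.timepoint_h < 0:
            raise DataModelError(
                f"sample {self.sample_id!r}: timepoint_h must be >= 0"
            )
        if self.replicate < 1:
            raise DataModelError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


@dataclass
class CountMatrix:
    """Raw integer counts, genes x samples, with sample design metadata.

    ``counts`` is an int64 array of shape ``(len(gene_ids), len(samples))``.
    """

    gene_ids: list[str]
    samples: list[SampleInfo]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise DataModelError(f"duplicate gene ID {g!r}")
                seen.add(g)
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise DataModelError("duplicate sample IDs in metadata")
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.gene_ids), len(self.samples)):
            raise DataModelError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0):
                i, j = np.argwhere(frac != 0)[0]
                raise DataModelError(
                    f"non-integer count at gene {self.gene_ids[i]!r}, "
                    f"sample {self.samples[j].sample_id!r}"
                )
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise DataModelError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.samples[j].sample_id!r}"
            )
        self.counts = arr.astype(np.int64)

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, keep: Iterable[str]) -> "CountMatrix":
        keep = list(keep)
        idx = {s.sample_id: i for i, s in enumerate(self.samples)}
        missing = [k for k in keep if k not in idx]
        if missing:
            raise DataModelError(f"unknown sample IDs: {missing}")
        cols = [idx[k] for k in keep]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            samples=[self.samples[c] for c in cols],
            counts=self.counts[:, cols],
        )

    def subset_genes(self, keep: Iterable[str]) -> "CountMatrix":
        keep = list(keep)
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [k for k in keep if k not in idx]
        if missing:
            raise DataModelError(f"unknown gene IDs: {missing}")
        rows = [idx[k] for k in keep]
        return CountMatrix(
            gene_ids=keep,
            samples=list(self.samples),
            counts=self.counts[rows, :],
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene functional annotation.

    ``secretion_score`` is a signal-peptide prediction confidence in
    [0, 1]; ``is_sscp`` flags small secreted cysteine-rich proteins, a
    class enriched among fungal effectors and elicitors.
    """

    gene_id: str
    secretion_score: float = 0.0
    kog_category: str = "unassigned"
    domain_note: str = ""
    is_sscp: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.secretion_score <= 1.0):
            raise DataModelError(
                f"gene {self.gene_id!r}: secretion_score "
                f"{self.secretion_score} outside [0, 1]"
            )


@dataclass
class PipelineConfig:
    """All numeric settings of the pipeline in one place.

    Defaults follow the published analysis where it states a value
    (signal-peptide cutoff 0.5 inclusive; DEG thresholds |log2FC| > 1.5
    strictly and FDR < 0.05 strictly; top 3 principal components; heatmap
    clip at +/-12.5 log2 fold change) and documented choices elsewhere.
    """

    signalp_threshold: float = 0.5
    lfc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    n_components: int = 3
    dbscan_eps: float = 0.6
    dbscan_min_samples: int = 5
    network_methods: tuple[str, ...] = ("pearson", "spearman", "mutual_information")
    edge_threshold_per_method: dict = field(
        default_factory=lambda: {
            "pearson": 0.70,
            "spearman": 0.70,
            "mutual_information": 0.30,
        }
    )
    consensus_min_support: int = 2
    heatmap_clip: float = 12.5
    kog_focus_categories: tuple[str, ...] = DEFAULT_KOG_FOCUS
    prior_count: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("signalp_threshold", "lfc_threshold", "fdr_threshold",
                     "dbscan_eps", "heatmap_clip"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DataModelError(f"{name} must be finite, got {v}")
        if self.n_components < 1:
            raise DataModelError("n_components must be >= 1")
        if self.dbscan_eps <= 0:
            raise DataModelError("dbscan_eps must be > 0")
        if self.dbscan_min_samples < 1:
            raise DataModelError("dbscan_min_samples must be >= 1")
        known = {"pearson", "spearman", "mutual_information"}
        bad = set(self.network_methods) - known
        if bad:
            raise DataModelError(f"unknown network methods: {sorted(bad)}")
        if not (1 <= self.consensus_min_support <= len(self.network_methods)):
            raise DataModelError(
                "consensus_min_support must lie in [1, number of methods]"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "network_methods" in d:
            d["network_methods"] = tuple(d["network_methods"])
        if "kog_focus_categories" in d:
            d["kog_focus_categories"] = tuple(d["kog_focus_categories"])
        return cls(**d)

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# -- counts I/O ---------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "condition", "strain", "timepoint_h", "replicate"]


def read_counts(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column gene IDs) plus a metadata TSV.

    Sample order follows the metadata file.  Every counts column must be
    described in the metadata; duplicate gene IDs, negative or non-integer
    counts are hard errors naming the offending cell.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "strain": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise DataModelError(f"metadata missing columns: {missing_cols}")
    samples = [
        SampleInfo(
            sample_id=str(r.sample_id),
            condition=str(r.condition),
            strain=str(r.strain),
            timepoint_h=float(r.timepoint_h),
            replicate=int(r.replicate),
        )
        for r in meta.itertuples()
    ]

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    meta_ids = [s.sample_id for s in samples]
    extra = [c for c in df.columns if c not in set(meta_ids)]
    if extra:
        raise DataModelError(f"samples in counts absent from metadata: {extra}")
    absent = [m for m in meta_ids if m not in set(df.columns)]
    if absent:
        raise DataModelError(f"samples in metadata absent from counts: {absent}")
    df = df[meta_ids]
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataModelError(f"duplicate gene ID {dup!r}")
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise DataModelError("counts table contains non-numeric entries")
    return CountMatrix(gene_ids=list(df.index), samples=samples, counts=values)


def write_counts(cm: CountMatrix, path: str | Path, metadata_path: str | Path) -> None:
    """Write counts and metadata TSVs (inverse of :func:`read_counts`)."""
    df = cm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "strain": s.strain,
                "timepoint_h": s.timepoint_h,
                "replicate": s.replicate,
            }
            for s in cm.samples
        ],
        columns=METADATA_COLUMNS,
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# -- annotation I/O -----------------------------------------------------------

ANNOTATION_COLUMNS = ["gene_id", "secretion_score", "kog_category", "domain_note"]


def read_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a gene annotation TSV into a gene_id -> record mapping.

    A missing secretion score falls back to 0.0 with a logged warning; a
    missing KOG category becomes "unassigned".  Scores outside [0, 1] are
    hard errors.  An optional ``is_sscp`` column (0/1 or true/false) is
    honoured.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing_cols = [c for c in ("gene_id",) if c not in df.columns]
    if missing_cols:
        raise DataModelError(f"annotation missing columns: {missing_cols}")
    out: dict[str, GeneAnnotation] = {}
    for r in df.itertuples():
        gid = str(r.gene_id)
        score = getattr(r, "secretion_score", np.nan)
        if score is None or (isinstance(score, float) and np.isnan(score)):
            logger.warning("gene %s: missing secretion_score, using 0.0", gid)
            score = 0.0
        kog = getattr(r, "kog_category", None)
        if kog is None or (isinstance(kog, float) and np.isnan(kog)):
            kog = "unassigned"
        note = getattr(r, "domain_note", "")
        if note is None or (isinstance(note, float) and np.isnan(note)):
            note = ""
        sscp = getattr(r, "is_sscp", False)
        if isinstance(sscp, str):
            sscp = sscp.strip().lower() in ("1", "true", "yes")
        elif isinstance(sscp, float) and np.isnan(sscp):
            sscp = False
        if gid in out:
            raise DataModelError(f"duplicate gene ID {gid!r} in annotation")
        out[gid] = GeneAnnotation(
            gene_id=gid,
            secretion_score=float(score),
            kog_category=str(kog),
            domain_note=str(note),
            is_sscp=bool(sscp),
        )
    return out


def write_annotation(ann: dict[str, GeneAnnotation] | Sequence[GeneAnnotation],
                     path: str | Path) -> None:
    records = list(ann.values()) if isinstance(ann, dict) else list(ann)
    df = pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "secretion_score": a.secretion_score,
                "kog_category": a.kog_category,
                "domain_note": a.domain_note,
                "is_sscp": int(a.is_sscp),
            }
            for a in records
        ],
        columns=ANNOTATION_COLUMNS + ["is_sscp"],
    )
    df.to_csv(path, sep="\t", index=False)
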