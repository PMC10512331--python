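"""Secretion filtering of DEGs and KOG-category summaries.

After differential-expression calling, candidate genes are restricted to
the predicted secretome: a gene is kept when its signal-peptide score is
at or above the cutoff (0.5 by default, boundary inclusive).  The
retained DEGs are then summarized per KOG functional category and
timepoint (the radar-plot counts) and as a clipped log2-fold-change
matrix with per-cell significance flags (the heatmap).  Significance is
always judged on the unclipped fold change; clipping only caps the color
scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coexhub.data_model import (
    DEFAULT_KOG_FOCUS,
    DataModelError,
    GeneAnnotation,
    PipelineConfig,
)


@dataclass
class KogSummary:
    """Up/down DEG counts per (KOG category, timepoint)."""

    counts: pd.DataFrame  # columns: kog_category, timepoint_h, n_up, n_down

    def cell(self, category: str, timepoint_h: float, direction: str) -> int:
        m = self.counts[(self.counts.kog_category == category)
                        & (self.counts.timepoint_h == timepoint_h)]
        if m.empty:
            return 0
        return int(m[f"n_{direction}"].iloc[0])

    def write(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


@dataclass
class HeatmapMatrix:
    """Clipped log2FC values (genes x timepoints) plus significance flags."""

    values: pd.DataFrame
    significant: pd.DataFrame
    clip: float

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def _score_of(gene_id: str, annotation: Mapping[str, GeneAnnotation]) -> float:
    ann = annotation.get(gene_id)
    return ann.secretion_score if ann is not None else 0.0


def filter_secreted(degs: pd.DataFrame, annotation: Mapping[str, GeneAnnotation],
                    threshold: float = 0.5) -> pd.DataFrame:
    """Keep DEG rows whose gene has secretion score >= threshold.

    The boundary is inclusive ("0.5 or higher").  Genes without an
    annotation record count as score 0.
    """
    if degs.empty:
        return degs.copy()
    keep = degs["gene_id"].map(lambda g: _score_of(str(g), annotation) >= threshold)
    return degs[keep].reset_index(drop=True)


def kog_radar_counts(secreted_degs: pd.DataFrame,
                     annotation: Mapping[str, GeneAnnotation],
                     focus_categories: Sequence[str] = DEFAULT_KOG_FOCUS,
                     ) -> KogSummary:
    """Count up/down-called secreted DEGs per focus category and timepoint.

    A gene differentially expressed at several timepoints contributes to
    each of them independently.  Genes annotated outside the focus
    categories (including "unassigned") appear in no cell.  Focus names
    not found in the known vocabulary (default focus set plus every
    category present in the annotation) are hard errors.
    """
    vocab = set(DEFAULT_KOG_FOCUS) | {a.kog_category for a in annotation.values()}
    unknown = [c for c in focus_categories if c not in vocab]
    if unknown:
        raise DataModelError(f"unknown KOG focus categories: {unknown}")

    called = secreted_degs[secreted_degs["call"].isin(["up", "down"])]
    tps = sorted(pd.unique(secreted_degs["timepoint_h"])) if not secreted_degs.empty else []
    rows = []
    for cat in focus_categories:
        genes_in_cat = {g for g, a in annotation.items() if a.kog_category == cat}
        for tp in tps:
            sub = called[(called["timepoint_h"] == tp)
                         & called["gene_id"].isin(genes_in_cat)]
            rows.append({
                "kog_category": cat,
                "timepoint_h": tp,
                "n_up": int((sub["call"] == "up").sum()),
                "n_down": int((sub["call"] == "down").sum()),
            })
    return KogSummary(counts=pd.DataFrame(
        rows, columns=["kog_category", "timepoint_h", "n_up", "n_down"]))


def heatmap_matrix(de_all_timepoints: pd.DataFrame, gene_subset: Sequence[str],
                   config: PipelineConfig | None = None) -> HeatmapMatrix:
    """Genes x timepoints matrix of clipped log2 fold changes.

    Values are clipped to [-clip, +clip] for display; the significance
    flag is true iff the unclipped |log2FC| exceeds the fold-change
    threshold and q is below the FDR threshold (both strict).  Every gene
    in the subset must have a DE row at every timepoint.
    """
    config = config or PipelineConfig()
    genes = [str(g) for g in gene_subset]
    tps = sorted(pd.unique(de_all_timepoints["timepoint_h"]))
    de = de_all_timepoints.set_index(["gene_id", "timepoint_h"])
    vals = pd.DataFrame(index=genes, columns=tps, dtype=float)
    sig = pd.DataFrame(False, index=genes, columns=tps)
    for g in genes:
        for tp in tps:
            try:
                row = de.loc[(g, tp)]
            except KeyError:
                raise DataModelError(
                    f"gene {g!r} has no DE result at timepoint {tp}"
                ) from None
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            lfc = float(row["log2fc"])
            vals.loc[g, tp] = float(np.clip(lfc, -config.heatmap_clip,
                                            config.heatmap_clip))
            sig.loc[g, tp] = bool(abs(lfc) > config.lfc_threshold
                                  and row["qvalue"] < config.fdr_threshold)
    return HeatmapMatrix(values=vals, significant=sig, clip=config.heatmap_clip)
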