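"""Unique/shared DEG set algebra between two strain contrasts.

Given differential-expression tables for two mutant-vs-wild-type
contrasts at the same timepoint, the comparison is the standard two-set
Venn decomposition per direction: genes called only in A, only in B, or
in both.  "Unique" is always per direction — a gene up in A and down in B
is unique to A's up set and unique to B's down set.  Unique genes are
then tabulated per KOG category, with a drill-down listing the genes of
one category together with their free-text domain notes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from coexhub.data_model import DataModelError, GeneAnnotation

DIRECTIONS = ("up", "down")


@dataclass
class ContrastComparison:
    """Venn decomposition of two called DEG tables at one timepoint."""

    name_a: str
    name_b: str
    timepoint_h: float
    unique_to_a: dict[str, set[str]]  # direction -> genes
    unique_to_b: dict[str, set[str]]
    shared: dict[str, set[str]]

    def summary_counts(self) -> pd.DataFrame:
        rows = [
            {"direction": d,
             "unique_to_a": len(self.unique_to_a[d]),
             "unique_to_b": len(self.unique_to_b[d]),
             "shared": len(self.shared[d])}
            for d in DIRECTIONS
        ]
        return pd.DataFrame(rows, columns=["direction", "unique_to_a",
                                           "unique_to_b", "shared"])


def _called_set(de: pd.DataFrame, direction: str) -> set[str]:
    return set(de.loc[de["call"] == direction, "gene_id"].astype(str))


def compare_contrasts(de_a: pd.DataFrame, de_b: pd.DataFrame,
                      timepoint_h: float,
                      name_a: str = "A", name_b: str = "B") -> ContrastComparison:
    """Two-set Venn decomposition of called DEGs, per direction.

    Both tables must contain rows for the requested timepoint (a
    mismatched timepoint is a hard error).
    """
    sub_a = de_a[de_a["timepoint_h"] == timepoint_h]
    sub_b = de_b[de_b["timepoint_h"] == timepoint_h]
    if sub_a.empty or sub_b.empty:
        raise DataModelError(
            f"both DE tables must cover timepoint {timepoint_h}"
        )
    uniq_a, uniq_b, shared = {}, {}, {}
    for d in DIRECTIONS:
        a, b = _called_set(sub_a, d), _called_set(sub_b, d)
        uniq_a[d] = a - b
        uniq_b[d] = b - a
        shared[d] = a & b
    return ContrastComparison(name_a=name_a, name_b=name_b,
                              timepoint_h=timepoint_h,
                              unique_to_a=uniq_a, unique_to_b=uniq_b,
                              shared=shared)


def tabulate_unique_by_category(comp: ContrastComparison,
                                annotation: Mapping[str, GeneAnnotation],
                                category: str | None = None) -> pd.DataFrame:
    """Count unique genes per (KOG category, strain, direction).

    Genes without an annotation record fall into "unassigned".  With
    ``category`` given, returns the drill-down instead: one row per unique
    gene of that category with its domain note.
    """
    def cat_of(g: str) -> str:
        a = annotation.get(g)
        return a.kog_category if a is not None else "unassigned"

    def note_of(g: str) -> str:
        a = annotation.get(g)
        return a.domain_note if a is not None else ""

    sides = [(comp.name_a, comp.unique_to_a), (comp.name_b, comp.unique_to_b)]
    if category is not None:
        rows = [
            {"strain": name, "direction": d, "gene_id": g,
             "domain_note": note_of(g)}
            for name, uniq in sides
            for d in DIRECTIONS
            for g in sorted(uniq[d])
            if cat_of(g) == category
        ]
        return pd.DataFrame(rows, columns=["strain", "direction", "gene_id",
                                           "domain_note"])

    rows = []
    cats = sorted({cat_of(g) for _, uniq in sides
                   for d in DIRECTIONS for g in uniq[d]})
    for cat in cats:
        for name, uniq in sides:
            for d in DIRECTIONS:
                n = sum(1 for g in uniq[d] if cat_of(g) == cat)
                rows.append({"kog_category": cat, "strain": name,
                             "direction": d, "n_genes": n})
    return pd.DataFrame(rows, columns=["kog_category", "strain",
                                       "direction", "n_genes"])
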