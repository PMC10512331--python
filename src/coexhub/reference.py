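"""Packaged reference data.

``enriched_targets.tsv`` is the published list of enriched targets
selected by the PCA / DBSCAN / centrality pipeline on the original
colonization time course (JGI protein IDs with their reported domain
annotations).  The ``is_sscp`` flag marks the targets reported as small
secreted cysteine-rich proteins; note the known elicitor SM2 is one of
them even though its domain note names the protein rather than the class.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_reference_targets() -> pd.DataFrame:
    """The published enriched-target table (gene_id, domain_note, is_sscp)."""
    ref = resources.files("coexhub.data").joinpath("enriched_targets.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    df["is_sscp"] = df["is_sscp"].astype(bool)
    return df


def reference_target_summary() -> dict[str, int]:
    """Counts recomputed from the packaged table: number of unique enriched
    targets and how many of them are SSCPs."""
    df = load_reference_targets()
    unique = df.drop_duplicates("gene_id")
    return {
        "n_unique_targets": int(unique.shape[0]),
        "n_sscp_targets": int(unique["is_sscp"].sum()),
    }
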