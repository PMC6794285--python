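"""Bundled example datasets.

Small published tables shipped as plain TSV so the worked examples and tests
run without any download: the disruptive-variant table for the TANC2 screen
(21 variants across 15 referring cohorts) and the 58-gene prioritized
candidate table with constraint scores and FMRP/RBFOX membership.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .variants import CohortTable, DeNovoVariant, GeneRecord, read_cohort_table, read_variant_table

__all__ = ["load_tanc2_variants", "load_tanc2_cohorts", "load_candidate_genes"]


def _data_path(name: str):
    return resources.files("dnmenrich.data").joinpath(name)


def load_tanc2_variants() -> list[DeNovoVariant]:
    """The disruptive and de novo missense variants of the TANC2 screen."""
    with resources.as_file(_data_path("tanc2_variants.tsv")) as p:
        return read_variant_table(p)


def load_tanc2_cohorts() -> CohortTable:
    """Per-cohort tested-proband counts for the TANC2 screen."""
    with resources.as_file(_data_path("tanc2_cohorts.tsv")) as p:
        return read_cohort_table(p)


def load_candidate_genes() -> tuple[pd.DataFrame, dict[str, GeneRecord], dict[str, int]]:
    """The 58 prioritized ASD candidate genes.

    Returns ``(table, gene_records, lgd_counts)`` where ``gene_records`` maps
    symbols to :class:`~dnmenrich.variants.GeneRecord` (membership decoded
    from the F/R/Both column, missing scores as ``None``) and ``lgd_counts``
    maps symbols to the observed LGD hit count.
    """
    with resources.as_file(_data_path("candidate_genes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    records: dict[str, GeneRecord] = {}
    counts: dict[str, int] = {}
    for _, row in df.iterrows():
        gene = row["gene"]
        membership = row["fmrp_rbfox"]
        rvis = None if row["rvis_pct"] in ("-", "", None) else float(row["rvis_pct"])
        records[gene] = GeneRecord(
            gene=gene,
            pli=float(row["pli"]),
            rvis_pct=rvis,
            fmrp_target=membership in ("F", "Both"),
            rbfox_target=membership in ("R", "Both"),
            brain_expressed=True,
            known_significant=False,
        )
        counts[gene] = int(row["lgd_count"])
    return df, records, counts
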