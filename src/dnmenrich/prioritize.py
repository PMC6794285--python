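"""Candidate-gene prioritization by the three published criteria.

A gene hit by de novo LGD mutations is retained when it is (i) intolerant to
mutation (pLI >= threshold AND RVIS percentile <= threshold), (ii) an FMRP or
RBFOX target, and (iii) not already established genome-wide significant.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .variants import DeNovoVariant, GeneRecord, Inheritance, LGD_EFFECTS

logger = logging.getLogger(__name__)

__all__ = ["prioritize_candidates", "candidates_from_variants"]

_EFFECT_ABBREV = {"stopgain": "SG", "frameshift": "FS", "splice_site": "SP"}
_MEMBERSHIP_ORDER = {"Both": 0, "F": 1, "R": 2}


def _membership(rec: GeneRecord) -> str:
    if rec.fmrp_target and rec.rbfox_target:
        return "Both"
    if rec.fmrp_target:
        return "F"
    if rec.rbfox_target:
        return "R"
    return "-"


def candidates_from_variants(
    vs: Sequence[DeNovoVariant],
) -> tuple[dict[str, int], dict[str, str]]:
    """Per-gene de novo LGD counts and effect-type strings from a variant list."""
    counts: dict[str, int] = {}
    effects: dict[str, list[str]] = {}
    for v in vs:
        if v.effect in LGD_EFFECTS and v.inheritance == Inheritance.DE_NOVO:
            counts[v.gene] = counts.get(v.gene, 0) + 1
            effects.setdefault(v.gene, []).append(_EFFECT_ABBREV[v.effect.value])
    return counts, {g: ",".join(sorted(set(e))) for g, e in effects.items()}


def prioritize_candidates(
    hit_counts: Mapping[str, int],
    genes: Mapping[str, GeneRecord],
    thresholds: tuple[float, float] = (0.84, 32.0),
    effect_types: Mapping[str, str] | None = None,
    missing_policy: str = "fail",
) -> pd.DataFrame:
    """Apply the three prioritization criteria and rank the survivors.

    Parameters
    ----------
    hit_counts
        ``gene -> de novo LGD count`` among probands.
    genes
        Per-gene annotation.  A hit gene with no record fails (logged).
    thresholds
        ``(pli_threshold, rvis_threshold)``; boundary values are retained.
    effect_types
        Optional ``gene -> 'SG,FS'``-style annotation carried into the output.
    missing_policy
        How a missing pLI/RVIS score interacts with the intolerance
        criterion: ``'fail'`` (default) drops the gene, ``'pass'`` lets a
        missing score satisfy its half of the criterion (useful when a score
        provider simply does not cover a gene).

    Returns a DataFrame with columns ``gene, lgd_count, effect_types,
    fmrp_rbfox, rvis_pct, pli`` sorted by membership (Both, F, R) then RVIS
    percentile ascending.
    """
    if missing_policy not in ("fail", "pass"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    pli_thr, rvis_thr = thresholds
    rows = []
    for gene, count in hit_counts.items():
        rec = genes.get(gene)
        if rec is None:
            logger.warning("hit gene %s has no annotation record; excluded", gene)
            continue
        pli_ok = (rec.pli >= pli_thr) if rec.pli is not None else (missing_policy == "pass")
        rvis_ok = (rec.rvis_pct <= rvis_thr) if rec.rvis_pct is not None else (missing_policy == "pass")
        if not (pli_ok and rvis_ok):
            continue
        if not (rec.fmrp_target or rec.rbfox_target):
            continue
        if rec.known_significant:
            continue
        rows.append(
            {
                "gene": gene,
                "lgd_count": int(count),
                "effect_types": (effect_types or {}).get(gene, ""),
                "fmrp_rbfox": _membership(rec),
                "rvis_pct": rec.rvis_pct,
                "pli": rec.pli,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "lgd_count", "effect_types", "fmrp_rbfox", "rvis_pct", "pli"])
    if df.empty:
        return df
    df["_m"] = df["fmrp_rbfox"].map(_MEMBERSHIP_ORDER)
    df = df.sort_values(["_m", "rvis_pct", "gene"], na_position="last").drop(columns="_m")
    return df.reset_index(drop=True)
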