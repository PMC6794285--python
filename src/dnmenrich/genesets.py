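"""Gene-set enrichment and data-driven constraint thresholds.

Two pieces of the prioritization machinery live here: (1) Fisher's exact test
of whether the genes hit by de novo LGD mutations are over-represented among
an RNA-binding-protein target list (FMRP, RBFOX), against a brain-expressed
background; and (2) derivation of pLI/RVIS intolerance cutoffs from the score
distribution of genes whose disease association is already established.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy import stats

from .variants import GeneRecord

__all__ = [
    "geneset_fisher",
    "derive_constraint_thresholds",
    "DEFAULT_PLI_THRESHOLD",
    "DEFAULT_RVIS_THRESHOLD",
]

DEFAULT_PLI_THRESHOLD = 0.84
DEFAULT_RVIS_THRESHOLD = 32.0


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> float:
    """Cross-product odds ratio with a Haldane–Anscombe 0.5 added to every
    cell only when some cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def geneset_fisher(
    hit_genes: Iterable[str],
    target_genes: Iterable[str],
    background: Iterable[str],
) -> tuple[float, float]:
    """Enrichment of hit genes in a target gene set over a fixed background.

    The 2x2 table crosses {hit, non-hit} with {target, non-target} over the
    background universe; hits must be a subset of the background and the
    target set is intersected with the background before testing.  Returns
    ``(odds_ratio, p_two_sided)`` with the exact test's minimum-likelihood
    two-sided convention.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene set is empty")
    hits = set(hit_genes)
    if not hits <= bg:
        missing = sorted(hits - bg)[:5]
        raise ValueError(f"hit genes outside the background (e.g. {missing})")
    targets = set(target_genes) & bg
    a = len(hits & targets)
    b = len(hits - targets)
    c = len(targets - hits)
    d = len(bg) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds_ratio_2x2(a, b, c, d), float(p)


def derive_constraint_thresholds(
    significant_genes: Iterable[GeneRecord] | None = None,
    pli_quantile: float = 0.05,
    rvis_quantile: float = 0.95,
) -> tuple[float, float]:
    """Intolerance cutoffs from the score distribution of established genes.

    Established risk genes are strongly constrained, so a lower quantile of
    their pLI distribution and an upper quantile of their RVIS-percentile
    distribution bound the region where new candidates plausibly live.
    Quantiles are lower empirical quantiles (inverse ECDF).  With no gene
    table supplied the published package defaults ``(0.84, 32)`` are
    returned.
    """
    if significant_genes is None:
        return DEFAULT_PLI_THRESHOLD, DEFAULT_RVIS_THRESHOLD
    recs = list(significant_genes)
    plis = np.array([g.pli for g in recs if g.pli is not None], dtype=float)
    rvis = np.array([g.rvis_pct for g in recs if g.rvis_pct is not None], dtype=float)
    if len(plis) < 5 or len(rvis) < 5:
        raise ValueError(
            "fewer than 5 significant genes with non-missing scores; "
            "supply explicit thresholds instead"
        )
    pli_thr = float(np.quantile(plis, pli_quantile, method="inverted_cdf"))
    rvis_thr = float(np.quantile(rvis, rvis_quantile, method="inverted_cdf"))
    return pli_thr, rvis_thr
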