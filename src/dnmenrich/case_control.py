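"""Carrier-based case–control burden test against a reference population.

Counts individuals carrying at least one qualifying variant (per-individual,
not per-allele) in cases and in a reference population, and compares carrier
fractions with Fisher's exact test on the 2x2 table
``[[case_carriers, case_noncarriers], [control_carriers, control_noncarriers]]``.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .genesets import odds_ratio_2x2

__all__ = ["ContingencyTable", "fisher_burden"]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table with its exact-test outcome.

    ``odds_ratio`` is the raw cross-product ratio (a·d)/(b·c); a 0.5
    continuity correction is added to every cell only when some cell is zero.
    ``p_two_sided`` follows the minimum-likelihood two-sided convention.
    """

    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int
    odds_ratio: float
    p_two_sided: float

    def __post_init__(self) -> None:
        if self.case_carriers > self.case_total or self.control_carriers > self.control_total:
            raise ValueError("carrier count exceeds group total")
        if self.case_total < 1 or self.control_total < 1:
            raise ValueError("group totals must be >= 1")
        if self.odds_ratio < 0 or not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("invalid test outputs")

    def summary(self) -> str:
        return (
            f"Carrier burden: {self.case_carriers}/{self.case_total} cases vs "
            f"{self.control_carriers}/{self.control_total} controls; "
            f"OR = {self.odds_ratio:.3g}, two-sided P = {self.p_two_sided:.3g}"
        )


def fisher_burden(
    case_carriers: int,
    case_total: int,
    control_carriers: int,
    control_total: int,
) -> ContingencyTable:
    """Exact test of carrier-fraction difference between cases and controls."""
    if case_carriers < 0 or control_carriers < 0:
        raise ValueError("carrier counts must be non-negative")
    if case_carriers > case_total or control_carriers > control_total:
        raise ValueError("carrier count exceeds group total")
    a, b = case_carriers, case_total - case_carriers
    c, d = control_carriers, control_total - control_carriers
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyTable(
        case_carriers=case_carriers,
        case_total=case_total,
        control_carriers=control_carriers,
        control_total=control_total,
        odds_ratio=odds_ratio_2x2(a, b, c, d),
        p_two_sided=float(p),
    )
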