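"""Proband-vs-sibling de novo LGD burden with a paternal-age covariate.

The comparison exploits the matched quad design (one affected proband and one
unaffected sibling per family): per-individual de novo LGD counts are modeled
as ``count ~ group + paternal_age``, and the group term's test probability is
the burden p-value.  The default fit is an ordinary linear model (the group
F-test is identical to the two-sided t-test on the group coefficient); a
Poisson log-linear alternative is available because counts are small
non-negative integers, but the linear model is the primary method.

Paternal age matters because the de novo mutation rate rises with the
father's age at conception; including it as a covariate prevents an age
imbalance between groups from masquerading as a disease signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .variants import (
    CohortTable,
    DeNovoVariant,
    GeneRecord,
    Inheritance,
    LGD_EFFECTS,
    count_events_per_individual,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterTag",
    "BurdenResult",
    "BurdenModel",
    "per_individual_rate",
    "rate_with_ci",
    "compare_burden",
    "exclude_genes",
    "PLI_THRESHOLD",
    "RVIS_THRESHOLD",
]

#: Published intolerance cutoffs: keep genes with pLI >= 0.84 and RVIS% <= 32.
PLI_THRESHOLD = 0.84
RVIS_THRESHOLD = 32.0


class FilterTag(str, Enum):
    ALL = "all"
    EXCLUDING_SIGNIFICANT = "excluding_significant"
    INTOLERANT_NONSIGNIFICANT = "intolerant_nonsignificant"


@dataclass(frozen=True)
class BurdenResult:
    """Outcome of one proband-vs-sibling burden comparison."""

    rate_probands: float
    rate_siblings: float
    ci95_probands: tuple[float, float]
    ci95_siblings: tuple[float, float]
    group_effect_p: float
    group_coef: float
    n_probands: int
    n_siblings: int
    filter_tag: FilterTag = FilterTag.ALL

    def __post_init__(self) -> None:
        if self.rate_probands < 0 or self.rate_siblings < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.group_effect_p <= 1.0):
            raise ValueError("group_effect_p must be a probability")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "filter": self.filter_tag.value,
                    "rate_probands": self.rate_probands,
                    "rate_siblings": self.rate_siblings,
                    "ci95_probands_lo": self.ci95_probands[0],
                    "ci95_probands_hi": self.ci95_probands[1],
                    "ci95_siblings_lo": self.ci95_siblings[0],
                    "ci95_siblings_hi": self.ci95_siblings[1],
                    "group_effect_p": self.group_effect_p,
                    "n_probands": self.n_probands,
                    "n_siblings": self.n_siblings,
                }
            ]
        )

    def summary(self) -> str:
        lines = [
            f"De novo LGD burden [{self.filter_tag.value}]",
            f"  probands: {self.rate_probands:.3f} per individual "
            f"(95% CI {self.ci95_probands[0]:.3f}-{self.ci95_probands[1]:.3f}, n={self.n_probands})",
            f"  siblings: {self.rate_siblings:.3f} per individual "
            f"(95% CI {self.ci95_siblings[0]:.3f}-{self.ci95_siblings[1]:.3f}, n={self.n_siblings})",
            f"  group effect (paternal-age adjusted): P = {self.group_effect_p:.3g}",
        ]
        return "\n".join(lines)


def rate_with_ci(counts: Sequence[int] | np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mean per-individual event rate with a normal-approximation 95% CI.

    The interval is ``mean ± 1.96 · sd/√n`` on the per-individual counts,
    floored at zero (a rate cannot be negative).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute a rate over zero individuals")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, (mean, mean)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size))
    lo = max(0.0, mean - 1.96 * se)
    hi = mean + 1.96 * se
    return mean, (lo, hi)


def per_individual_rate(
    vs: Iterable[DeNovoVariant],
    cohort: CohortTable,
    role: str,
    classes=LGD_EFFECTS,
    inheritance: Inheritance | None = Inheritance.DE_NOVO,
) -> tuple[float, tuple[float, float]]:
    """Per-individual qualifying-event rate for one role, with 95% CI.

    Individuals of the role with zero events count in the denominator.
    """
    ids = cohort.ids_with_role(role)
    if not ids:
        raise ValueError(f"cohort lists no individuals with role {role!r}")
    counts = count_events_per_individual(vs, ids, classes=classes, inheritance=inheritance)
    return rate_with_ci(np.array([counts[i] for i in ids]))


def compare_burden(
    counts_by_individual: Mapping[str, int],
    roles: Mapping[str, str],
    paternal_age: Mapping[str, float | None],
    filter_tag: FilterTag = FilterTag.ALL,
    family: str = "linear",
) -> BurdenResult:
    """Fit ``count ~ group + paternal_age`` and test the group term.

    ``family='linear'`` (default) fits OLS and reports the two-sided group
    t-test probability (equal to the single-df F-test); ``family='poisson'``
    fits a Poisson GLM with a log link and reports the group Wald test.
    Missing paternal ages are imputed by the overall mean age.
    """
    ids = list(counts_by_individual)
    y = np.array([counts_by_individual[i] for i in ids], dtype=float)
    group = np.array([1.0 if roles[i] == "proband" else 0.0 for i in ids])
    ages_raw = [paternal_age.get(i) for i in ids]
    known = [a for a in ages_raw if a is not None and not (isinstance(a, float) and math.isnan(a))]
    mean_age = float(np.mean(known)) if known else 0.0
    age = np.array(
        [mean_age if a is None or (isinstance(a, float) and math.isnan(a)) else float(a) for a in ages_raw]
    )

    n_pro = int(group.sum())
    n_sib = int(len(ids) - n_pro)
    if n_pro == 0 or n_sib == 0:
        raise ValueError("both probands and siblings are required for a burden comparison")
    if np.ptp(y) == 0 and np.ptp(age) == 0:
        raise ValueError("degenerate model: all counts identical and ages constant")

    X = np.column_stack([np.ones_like(y), group, age])
    # Drop the age column if constant (it would be collinear with the intercept).
    if np.ptp(age) == 0:
        X = X[:, :2]
    if family == "linear":
        fit = sm.OLS(y, X).fit()
    elif family == "poisson":
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    else:
        raise ValueError(f"unknown family {family!r}")
    coef = float(fit.params[1])
    p = float(fit.pvalues[1])
    if math.isnan(p):  # zero residual variance with a real group difference
        p = 0.0

    rate_pro, ci_pro = rate_with_ci(y[group == 1.0])
    rate_sib, ci_sib = rate_with_ci(y[group == 0.0])
    return BurdenResult(
        rate_probands=rate_pro,
        rate_siblings=rate_sib,
        ci95_probands=ci_pro,
        ci95_siblings=ci_sib,
        group_effect_p=min(1.0, p),
        group_coef=coef,
        n_probands=n_pro,
        n_siblings=n_sib,
        filter_tag=filter_tag,
    )


def exclude_genes(
    vs: Sequence[DeNovoVariant],
    genes: Mapping[str, GeneRecord],
    mode: str,
    pli_threshold: float = PLI_THRESHOLD,
    rvis_threshold: float = RVIS_THRESHOLD,
) -> list[DeNovoVariant]:
    """Drop variants by gene-level annotation.

    ``mode='known_significant'`` removes variants in genes already established
    genome-wide significant (so the burden reflects *new* signal);
    ``mode='not_intolerant'`` keeps only variants in intolerant genes, i.e.
    pLI >= ``pli_threshold`` AND RVIS percentile <= ``rvis_threshold``
    (boundary values retained).  A gene absent from the annotation, or with a
    missing score in intolerance mode, fails the filter and is logged.
    """
    if mode not in ("known_significant", "not_intolerant"):
        raise ValueError(f"unknown exclusion mode {mode!r}")
    out: list[DeNovoVariant] = []
    for v in vs:
        rec = genes.get(v.gene)
        if rec is None:
            logger.warning("gene %s has no annotation record; variant fails the %s filter", v.gene, mode)
            continue
        if mode == "known_significant":
            if not rec.known_significant:
                out.append(v)
        else:
            if (
                rec.pli is not None
                and rec.rvis_pct is not None
                and rec.pli >= pli_threshold
                and rec.rvis_pct <= rvis_threshold
            ):
                out.append(v)
            elif rec.pli is None or rec.rvis_pct is None:
                logger.warning("gene %s has missing constraint scores; variant fails the intolerance filter", v.gene)
    return out


class BurdenModel:
    """Paternal-age-adjusted burden comparison as a fit-able model object.

    Parameters
    ----------
    counts_by_individual
        De novo LGD count per individual (zeros included).
    roles
        ``individual_id -> 'proband' | 'sibling'``.
    paternal_age
        ``individual_id -> father's age at birth`` (years; ``None`` = missing,
        imputed by the overall mean).
    """

    def __init__(
        self,
        counts_by_individual: Mapping[str, int],
        roles: Mapping[str, str],
        paternal_age: Mapping[str, float | None] | None = None,
        filter_tag: FilterTag = FilterTag.ALL,
    ) -> None:
        self.counts_by_individual = dict(counts_by_individual)
        self.roles = dict(roles)
        self.paternal_age = dict(paternal_age or {})
        self.filter_tag = filter_tag

    @classmethod
    def from_variants(
        cls,
        vs: Sequence[DeNovoVariant],
        cohort: CohortTable,
        genes: Mapping[str, GeneRecord] | None = None,
        filter_tag: FilterTag = FilterTag.ALL,
        pli_threshold: float = PLI_THRESHOLD,
        rvis_threshold: float = RVIS_THRESHOLD,
    ) -> "BurdenModel":
        """Build the comparison from a variant list, applying the tag's gene filter."""
        if filter_tag != FilterTag.ALL:
            if genes is None:
                raise ValueError("gene annotation is required for filtered burden categories")
            vs = exclude_genes(vs, genes, "known_significant")
            if filter_tag == FilterTag.INTOLERANT_NONSIGNIFICANT:
                vs = exclude_genes(vs, genes, "not_intolerant", pli_threshold, rvis_threshold)
        ids = [iid for iid, _, _, _ in cohort.individuals]
        counts = count_events_per_individual(vs, ids)
        return cls(counts, cohort.individual_role, cohort.paternal_ages, filter_tag)

    def fit(self, family: str = "linear") -> BurdenResult:
        return compare_burden(
            self.counts_by_individual, self.roles, self.paternal_age, self.filter_tag, family=family
        )
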