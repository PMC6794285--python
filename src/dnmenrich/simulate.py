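"""Synthetic cohorts, gene annotation and single-cell matrices with known truth.

Every generator is a pure function of its seed and parameters (numpy
``default_rng``; no global state), and writes/returns the same structures the
readers consume, so each pipeline stage can be tested end-to-end without any
external data.

The cohort generator emulates the statistical structure of a simplex-quad
exome study: families with one affected proband and one unaffected sibling,
per-individual de novo LGD counts Poisson with a genome-wide mean that is
multiplied across genes, elevated in probands for a designated set of risk
genes, and modulated by the father's age at birth.  Two parameter presets are
provided: ``"ssc-like"`` (1902 quads, proband/sibling genome-wide rates
0.16/0.09) and ``"tiny"`` (20 quads, for fast tests).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .scrna import CellExpressionInput
from .variants import CohortTable, DeNovoVariant, Effect, GeneRecord, Inheritance

__all__ = [
    "simulate_cohort",
    "simulate_quad_counts",
    "simulate_gene_annotation",
    "simulate_scrna",
    "preset_cohort_params",
    "PRESETS",
]

_LGD_CLASSES = (Effect.STOPGAIN, Effect.FRAMESHIFT, Effect.SPLICE_SITE)

#: Mean/SD of paternal age at birth (years), typical of exome trio cohorts.
PATERNAL_AGE_MEAN = 33.0
PATERNAL_AGE_SD = 5.0


def _gene_rate_vector(per_gene_rates: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    genes = list(per_gene_rates)
    rates = np.array([per_gene_rates[g] for g in genes], dtype=float)
    if (rates <= 0).any():
        raise ValueError("all per-gene rates must be positive")
    return genes, rates


def simulate_quad_counts(
    n_quads: int,
    proband_mean: float,
    sibling_mean: float,
    paternal_age_effect: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast path: per-individual de novo LGD counts for a quad cohort.

    Returns ``(proband_counts, sibling_counts, paternal_age)`` with one entry
    per family; the age (shared by the two children of a family) multiplies
    both means by ``exp(effect · (age − mean age))``.
    """
    rng = np.random.default_rng(seed)
    age = rng.normal(PATERNAL_AGE_MEAN, PATERNAL_AGE_SD, size=n_quads)
    mod = np.exp(paternal_age_effect * (age - PATERNAL_AGE_MEAN))
    pro = rng.poisson(proband_mean * mod)
    sib = rng.poisson(sibling_mean * mod)
    return pro, sib, age


def simulate_cohort(
    n_quads: int,
    per_gene_rates: Mapping[str, float],
    risk_genes: Sequence[str] | set[str] = (),
    fold_elevation: float = 1.0,
    paternal_age_effect: float = 0.0,
    seed: int = 0,
    cohort_name: str = "sim",
) -> tuple[list[DeNovoVariant], CohortTable]:
    """Simulate a quad-family cohort of de novo LGD variants.

    Per individual, the de novo LGD count is Poisson with mean
    ``Σ_g rate_g · exp(effect · (age − mean age))``, where risk-gene rates are
    multiplied by ``fold_elevation`` in probands only; events are assigned to
    genes multinomially in proportion to the (adjusted) rates.  Deterministic
    under a fixed seed.
    """
    genes, base_rates = _gene_rate_vector(per_gene_rates)
    risk_mask = np.array([g in set(risk_genes) for g in genes])
    pro_rates = np.where(risk_mask, base_rates * fold_elevation, base_rates)

    rng = np.random.default_rng(seed)
    variants: list[DeNovoVariant] = []
    individuals: list[tuple[str, str, str, float | None]] = []
    for fam in range(n_quads):
        age = float(rng.normal(PATERNAL_AGE_MEAN, PATERNAL_AGE_SD))
        mod = math.exp(paternal_age_effect * (age - PATERNAL_AGE_MEAN))
        for role, rates in (("proband", pro_rates), ("sibling", base_rates)):
            iid = f"fam{fam:05d}.{'p1' if role == 'proband' else 's1'}"
            individuals.append((iid, role, cohort_name, age))
            total = rates.sum() * mod
            n_events = int(rng.poisson(total))
            if n_events == 0:
                continue
            gene_idx = rng.choice(len(genes), size=n_events, p=rates / rates.sum())
            for j, gi in enumerate(gene_idx):
                eff = _LGD_CLASSES[int(rng.integers(len(_LGD_CLASSES)))]
                variants.append(
                    DeNovoVariant(
                        individual_id=iid,
                        gene=genes[int(gi)],
                        effect=eff,
                        inheritance=Inheritance.DE_NOVO,
                        nt_change=f"c.sim_{fam}_{role}_{j}",
                        role=role,
                        cohort=cohort_name,
                    )
                )
    cohort = CohortTable(individuals=individuals, cohort_sizes={cohort_name: 2 * n_quads})
    return variants, cohort


def simulate_gene_annotation(
    n_genes: int,
    frac_fmrp: float = 0.10,
    frac_rbfox: float = 0.08,
    frac_significant: float = 0.02,
    seed: int = 0,
    genome_mu_lgd: float = 0.09,
) -> dict[str, GeneRecord]:
    """Simulate a per-gene annotation table.

    pLI is drawn from a mixture concentrating mass near 0 and near 1 (the
    empirical shape of the constraint score), RVIS percentiles uniform on
    [0, 100], set memberships Bernoulli, and mutation-rate parameters
    proportional to a lognormal simulated gene length: ``rel_rate_ch``
    normalizes to sum to 1 and ``mu_lgd = rel_rate_ch · genome_mu_lgd``
    (genome-wide per-haploid LGD mutation probability per generation).
    """
    rng = np.random.default_rng(seed)
    names = [f"G{i:05d}" for i in range(n_genes)]
    near_one = rng.random(n_genes) < 0.3
    pli = np.where(near_one, rng.beta(8.0, 0.5, n_genes), rng.beta(0.5, 8.0, n_genes))
    rvis = rng.uniform(0.0, 100.0, n_genes)
    lengths = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    rel = lengths / lengths.sum()
    fmrp = rng.random(n_genes) < frac_fmrp
    rbfox = rng.random(n_genes) < frac_rbfox
    sig = rng.random(n_genes) < frac_significant
    return {
        names[i]: GeneRecord(
            gene=names[i],
            pli=float(np.clip(pli[i], 0.0, 1.0)),
            rvis_pct=float(rvis[i]),
            rel_rate_ch=float(rel[i]),
            mu_lgd=float(rel[i] * genome_mu_lgd),
            fmrp_target=bool(fmrp[i]),
            rbfox_target=bool(rbfox[i]),
            brain_expressed=True,
            known_significant=bool(sig[i]),
        )
        for i in range(n_genes)
    }


def simulate_scrna(
    n_cells_per_type: Mapping[str, int],
    detection_probs: Mapping[str, float],
    seed: int = 0,
    gene_of_interest: str = "GOI",
    n_background_genes: int = 20,
    background_detection: float = 0.3,
    lognormal_sigma: float = 0.5,
) -> CellExpressionInput:
    """Simulate a labeled expression matrix for one gene of interest.

    Expression is Bernoulli(detection probability) × a lognormal magnitude;
    background genes share a common detection probability so the matrix is a
    realistic sparse cells × genes container, not a single column.
    """
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for t, n in n_cells_per_type.items():
        labels.extend([t] * int(n))
    n_cells = len(labels)
    genes = [gene_of_interest] + [f"BG{i:03d}" for i in range(n_background_genes)]
    expr = np.zeros((n_cells, len(genes)))
    det_p = np.array([detection_probs[t] for t in labels])
    detected = rng.random(n_cells) < det_p
    expr[:, 0] = detected * rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_cells)
    for j in range(1, len(genes)):
        on = rng.random(n_cells) < background_detection
        expr[:, j] = on * rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_cells)
    return CellExpressionInput(expr, genes, labels, gene_of_interest)


def preset_cohort_params(name: str, seed: int = 0) -> dict:
    """Named parameter presets for :func:`simulate_cohort`.

    ``"ssc-like"``: 1902 quads; 500 genes whose baseline rates sum to 0.09
    (the sibling genome-wide LGD rate), with 25 risk genes holding a combined
    baseline share of 0.014 elevated 6-fold in probands, bringing the proband
    genome-wide rate to 0.16.  ``"tiny"``: 20 quads, 50 genes, same rate
    structure scaled, for fast tests.
    """
    if name == "ssc-like":
        n_quads, n_genes, n_risk = 1902, 500, 25
    elif name == "tiny":
        n_quads, n_genes, n_risk = 20, 50, 5
    else:
        raise ValueError(f"unknown preset {name!r}")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    risk = genes[:n_risk]
    # Baseline (sibling) genome-wide rate 0.09: risk genes carry 0.014 of it,
    # elevated 6-fold in probands -> proband rate 0.09 + 5*0.014 = 0.16.
    risk_share, fold = 0.014, 6.0
    rates = {g: risk_share / n_risk if g in set(risk) else (0.09 - risk_share) / (n_genes - n_risk) for g in genes}
    return {
        "n_quads": n_quads,
        "per_gene_rates": rates,
        "risk_genes": risk,
        "fold_elevation": fold,
        "paternal_age_effect": 0.0,
        "seed": seed,
    }


PRESETS = ("ssc-like", "tiny")
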