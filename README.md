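# dnmenrich

Statistics for de novo mutation (DNM) gene discovery in neurodevelopmental
disorders. Trio and quad exome studies of autism and related conditions ask
a recurring set of questions: do affected children carry more de novo likely
gene-disrupting (LGD; stopgain, frameshift, splice-site) mutations than their
unaffected siblings? Which mutated genes are worth following up — intolerant
to mutation, targets of neuronal RNA-binding proteins, not already
established? Is the pile-up of de novo hits in one gene across many cohorts
bigger than mutation-rate models predict? And where in the developing brain
is that gene expressed? `dnmenrich` implements this pipeline as a tested
library with a thin CLI, for statistical geneticists analyzing family-based
sequencing cohorts.

## What it computes

* **Variant filtering and accounting** — effect-class normalization, the
  MAF > 0.1% population filter, removal of low-confidence recurrent sites,
  inheritance tallies, and cohort-size accounting (each contributing cohort's
  tested count summed exactly once).
* **Quad burden** (`BurdenModel.fit()`) — per-individual LGD rates with 95%
  CIs and the proband-vs-sibling contrast from the linear model
  `count ~ group + paternal_age`, optionally restricted to intolerant
  (pLI ≥ 0.84, RVIS% ≤ 32) and/or not-yet-significant genes.
* **Gene-set enrichment** — Fisher's exact test of mutated genes in
  FMRP/RBFOX target lists over a brain-expressed background; constraint
  thresholds derivable as quantiles of established genes' scores.
* **Prioritization** — the three-criterion candidate ranking (intolerant ∧
  FMRP/RBFOX target ∧ not known-significant).
* **Gene-level enrichment** (`DeNovoEnrichmentModel.fit()`) — for observed
  hit count k in N individuals, tail probabilities under two models: the
  divergence-calibrated (CH) model, λ = N·r·p_g with r = 1.5 expected DNMs
  per exome and p_g the gene's relative rate, and the trinucleotide-context
  model, λ = 2·N·μ_g; Bonferroni correction over 2 models × 19,000 genes and
  a sensitivity sweep over r ∈ {1.0, 1.5, 2.0}.
* **Case–control carrier burden** — Fisher's exact test of carrier fractions
  against a reference population.
* **Cell-type enrichment** (`CellTypeEnrichmentModel.fit()`) — per-cell-type
  detection odds ratios and Wilcoxon rank-sum tests (one-vs-rest, Bonferroni
  adjusted) for a single gene in labeled single-cell expression.
* **Simulators** — seeded generators for quad cohorts with implanted risk
  genes and a paternal-age effect, gene annotation tables, and labeled
  single-cell matrices, so every stage is testable with known ground truth.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

The package ships the disruptive-variant table of a multi-cohort screen of
the postsynaptic-density gene *TANC2* and the 58-gene candidate table it came
from, as small TSVs.

```python
from dnmenrich import (fisher_burden, tally_inheritance,
                       cohort_size_accounting, Inheritance)
from dnmenrich.datasets import (load_tanc2_variants, load_tanc2_cohorts,
                                load_candidate_genes)
from dnmenrich.prioritize import prioritize_candidates

vs, cohorts = load_tanc2_variants(), load_tanc2_cohorts()
print({k.value: v for k, v in tally_inheritance(vs).items()})
print(cohort_size_accounting(vs, cohorts))
print(cohort_size_accounting(vs, cohorts,
                             restrict_inheritance=[Inheritance.DE_NOVO]))
print(fisher_burden(13, 17567, 3, 45375).summary())
```

prints

```
{'de_novo': 11, 'paternal': 2, 'maternal': 2, 'undetermined': 1}
(13, 17567)
(10, 16113)
Carrier burden: 13/17567 cases vs 3/45375 controls; OR = 11.2, two-sided P = 1.42e-05
```

Reading across: of the 16 LGD variants, 11 are de novo and 4 inherited; 13
carrier probands come from cohorts with stated sizes totalling 17,567 tested
individuals, and the de novo carriers with known cohort sizes were screened
from 16,113; those 13 carriers against 3 carriers among 45,375 reference
individuals give an 11-fold enriched carrier rate with exact-test
P ≈ 1.4 × 10⁻⁵.

Prioritization on the bundled candidate annotation (`missing_policy="pass"`
keeps the four genes whose RVIS score is simply not published):

```python
_, records, lgd_counts = load_candidate_genes()
table = prioritize_candidates(lgd_counts, records, missing_policy="pass")
print(table.head(6).to_string(index=False))
```

```
  gene  lgd_count effect_types fmrp_rbfox  rvis_pct  pli
  UBR5          1                    Both      0.21  1.0
   DST          1                    Both      0.28  1.0
 TANC2          1                    Both      0.37  1.0
  NBEA          1                    Both      1.16  1.0
GRIN2B          3                    Both      1.28  1.0
 NRXN1          1                    Both      1.78  1.0
```

All 58 genes survive (they were selected by these criteria); genes in both
target sets sort first, most-intolerant (lowest RVIS percentile) at the top.

From the shell, the same carrier test:

```bash
dnmenrich case-control --case-carriers 13 --case-n 17567 \
    --control-carriers 3 --control-n 45375
```

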