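# Methods

`dnmenrich` implements the statistical pipeline used to nominate and confirm
risk genes for neurodevelopmental disorders (NDD/ASD) from de novo mutation
data. This note documents the models, their assumptions, the tunable
parameters, the synthetic-data generators, and the numerical choices.

## Variant model and filters

The unit of analysis is a coding variant annotated with an effect class and an
inheritance call; effect annotation is an *input* (ANNOVAR-style labels are
normalized through a closed alias map, unknown labels become `other`).
Likely gene-disrupting (LGD) variants are stopgains, frameshifts and canonical
splice-site mutations.

Two filters precede every analysis:

* **Population frequency** — variants with reference-population minor allele
  frequency strictly greater than 0.1% (default `maf_threshold = 0.001`) are
  removed; a variant absent from the reference population is retained, since
  absence cannot exceed a threshold. The comparison is strict (`>` removes,
  `=` retains).
* **Recurrence artifacts** — a site whose canonical key
  (`chrom:pos:ref:alt`, or `gene:nt_change` when coordinates are absent)
  occurs in two or more distinct families *and* carries an upstream
  low-confidence flag is removed. Recurrence alone is not disqualifying: the
  same splice-donor mutation can genuinely arise independently in unrelated
  families, so the artifact signature requires both conditions. Families are
  identified by the individual-id prefix before the first `.`.

Both filters are order-preserving and idempotent.

Cohort-size accounting counts distinct carrier probands whose referring
cohort has a stated tested-individual count, and sums each contributing
cohort's size exactly once regardless of how many carriers it contributed —
the denominator of the screen, not a sum over carriers.

## Proband-vs-sibling burden (`BurdenModel`)

Simplex quad families (affected proband + unaffected sibling) allow a matched
burden comparison. Per-individual de novo LGD counts are modeled as

    count ~ group + paternal_age

by ordinary least squares; the burden p-value is the two-sided t-test on the
group coefficient (identical to the single-df F-test). Paternal age at birth
enters as a covariate because the de novo rate rises with father's age;
missing ages are imputed by the overall mean, which leaves the group contrast
unbiased under missingness unrelated to group. A Poisson log-linear fit is
available (`family="poisson"`) since counts are small non-negative integers,
but the linear model is the default: with n ≈ 2000 per arm the OLS group test
is well calibrated (type-I error 0.045–0.065 at α = 0.05 in the null
simulations here) and directly interpretable as a rate difference.

Three gene-filter categories mirror the standard analysis: all LGD events;
excluding genes with already-established genome-wide significance (does new
signal remain once known genes are removed?); and restricted further to
intolerant genes. Intolerance means pLI ≥ 0.84 AND RVIS percentile ≤ 32 by
default — boundary values are retained, and a gene with a missing score fails
the filter by default (`missing_policy="pass"` is available, because public
constraint tables simply do not cover some genes and an analyst may prefer
not to penalize them).

Rates are reported per individual with a normal-approximation 95% CI
(mean ± 1.96·sd/√n on per-individual counts), floored at zero.

## Gene-set enrichment and constraint thresholds

Whether the mutated genes are over-represented among FMRP or RBFOX targets is
tested with Fisher's exact test on the 2×2 table {hit, non-hit} × {target,
non-target} over a brain-expressed background universe; the target list is
intersected with the background first, and hit genes must be a subset of it.
The two-sided p follows the minimum-likelihood convention (sum of table
probabilities not exceeding the observed table's), the dominant convention in
statistical software; the odds ratio is the raw cross-product, with a
Haldane–Anscombe 0.5 added to every cell only when some cell is zero.

Intolerance cutoffs can be derived from the constraint-score distribution of
established risk genes: the lower empirical quantile (inverse ECDF) of their
pLI and the upper quantile of their RVIS percentile. The inverse-ECDF type
was chosen because the thresholds should be attained scores, not
interpolants; it is configurable. With no gene table the package defaults are
the published cutoffs (0.84, 32).

## Candidate prioritization

A gene hit by de novo LGD mutations survives when it is (i) intolerant
(pLI/RVIS as above), (ii) an FMRP **or** RBFOX target (union semantics), and
(iii) not already genome-wide significant. Output is sorted by membership
(Both, F, R) then RVIS percentile ascending — the grouping used in published
candidate tables; the ordering is a presentation choice, not part of the
statistics. Retention is monotone: relaxing either threshold can only grow
the output, and adding a failing gene to the input never changes it.

## Gene-level de novo enrichment (`DeNovoEnrichmentModel`)

Both models compute the probability of observing at least k de novo LGD hits
in one gene across N screened individuals.

* **CH model** (divergence-calibrated): the exome-wide expected number of de
  novo mutations per individual is r (default **1.5**); the gene's share is
  its relative locus-specific rate p_g ∈ (0,1). Total expected mutations
  T = N·r; the tail is P(X ≥ k) with X ~ Binomial(round(T), p_g), or — the
  default — its Poisson limit with λ = T·p_g. The Poisson form is used by
  default because in the operating regime (λ ≪ 1, T ≥ 10³) the two agree to
  ~k(k−1)/2T relative while the Poisson tail is simpler and numerically
  stable; the binomial is available by flag.
* **Trinucleotide-context model** (denovolyzeR-style): the gene carries an
  absolute per-haploid LGD mutation probability μ_g; λ = 2·N·μ_g (two haploid
  genomes per child) and the tail is Poisson. The diploid factor is
  configurable for rate tables already expressed per diploid genome.

k = 0 returns p = 1 by construction. Tail probabilities are evaluated with
survival functions computed in the tail (never 1 − CDF), so values of order
10⁻¹⁴ are representable without cancellation. Raw p-values are
Bonferroni-adjusted across models × genes (defaults **2 × 19,000**,
min(1, p·m·g)). A sensitivity sweep re-tests at alternative per-exome rates
(default extremes 1.0 and 2.0 around 1.5) because de novo discovery
sensitivity differs between sequencing centers; the adjusted p is monotone
non-decreasing in r at fixed k.

Per-gene rates are inputs: the package does not estimate mutation rates from
sequence.

## Case–control carrier burden

Carriers (individuals with ≥ 1 qualifying variant; per-individual, not
per-allele) in the case cohort versus a reference population, compared with
Fisher's exact test on `[[case_carriers, case_noncarriers],
[control_carriers, control_noncarriers]]`. The odds ratio is the raw
cross-product (0.5 correction only on zero cells). Note that placing group
*totals* instead of non-carrier counts in the table changes the p-value by
under 1% at screen scale but is not the correct construction; this package
always uses carriers/non-carriers, which matches R's `fisher.test` on the
same table exactly.

## Cell-type expression enrichment

For one gene in a labeled single-cell matrix of pre-processed normalized
expression, each cell type is compared one-vs-rest:

* **detection odds ratio** — expression above a threshold (default > 0; the
  binarization is configurable) in-type vs all other cells, 0.5 correction on
  zero cells; if detection is degenerate (everything or nothing detected
  globally) the OR is reported as 1;
* **rank-sum test** — two-sided Wilcoxon on the expression values, exact by
  enumeration when both groups have ≤ 50 cells and the pooled values are
  untied, otherwise the tie-corrected normal approximation with continuity
  correction (the convention of R's `wilcox.test`);
* **Bonferroni** over the number of types actually tested.

One-vs-rest (rather than all pairwise) is used because the question is
enrichment or depletion of each type against the organ-wide background.
Types with fewer than 2 cells are excluded with a warning. Rows are ordered
by mean in-type expression, descending. Fine cluster labels can be collapsed
to broad types through a user-supplied mapping before testing. The module
performs no normalization, clustering or embedding.

## Synthetic data generators

All generators are pure functions of an explicit seed (numpy `default_rng`;
no global state) and emit exactly the structures the readers consume.

* **Quad cohorts** — per individual, the de novo LGD count is Poisson with
  mean Σ_g rate_g, multiplied by `fold_elevation` in probands for designated
  risk genes and by `exp(slope · (age − 33))` for a paternal-age effect
  (ages ~ Normal(33, 5) years, typical of exome trio cohorts); events are
  assigned to genes multinomially in proportion to the adjusted rates. The
  `"ssc-like"` preset uses 1902 quads and 500 genes whose baseline rates sum
  to 0.09 per individual (the sibling genome-wide LGD rate), with 25 risk
  genes holding a combined baseline share of 0.014 elevated 6-fold in
  probands, giving the proband genome-wide rate 0.16; `"tiny"` (20 quads)
  exists for fast tests.
* **Gene annotation** — pLI from a Beta mixture concentrating near 0 and 1,
  RVIS percentiles uniform, memberships Bernoulli, and mutation-rate
  parameters proportional to a lognormal simulated gene length
  (`rel_rate_ch` sums to 1; `mu_lgd = rel_rate_ch × 0.09`, a genome-wide
  per-haploid LGD probability giving ≈ 0.18 expected LGD events per child).
* **Single-cell matrices** — expression is Bernoulli(per-type detection
  probability) × lognormal magnitude, with background genes at a common
  detection rate so the container is a realistic sparse matrix.

What the generators do **not** emulate: sequence context (no trinucleotide
spectra, no CpG structure — rates are drawn, not derived), locus-specific
detection sensitivity, relatedness beyond the quad, batch effects, dropout
structure beyond Bernoulli detection, and inherited variation. Passing tests
therefore demonstrate correctness of the *statistics* under their stated
models, not robustness to the full messiness of real sequencing data.

## Validation experiments and problem sizes

`dnmenrich.validation` packages three seeded study-scale experiments, used by
the test suite and the reproduction script:

* **Null calibration** — 10⁴ genes with counts drawn from their own model;
  because counts are discrete, P(p ≤ t) ≤ t, so raw p-values are
  stochastically ≥ uniform; checked via the one-sided KS statistic D⁺.
* **Risk-gene recovery** — a scaled-down genome of 200 equally-sized genes
  sharing a genome-wide proband rate of 0.16 over 1902 probands, 5 genes
  elevated 10-fold. Under these conditions a risk gene expects λ = 15.2 hits
  against a null λ = 1.52, and the probability that any risk gene falls below
  the rank-10 boundary is ≈ 7×10⁻⁴ per gene analytically, so requiring all
  five in the top 10 in ≥ 95/100 replicates is a sharp but attainable bar.
  The gene count is scaled down (not the cohort) because a 10-fold elevation
  of an average-sized gene's rate in a full-size genome is statistically
  invisible at this cohort size — risk genes in real screens are large genes.
* **Burden power/type-I** — 500 alternative replicates (rates 0.16 vs 0.09)
  and 1000 null replicates (0.12 vs 0.12) at 1902 families per arm.

These sizes keep a full validation run under ~30 s on one core while leaving
Monte-Carlo error well inside the asserted bands.

## Degenerate inputs and tie-breaks

* Empty variant lists tally to zero everywhere; an empty hit set prioritizes
  to an empty table.
* A burden design with all counts identical and constant ages raises a
  degenerate-model error; if residual variance is zero but a group difference
  exists, the p-value is reported as 0.
* Constant expression across all cells yields OR = 1 and p = 1 for every
  type (exchangeable null; there is nothing to test).
* Equal p-values rank by gene symbol for deterministic output ordering.
* Thresholds at exact boundaries (pLI = 0.84, RVIS = 32, MAF = 0.1%) retain
  the gene/variant.

## Known limitations

* The paternal-age adjustment assumes a log-linear (simulation) /
  linear (fit) age effect; strong non-linearity would be mis-modeled.
* The CH model's `round(T)` binomial size loses at most half a mutation of
  expectation; irrelevant at screen scale, visible only for toy N.
* Bonferroni across models × genes is conservative given the two models are
  highly correlated; no FDR alternative is provided because genome-wide
  claims in this setting conventionally use family-wise control.
* The exact rank-sum path is quadratic in group size and is therefore capped
  at 50 cells per group; above that the tie-corrected normal approximation
  is used, which is standard but approximate for heavily tied sparse genes.
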