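"""Per-individual rates and the covariate-adjusted burden comparison."""

import numpy as np
import pytest

from conftest import mkvar
from dnmenrich.burden import (
    BurdenModel,
    FilterTag,
    compare_burden,
    exclude_genes,
    per_individual_rate,
    rate_with_ci,
)
from dnmenrich.simulate import (
    preset_cohort_params,
    simulate_cohort,
    simulate_gene_annotation,
    simulate_quad_counts,
)
from dnmenrich.variants import CohortTable, GeneRecord


def _counts_vector(n, total_events):
    """n individuals carrying total_events events, spread one per carrier."""
    v = np.zeros(n, dtype=int)
    v[:total_events] = 1
    return v


class TestRates:
    def test_published_proband_rate(self):
        rate, _ = rate_with_ci(_counts_vector(1902, 307))
        assert round(rate, 2) == 0.16

    def test_published_sibling_rate(self):
        rate, _ = rate_with_ci(_counts_vector(1902, 174))
        assert round(rate, 2) == 0.09

    def test_zero_events(self):
        rate, (lo, hi) = rate_with_ci(np.zeros(50, dtype=int))
        assert rate == 0.0 and lo == 0.0 and hi == 0.0

    def test_ci_ordered_and_nonnegative(self):
        rng = np.random.default_rng(0)
        rate, (lo, hi) = rate_with_ci(rng.poisson(0.2, 500))
        assert 0.0 <= lo <= rate <= hi

    def test_per_individual_rate_counts_zero_carriers(self):
        cohort = CohortTable(
            individuals=[(f"f{i}.p1", "proband", "sim", None) for i in range(10)]
        )
        vs = [mkvar("f0.p1"), mkvar("f1.p1"), mkvar("f1.p1", gene="G2")]
        rate, _ = per_individual_rate(vs, cohort, "proband")
        assert rate == pytest.approx(0.3)

    def test_zero_individuals_raise(self):
        cohort = CohortTable(individuals=[("a.p1", "proband", "x", None)])
        with pytest.raises(ValueError):
            per_individual_rate([], cohort, "sibling")


class TestCompareBurden:
    def _mappings(self, pro, sib, age):
        counts, roles, ages = {}, {}, {}
        for i, (p, s, a) in enumerate(zip(pro, sib, age)):
            counts[f"f{i}.p"] = int(p); roles[f"f{i}.p"] = "proband"; ages[f"f{i}.p"] = float(a)
            counts[f"f{i}.s"] = int(s); roles[f"f{i}.s"] = "sibling"; ages[f"f{i}.s"] = float(a)
        return counts, roles, ages

    def test_identical_groups_give_null_result(self):
        base = [0, 1, 0, 2, 1, 0, 0, 1]
        ages = [30.0, 31, 32, 33, 34, 35, 36, 37]
        counts, roles, a = self._mappings(base, base, ages)
        res = compare_burden(counts, roles, a)
        assert res.group_coef == pytest.approx(0.0, abs=1e-12)
        assert res.group_effect_p > 0.99

    def test_recovers_simulated_group_difference(self):
        pro, sib, age = simulate_quad_counts(1902, 0.16, 0.09, seed=7)
        res = compare_burden(*self._mappings(pro, sib, age))
        assert res.group_effect_p < 1e-4
        assert res.group_coef > 0
        assert round(res.rate_probands, 1) == 0.2 or res.rate_probands > res.rate_siblings

    def test_missing_ages_are_mean_imputed(self):
        pro, sib, age = simulate_quad_counts(200, 0.3, 0.1, seed=3)
        counts, roles, ages = self._mappings(pro, sib, age)
        for k in list(ages)[::3]:
            ages[k] = None
        res = compare_burden(counts, roles, ages)
        assert 0.0 <= res.group_effect_p <= 1.0

    def test_degenerate_model_raises(self):
        counts = {"a.p": 1, "b.s": 1}
        roles = {"a.p": "proband", "b.s": "sibling"}
        ages = {"a.p": 30.0, "b.s": 30.0}
        with pytest.raises(ValueError, match="degenerate"):
            compare_burden(counts, roles, ages)

    def test_poisson_family_agrees_in_direction(self):
        pro, sib, age = simulate_quad_counts(500, 0.3, 0.1, seed=11)
        args = self._mappings(pro, sib, age)
        lin = compare_burden(*args, family="linear")
        poi = compare_burden(*args, family="poisson")
        assert lin.group_effect_p < 0.05 and poi.group_effect_p < 0.05


class TestExcludeGenes:
    def _genes(self):
        return {
            "KEEP": GeneRecord(gene="KEEP", pli=1.0, rvis_pct=0.37),
            "BOUNDARY": GeneRecord(gene="BOUNDARY", pli=0.84, rvis_pct=32.0),
            "TOLERANT": GeneRecord(gene="TOLERANT", pli=0.2, rvis_pct=80.0),
            "NOSCORE": GeneRecord(gene="NOSCORE", pli=1.0, rvis_pct=None),
            "SIG": GeneRecord(gene="SIG", pli=1.0, rvis_pct=1.0, known_significant=True),
        }

    def test_intolerance_filter_with_boundaries(self):
        genes = self._genes()
        vs = [mkvar(f"F{i}.p1", gene=g) for i, g in enumerate(genes)]
        kept = exclude_genes(vs, genes, "not_intolerant")
        assert sorted(v.gene for v in kept) == ["BOUNDARY", "KEEP", "SIG"]

    def test_missing_scores_fail_intolerance(self):
        genes = self._genes()
        vs = [mkvar("A.p1", gene="NOSCORE")]
        assert exclude_genes(vs, genes, "not_intolerant") == []

    def test_known_significant_mode(self):
        genes = self._genes()
        vs = [mkvar("A.p1", gene="SIG"), mkvar("B.p1", gene="KEEP")]
        kept = exclude_genes(vs, genes, "known_significant")
        assert [v.gene for v in kept] == ["KEEP"]

    def test_filters_commute(self):
        genes = simulate_gene_annotation(80, frac_significant=0.2, seed=4)
        vs = [mkvar(f"F{i}.p1", gene=g) for i, g in enumerate(genes)]
        ab = exclude_genes(exclude_genes(vs, genes, "known_significant"), genes, "not_intolerant")
        ba = exclude_genes(exclude_genes(vs, genes, "not_intolerant"), genes, "known_significant")
        assert ab == ba

    def test_matches_hand_enumeration_on_fixture(self):
        genes = simulate_gene_annotation(50, seed=8)
        vs = [mkvar(f"F{i}.p1", gene=g) for i, g in enumerate(list(genes) * 1)][:50]
        kept = exclude_genes(vs, genes, "not_intolerant")
        expected = [
            v
            for v in vs
            if genes[v.gene].pli >= 0.84 and genes[v.gene].rvis_pct <= 32.0
        ]
        assert kept == expected


class TestBurdenModel:
    def test_from_variants_full_pipeline(self):
        params = preset_cohort_params("tiny", seed=21)
        vs, cohort = simulate_cohort(**params)
        genes = simulate_gene_annotation(len(params["per_gene_rates"]), seed=21)
        res = BurdenModel.from_variants(vs, cohort, genes, FilterTag.ALL).fit()
        assert res.n_probands == res.n_siblings == params["n_quads"]
        assert "probands" in res.summary()

    def test_filtered_categories_need_gene_table(self):
        vs, cohort = simulate_cohort(**preset_cohort_params("tiny", seed=1))
        with pytest.raises(ValueError, match="annotation"):
            BurdenModel.from_variants(vs, cohort, None, FilterTag.EXCLUDING_SIGNIFICANT)
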