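"""Record types, TSV I/O, LGD classification, filters and tallies."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import mkvar
from dnmenrich.simulate import preset_cohort_params, simulate_cohort
from dnmenrich.variants import (
    CohortTable,
    Effect,
    Inheritance,
    TableFormatError,
    cohort_size_accounting,
    filter_variants,
    is_lgd,
    normalize_effect,
    read_variant_table,
    tally_inheritance,
    write_variant_table,
)


class TestReadVariantTable:
    def test_parses_published_splice_site_row(self, tanc2_variants):
        v = next(v for v in tanc2_variants if v.individual_id == "CC1.p1")
        assert v.effect is Effect.SPLICE_SITE
        assert v.inheritance is Inheritance.DE_NOVO
        assert v.nt_change == "c.1219+1G>A"

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("individual_id\trole\tcohort\tgene\teffect\tinheritance\n")
        assert read_variant_table(p) == []

    def test_missing_required_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("individual_id\trole\tcohort\tgene\teffect\nA.p1\tproband\tX\tG1\tstopgain\n")
        with pytest.raises(TableFormatError, match="inheritance"):
            read_variant_table(p)

    def test_unparseable_row_reports_row_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "individual_id\trole\tcohort\tgene\teffect\tinheritance\tref_pop_maf\n"
            "A.p1\tproband\tX\tG1\tstopgain\tde_novo\t0.0\n"
            "B.p1\tproband\tX\tG2\tstopgain\tde_novo\tnot_a_number\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_variant_table(p)

    def test_unknown_effect_maps_to_other(self):
        assert normalize_effect("weird_new_consequence") is Effect.OTHER
        assert normalize_effect("stop_gained") is Effect.STOPGAIN
        assert normalize_effect("splice_donor_variant") is Effect.SPLICE_SITE

    def test_write_read_round_trip(self, tmp_path):
        vs, _ = simulate_cohort(**preset_cohort_params("tiny", seed=11))
        assert len(vs) > 0
        p1 = tmp_path / "a.tsv"
        write_variant_table(vs, p1)
        back = read_variant_table(p1)
        assert back == vs
        # second write is byte-identical
        p2 = tmp_path / "b.tsv"
        write_variant_table(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


@pytest.mark.parametrize(
    "effect,expected",
    [
        (Effect.STOPGAIN, True),
        (Effect.FRAMESHIFT, True),
        (Effect.SPLICE_SITE, True),
        (Effect.MISSENSE, False),
        (Effect.SYNONYMOUS, False),
        (Effect.OTHER, False),
    ],
)
def test_is_lgd(effect, expected):
    assert is_lgd(mkvar("A.p1", effect=effect)) is expected


class TestFilterVariants:
    def _fixture(self):
        vs = []
        # 14 clean variants across distinct genes/families
        for i in range(14):
            vs.append(mkvar(f"F{i}.p1", gene=f"G{i}", ref_pop_maf=0.0))
        # 4 common variants above the 0.1% threshold
        for i in range(4):
            vs.append(mkvar(f"C{i}.p1", gene=f"H{i}", ref_pop_maf=0.002))
        # 2 low-confidence calls at a site recurring in two families
        for fam in ("R0", "R1"):
            vs.append(
                mkvar(f"{fam}.p1", gene="REC", nt_change="c.100A>T", low_confidence=True)
            )
        return vs

    def test_hand_enumerated_fixture(self):
        vs = self._fixture()
        kept = filter_variants(vs, 0.001, True)
        assert len(kept) == 14
        assert filter_variants(kept, 0.001, True) == kept  # idempotent

    def test_maf_comparison_is_strict(self):
        at_threshold = mkvar("A.p1", ref_pop_maf=0.001)
        above = mkvar("B.p1", ref_pop_maf=0.0011)
        assert filter_variants([at_threshold, above], 0.001, False) == [at_threshold]

    def test_missing_maf_is_retained(self):
        v = mkvar("A.p1", ref_pop_maf=None)
        assert filter_variants([v], 0.001, True) == [v]

    def test_genuine_recurrence_without_low_confidence_is_kept(self):
        # the same splice-site hit seen independently in two families
        vs = [
            mkvar("X.p1", gene="TANC2", nt_change="c.1219+1G>A"),
            mkvar("Y.p1", gene="TANC2", nt_change="c.1219+1G>A"),
        ]
        assert filter_variants(vs, 0.001, True) == vs

    def test_recurrence_within_one_family_is_not_recurrent(self):
        vs = [
            mkvar("X.p1", gene="G", nt_change="c.1A>T", low_confidence=True),
            mkvar("X.s1", gene="G", nt_change="c.1A>T", low_confidence=True),
        ]
        assert filter_variants(vs, 0.001, True) == vs

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        mafs=st.lists(st.one_of(st.none(), st.floats(0, 1)), min_size=0, max_size=30),
        thr=st.floats(0, 1),
    )
    def test_never_grows_and_idempotent(self, mafs, thr):
        vs = [mkvar(f"F{i}.p1", gene=f"G{i}", ref_pop_maf=m) for i, m in enumerate(mafs)]
        once = filter_variants(vs, thr, True)
        assert len(once) <= len(vs)
        assert filter_variants(once, thr, True) == once


class TestTallyInheritance:
    def test_published_lgd_tally(self, tanc2_variants):
        tally = tally_inheritance(tanc2_variants)
        assert tally[Inheritance.DE_NOVO] == 11
        assert tally[Inheritance.PATERNAL] + tally[Inheritance.MATERNAL] == 4
        assert tally[Inheritance.UNDETERMINED] == 1
        n_lgd = sum(1 for v in tanc2_variants if is_lgd(v))
        assert sum(tally.values()) == n_lgd == 16

    def test_empty_input(self):
        assert all(c == 0 for c in tally_inheritance([]).values())

    def test_matches_known_composition(self):
        vs = (
            [mkvar(f"A{i}.p1", inheritance=Inheritance.DE_NOVO) for i in range(3)]
            + [mkvar(f"B{i}.p1", inheritance=Inheritance.PATERNAL) for i in range(2)]
            + [mkvar("C.p1", effect=Effect.MISSENSE, inheritance=Inheritance.DE_NOVO)]
        )
        tally = tally_inheritance(vs)
        assert tally[Inheritance.DE_NOVO] == 3 and tally[Inheritance.PATERNAL] == 2
        assert sum(tally.values()) == 5  # missense row does not qualify


class TestCohortSizeAccounting:
    def test_published_all_lgd_accounting(self, tanc2_variants, tanc2_cohorts):
        assert cohort_size_accounting(tanc2_variants, tanc2_cohorts) == (13, 17567)

    def test_published_de_novo_accounting(self, tanc2_variants, tanc2_cohorts):
        n, total = cohort_size_accounting(
            tanc2_variants, tanc2_cohorts, restrict_inheritance=[Inheritance.DE_NOVO]
        )
        assert total == 16113
        assert n == 10  # the eleventh de novo carrier's cohort has no stated size

    def test_single_cohort_deduplication(self):
        vs = [mkvar(f"F{i}.p1", cohort="X") for i in range(3)]
        cohorts = CohortTable(cohort_sizes={"X": 100})
        assert cohort_size_accounting(vs, cohorts) == (3, 100)

    def test_total_invariant_to_carrier_duplication(self):
        cohorts = CohortTable(cohort_sizes={"X": 100, "Y": 250})
        base = [mkvar("A.p1", cohort="X"), mkvar("B.p1", cohort="Y")]
        extra = base + [mkvar(f"A{i}.p1", cohort="X", gene=f"G{i}") for i in range(5)]
        assert cohort_size_accounting(base, cohorts)[1] == 350
        assert cohort_size_accounting(extra, cohorts)[1] == 350
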