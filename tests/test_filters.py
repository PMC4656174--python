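"""The four inheritance filters and the trio family mode."""

import random

import pytest

from oracles import (
    oracle_dominant_nucleotide,
    oracle_dominant_unit,
    oracle_family_dominant,
    oracle_recessive_nucleotide,
    oracle_recessive_unit,
    random_cohort_fixture,
    to_sample_sets,
)
from vcfsieve.annotation import AnnotationUnit
from vcfsieve.filters import (
    annotate_cohort,
    dominant_nucleotide,
    dominant_unit,
    family_dominant,
    family_recessive,
    recessive_nucleotide,
    recessive_unit,
)
from vcfsieve.model import (
    Cohort,
    Role,
    RoleError,
    SampleVariantSet,
    UnannotatedVariantError,
    Variant,
    Zygosity,
)
from vcfsieve.pendet import explicit_thresholds

from conftest import HET, HOM, V, case, control

v1 = V(pos=100)
v2 = V(pos=200)
v3 = V(pos=300)


def th(n_c, c_g, n_s=None):
    return explicit_thresholds(n_c, c_g, n_s if n_s is not None else max(n_c, 1))


def geneG():
    return AnnotationUnit("G", "chr1", [(50, 250)], "t")


def geneH():
    return AnnotationUnit("H", "chr1", [(260, 400)], "t")


class TestDominantNucleotide:
    def test_shared_variant_survives_control_filtering(self):
        cohort = Cohort(
            cases=[case("A", {v1: HET, v2: HET}), case("B", {v1: HOM, v3: HET})],
            controls=[control("C", {v3: HET})],
        )
        assert dominant_nucleotide(cohort, th(2, 0, 2)).variant_set() == {v1}
        assert dominant_nucleotide(cohort, th(1, 0, 2)).variant_set() == {v1, v2}

    def test_single_case_no_controls_is_identity(self):
        cohort = Cohort(cases=[case("A", {v1: HET, v2: HOM})])
        assert dominant_nucleotide(cohort, th(1, 0, 1)).variant_set() == {v1, v2}

    def test_counts_reported_per_row(self):
        cohort = Cohort(
            cases=[case("A", {v1: HET}), case("B", {v1: HOM})],
            controls=[control("C", {v1: HET}), control("D", {})],
        )
        (row,) = dominant_nucleotide(cohort, th(2, 1, 2)).rows
        assert (row.case_count, row.control_count) == (2, 1)

    def test_full_sharing_no_controls_equals_set_intersection(self, rng):
        for _ in range(25):
            cases, _, _, _ = random_cohort_fixture(rng, max_samples=5, max_variants=60, max_units=5)
            cohort = Cohort(cases=to_sample_sets(cases, [])[0])
            got = dominant_nucleotide(cohort, th(len(cases), 0, len(cases)))
            expected = set.intersection(*(set(c) for c in cases))
            assert got.variant_set() == expected


class TestRecessiveNucleotide:
    def test_control_het_does_not_filter(self):
        cohort = Cohort(
            cases=[case("A", {v1: HOM, v2: HET})],
            controls=[control("C", {v1: HET})],
        )
        assert recessive_nucleotide(cohort, th(1, 0)).variant_set() == {v1}

    def test_control_hom_filters(self):
        cohort = Cohort(
            cases=[case("A", {v1: HOM})], controls=[control("C", {v1: HOM})]
        )
        assert recessive_nucleotide(cohort, th(1, 0)).variant_set() == set()

    def test_case_het_never_supports(self):
        cohort = Cohort(cases=[case("A", {v1: HET})])
        assert recessive_nucleotide(cohort, th(1, 0)).variant_set() == set()

    def test_retained_subset_of_case_homozygotes(self, rng):
        for _ in range(25):
            cases, controls, _, _ = random_cohort_fixture(rng, max_samples=6, max_variants=80, max_units=5)
            cs, xs = to_sample_sets(cases, controls)
            cohort = Cohort(cs, xs)
            got = recessive_nucleotide(cohort, th(1, 1, len(cases))).variant_set()
            homs = {v for c in cases for v, z in c.items() if z is HOM}
            assert got <= homs


class TestRecessiveUnit:
    def _acohort(self, cases, controls, units):
        return annotate_cohort(Cohort(cases, controls), units)

    def test_compound_het_unit_retained_single_het_unit_not(self):
        ac = self._acohort(
            [case("A", {v1: HET, v2: HET, v3: HET})], [], [geneG(), geneH()]
        )
        res = recessive_unit(ac, th(1, 0))
        assert [k for k, _ in res.retained_units] == [("t", "G")]
        assert res.variant_set() == {v1, v2}

    def test_comphet_control_filters_whole_unit(self):
        ac = self._acohort(
            [case("A", {v1: HET, v2: HET})],
            [control("C", {v1: HET, v2: HET})],
            [geneG()],
        )
        assert recessive_unit(ac, th(1, 0)).retained_units == []

    def test_single_het_control_filters_nothing(self):
        ac = self._acohort(
            [case("A", {v1: HET, v2: HET})],
            [control("C", {v1: HET})],
            [geneG()],
        )
        res = recessive_unit(ac, th(1, 0))
        assert [k for k, _ in res.retained_units] == [("t", "G")]
        assert res.variant_set() == {v1, v2}

    def test_hom_control_filters_that_variant_only(self):
        # control hom at v1 removes v1 everywhere; case stays comphet via v2+v3
        ac = self._acohort(
            [case("A", {v1: HET, v2: HET, v3: HET})],
            [control("C", {v1: HOM})],
            [AnnotationUnit("G", "chr1", [(50, 400)], "t")],
        )
        res = recessive_unit(ac, th(1, 0))
        assert res.variant_set() == {v2, v3}

    def test_multiallelic_site_counts_as_compound_het(self):
        """Two HET observations decomposed from one multi-allelic site are
        two distinct variants, hence a qualifying compound heterozygote."""
        a = V(pos=100, alt="G")
        b = V(pos=100, alt="T")
        ac = self._acohort([case("A", {a: HET, b: HET})], [], [geneG()])
        assert [k for k, _ in recessive_unit(ac, th(1, 0)).retained_units] == [("t", "G")]

    def test_unannotated_variant_is_an_error(self):
        bad = V(chrom="chr9", pos=5)
        ac = self._acohort([case("A", {bad: HOM})], [], [geneG()])
        with pytest.raises(UnannotatedVariantError, match="annotate"):
            recessive_unit(ac, th(1, 0))

    def test_shared_units_not_shared_nucleotides(self):
        ac = self._acohort(
            [case("A", {v1: HOM}), case("B", {v2: HOM})], [], [geneG()]
        )
        res = recessive_unit(ac, th(2, 0, 2))
        assert [k for k, n in res.retained_units] == [("t", "G")]
        assert res.retained_units[0][1] == 2


class TestDominantUnit:
    def _acohort(self, cases, controls, units):
        return annotate_cohort(Cohort(cases, controls), units)

    def test_any_control_variant_filters(self):
        ac = self._acohort(
            [case("A", {v1: HET})], [control("C", {v1: HOM})], [geneG()]
        )
        assert dominant_unit(ac, th(1, 0)).retained_units == []

    def test_unit_shared_through_different_nucleotides(self):
        cases = [case("A", {v1: HET}), case("B", {v2: HET})]
        ac = self._acohort(cases, [], [geneG()])
        res = dominant_unit(ac, th(2, 0, 2))
        assert [k for k, _ in res.retained_units] == [("t", "G")]
        # contrast: at nucleotide level nothing is shared
        nuc = dominant_nucleotide(Cohort([case("A", {v1: HET}), case("B", {v2: HET})]), th(2, 0, 2))
        assert nuc.variant_set() == set()


class TestFamily:
    def test_de_novo_rule(self):
        child = SampleVariantSet("kid", Role.CHILD, {v1: HET, v2: HOM, v3: HET})
        mother = SampleVariantSet("mum", Role.MOTHER, {v1: HET})
        father = SampleVariantSet("dad", Role.FATHER, {})
        res = family_dominant(child, mother, father)
        assert res.variant_set() == {v3}

    def test_without_parents_keeps_all_child_hets(self):
        child = SampleVariantSet("kid", Role.CHILD, {v1: HET, v2: HOM})
        with pytest.warns(UserWarning, match="parents"):
            res = family_dominant(child)
        assert res.variant_set() == {v1}

    def test_homozygous_child_variant_is_not_de_novo(self):
        child = SampleVariantSet("kid", Role.CHILD, {v1: HOM})
        with pytest.warns(UserWarning):
            assert family_dominant(child).variant_set() == set()

    def test_unrelated_roles_rejected(self):
        child = SampleVariantSet("kid", Role.CHILD, {v1: HET})
        stranger = SampleVariantSet("s", Role.CONTROL, {})
        with pytest.raises(RoleError, match="unrelated"):
            family_dominant(child, stranger, None)
        with pytest.raises(RoleError, match="CHILD"):
            family_dominant(SampleVariantSet("s", Role.CASE, {}))

    def test_family_recessive_extension(self):
        child = SampleVariantSet("kid", Role.CHILD, {v1: HOM, v2: HOM, v3: HET})
        mother = SampleVariantSet("mum", Role.MOTHER, {v1: HET, v2: HOM})
        father = SampleVariantSet("dad", Role.FATHER, {v1: HET})
        res = family_recessive(child, mother, father)
        assert res.variant_set() == {v1}


class TestOracleAgreementAndMonotonicity:
    def test_filters_agree_with_brute_force(self, rng):
        for _ in range(60):
            cases, controls, units, _ = random_cohort_fixture(
                rng, max_samples=8, max_variants=120, max_units=12
            )
            cs, xs = to_sample_sets(cases, controls)
            cohort = Cohort(cs, xs)
            n_c = rng.randint(1, len(cases))
            c_g = rng.randint(0, max(0, len(controls)))
            t = explicit_thresholds(n_c, c_g, len(cases))
            assert dominant_nucleotide(cohort, t).variant_set() == oracle_dominant_nucleotide(cases, controls, n_c, c_g)
            assert recessive_nucleotide(cohort, t).variant_set() == oracle_recessive_nucleotide(cases, controls, n_c, c_g)
            ac = annotate_cohort(cohort, units)
            got_r = recessive_unit(ac, t)
            exp_units, exp_variants = oracle_recessive_unit(cases, controls, units, n_c, c_g)
            assert {k for k, _ in got_r.retained_units} == exp_units
            assert got_r.variant_set() == exp_variants
            got_d = dominant_unit(ac, t)
            exp_units, exp_variants = oracle_dominant_unit(cases, controls, units, n_c, c_g)
            assert {k for k, _ in got_d.retained_units} == exp_units
            assert got_d.variant_set() == exp_variants

    def test_family_agrees_with_brute_force(self, rng):
        for _ in range(40):
            cases, controls, units, pool = random_cohort_fixture(rng, max_samples=3, max_variants=80, max_units=6)
            obs = cases[0]
            mother = controls[0] if len(controls) > 0 else None
            father = controls[1] if len(controls) > 1 else None
            child_s = SampleVariantSet("kid", Role.CHILD, dict(obs))
            mother_s = SampleVariantSet("m", Role.MOTHER, dict(mother)) if mother is not None else None
            father_s = SampleVariantSet("f", Role.FATHER, dict(father)) if father is not None else None
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = family_dominant(child_s, mother_s, father_s).variant_set()
            assert got == oracle_family_dominant(obs, mother, father)

    def test_adding_a_control_never_enlarges_retained_sets(self, rng):
        for _ in range(30):
            cases, controls, units, pool = random_cohort_fixture(
                rng, max_samples=6, max_variants=80, max_units=8
            )
            from oracles import random_obs

            extra = random_obs(rng, pool, max(1, len(pool) // 2))
            n_c = rng.randint(1, len(cases))
            c_g = rng.randint(0, len(controls))
            t = explicit_thresholds(n_c, c_g, len(cases))
            for flt, unit_level in [
                (dominant_nucleotide, False),
                (recessive_nucleotide, False),
                (dominant_unit, True),
                (recessive_unit, True),
            ]:
                cs, xs = to_sample_sets(cases, controls)
                cs2, xs2 = to_sample_sets(cases, controls + [extra])
                if unit_level:
                    before = flt(annotate_cohort(Cohort(cs, xs), units), t)
                    after = flt(annotate_cohort(Cohort(cs2, xs2), units), t)
                    assert {k for k, _ in after.retained_units} <= {
                        k for k, _ in before.retained_units
                    }
                else:
                    before = flt(Cohort(cs, xs), t)
                    after = flt(Cohort(cs2, xs2), t)
                assert after.variant_set() <= before.variant_set()

    def test_tightening_thresholds_never_enlarges_retained_sets(self, rng):
        for _ in range(30):
            cases, controls, units, _ = random_cohort_fixture(
                rng, max_samples=6, max_variants=80, max_units=8
            )
            cs, xs = to_sample_sets(cases, controls)
            cohort = Cohort(cs, xs)
            n_c = rng.randint(1, len(cases))
            c_g = rng.randint(0, len(controls))
            loose = explicit_thresholds(n_c, c_g + 1, len(cases))
            tight_nc = explicit_thresholds(min(n_c + 1, len(cases)), c_g + 1, len(cases))
            tight_cg = explicit_thresholds(n_c, c_g, len(cases))
            for flt in (dominant_nucleotide, recessive_nucleotide):
                base = flt(cohort, loose).variant_set()
                assert flt(cohort, tight_nc).variant_set() <= base
                assert flt(cohort, tight_cg).variant_set() <= base
            ac = annotate_cohort(cohort, units)
            for flt in (dominant_unit, recessive_unit):
                base = {k for k, _ in flt(ac, loose).retained_units}
                assert {k for k, _ in flt(ac, tight_nc).retained_units} <= base
                assert {k for k, _ in flt(ac, tight_cg).retained_units} <= base
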