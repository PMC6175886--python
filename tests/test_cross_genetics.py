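"""Cross engine: gametes, offspring distributions, dosage ratios, complementation."""

import numpy as np
import pytest
from scipy import stats

from polyswitch.cross_genetics import (
    FUNCTIONAL,
    NULL,
    XO,
    XX,
    ComplementationMatrix,
    CrossDesign,
    TransitivityError,
    complementation_groups,
    cross,
    dosage_ratio,
    enumerate_panel,
    functional_dosage,
    gametes,
    genotype,
    hybrid_panel,
    intraspecific_panel,
    morph_regime,
    pacificus_mutant,
    sample_cross,
    self_cross,
    wildtype,
)
from polyswitch.synthetic_data import DEFAULT_COMPLEMENTATION, gen_complementation_matrix


class TestGametes:
    def test_xo_male_x_null_transmission(self):
        male = genotype(XO, eud_1=(NULL,), seud_1=(FUNCTIONAL, FUNCTIONAL))
        dist = gametes(male)
        x_bearing = {g: p for g, p in dist.items() if g.has_x}
        nullo = {g: p for g, p in dist.items() if not g.has_x}
        assert sum(x_bearing.values()) == pytest.approx(0.5)
        assert sum(nullo.values()) == pytest.approx(0.5)
        for g in x_bearing:
            assert g.allele_map["eud-1"] == NULL
        for g in nullo:
            assert "eud-1" not in g.allele_map

    def test_homozygote_single_gamete_class(self):
        dist = gametes(wildtype("P. pacificus"))
        assert len(dist) == 1 and next(iter(dist.values())) == pytest.approx(1.0)

    def test_autosomal_heterozygote_half_half(self):
        het = pacificus_mutant(seud_1=(FUNCTIONAL, NULL))
        dist = gametes(het)
        assert len(dist) == 2
        assert all(p == pytest.approx(0.5) for p in dist.values())

    def test_distribution_normalised(self):
        parent = genotype(
            XX, eud_1=(FUNCTIONAL, NULL), seud_1=(FUNCTIONAL, NULL)
        )
        assert sum(gametes(parent).values()) == pytest.approx(1.0)

    def test_paralog_co_transmission_option(self):
        pex = genotype(
            XX,
            eud_1=(FUNCTIONAL, FUNCTIONAL),
            **{"seud_11": (FUNCTIONAL, NULL), "seud_12": (NULL, FUNCTIONAL)},
        )
        free = gametes(pex)
        linked = gametes(pex, co_transmit=[("seud-1.1", "seud-1.2")])
        assert len(free) == 4  # independent assortment
        assert len(linked) == 2  # haplotypes travel together
        for g in linked:
            pair = (g.allele_map["seud-1.1"], g.allele_map["seud-1.2"])
            assert pair in ((FUNCTIONAL, NULL), (NULL, FUNCTIONAL))


class TestCross:
    def test_wt_by_wt_dosage_classes(self):
        dist = cross(wildtype("P. pacificus"), wildtype("P. pacificus", sex=XO))
        for child, p in dist.items():
            E, S = dosage_ratio(child)
            if child.sex == XX:
                assert (E, S) == (2, 2)
            else:
                assert (E, S) == (1, 2)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_mutant_father_transmits_autosome_not_x(self):
        """A seud-1 mutant father passes the autosomal null to all F1; F1 males
        carry only the maternal X."""
        father = genotype(XO, eud_1=(FUNCTIONAL,), seud_1=(NULL, NULL))
        mother = wildtype("P. pacificus")
        for child in cross(mother, father):
            assert NULL in child.states("seud-1")
            if child.sex == XO:
                assert child.states("eud-1") == (FUNCTIONAL,)  # maternal X only

    def test_probabilities_sum_to_one(self):
        mother = genotype(XX, eud_1=(FUNCTIONAL, NULL), seud_1=(FUNCTIONAL, NULL))
        father = genotype(XO, eud_1=(NULL,), seud_1=(FUNCTIONAL, NULL))
        dist = cross(mother, father)
        assert sum(dist.values()) == pytest.approx(1.0)
        assert all(p >= 0 for p in dist.values())

    def test_sex_ratio_half_half(self):
        dist = cross(wildtype("P. pacificus"), wildtype("P. pacificus", sex=XO))
        p_male = sum(p for g, p in dist.items() if g.sex == XO)
        assert p_male == pytest.approx(0.5)

    def test_selfing_all_xx_and_mendelian_ratio(self):
        het = pacificus_mutant(seud_1=(FUNCTIONAL, NULL))
        dist = self_cross(het)
        assert all(g.sex == XX for g in dist)
        by_s = {}
        for g, p in dist.items():
            s = functional_dosage(g, "seud-1")
            by_s[s] = by_s.get(s, 0.0) + p
        assert by_s[2] == pytest.approx(0.25)
        assert by_s[1] == pytest.approx(0.5)
        assert by_s[0] == pytest.approx(0.25)

    def test_reciprocal_crosses_same_autosomal_dosage(self):
        a_mother = pacificus_mutant(seud_1=(NULL, NULL))
        a_father = wildtype("P. pacificus", sex=XO)
        b_mother = wildtype("P. pacificus")
        b_father = genotype(XO, eud_1=(FUNCTIONAL,), seud_1=(NULL, NULL))

        def autosomal_dist(dist):
            out = {}
            for g, p in dist.items():
                s = functional_dosage(g, "seud-1")
                out[s] = out.get(s, 0.0) + p
            return out

        assert autosomal_dist(cross(a_mother, a_father)) == pytest.approx(
            autosomal_dist(cross(b_mother, b_father))
        )

    def test_f1_dosage_additivity(self):
        """Offspring (E, S) equals the sum of the two gamete contributions."""
        mother = genotype(XX, eud_1=(FUNCTIONAL, NULL), seud_1=(FUNCTIONAL, NULL))
        father = wildtype("P. exspectatus", sex=XO)
        for gm, pm in gametes(mother).items():
            for gf, pf in gametes(father).items():
                from polyswitch.cross_genetics import _combine

                child = _combine(gm, gf)
                e_expect = sum(
                    1
                    for g in (gm, gf)
                    for n, s in g.alleles
                    if n == "eud-1" and s == FUNCTIONAL
                )
                s_expect = sum(
                    1
                    for g in (gm, gf)
                    for n, s in g.alleles
                    if n.startswith("seud-1") and s == FUNCTIONAL
                )
                assert dosage_ratio(child) == (e_expect, s_expect)

    def test_monte_carlo_matches_enumeration(self, rng):
        mother = genotype(XX, eud_1=(FUNCTIONAL, NULL), seud_1=(FUNCTIONAL, NULL))
        father = genotype(XO, eud_1=(NULL,), seud_1=(FUNCTIONAL, NULL))
        exact = cross(mother, father)
        n = 10_000
        sample = sample_cross(mother, father, n, rng)
        observed = [sample.get(g, 0) for g in exact]
        expected = [p * n for p in exact.values()]
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.001


class TestDosage:
    def test_wildtype_reference(self):
        assert dosage_ratio(wildtype("P. pacificus")) == (2, 2)
        assert dosage_ratio(wildtype("P. exspectatus")) == (2, 4)

    def test_hybrid_f1_female_wt(self):
        dist = cross(wildtype("P. pacificus"), wildtype("P. exspectatus", sex=XO))
        females = [g for g in dist if g.sex == XX]
        assert all(dosage_ratio(g) == (2, 3) for g in females)

    def test_hybrid_f1_from_double_mutant_mother(self):
        mother = pacificus_mutant(eud_1=(NULL, NULL), seud_1=(NULL, NULL))
        dist = cross(mother, wildtype("P. exspectatus", sex=XO))
        females = [g for g in dist if g.sex == XX]
        assert all(dosage_ratio(g) == (1, 2) for g in females)


class TestPanels:
    def test_hybrid_panel_reproduces_four_ratio_classes(self):
        table = enumerate_panel(hybrid_panel())
        classes = set(zip(table["E"], table["S"]))
        assert classes == {(2, 3), (1, 3), (2, 2), (1, 2)}
        assert np.allclose(
            table.groupby("design")["probability"].sum(), 1.0
        )

    def test_intraspecific_panel_flags_almost_all_eu(self):
        table = enumerate_panel(intraspecific_panel())
        flagged = table[(table["E"] == 2) & (table["S"] == 1)]
        assert not flagged.empty
        assert (flagged["regime"] == "almost all-Eu").all()

    def test_empty_design_list(self):
        assert enumerate_panel([]).empty

    def test_regime_boundaries(self):
        from polyswitch.cross_genetics import DosageRatio

        assert morph_regime(DosageRatio(2, 0)) == "all-Eu"
        assert morph_regime(DosageRatio(0, 2)) == "all-St"
        assert morph_regime(DosageRatio(2, 2)) == "graded"
        with pytest.raises(ValueError):
            morph_regime(DosageRatio(0, 0))


class TestComplementation:
    def test_default_fixture_three_groups(self):
        groups = complementation_groups(gen_complementation_matrix())
        assert len(groups) == 3
        sizes = sorted(len(g) for g in groups)
        assert sizes == [2, 2, 3]
        assert ("iub7", "iub8") in [tuple(sorted(g)) for g in groups]

    def test_all_complement_gives_singletons(self):
        mutants = [f"m{i}" for i in range(7)]
        matrix = ComplementationMatrix.from_pairs(mutants, [])
        groups = complementation_groups(matrix)
        assert len(groups) == 7 and all(len(g) == 1 for g in groups)

    def test_intransitive_matrix_rejected_with_triples(self):
        matrix = ComplementationMatrix.from_pairs(
            ["a", "b", "c"], [("a", "b"), ("b", "c")]  # a~b, b~c, but a complements c
        )
        with pytest.raises(TransitivityError) as err:
            complementation_groups(matrix)
        assert err.value.triples  # offending triple(s) reported
        (a, w, c) = err.value.triples[0]
        assert {a, c} == {"a", "c"} and w == "b"

    def test_matrix_symmetric_and_reflexive(self):
        matrix = gen_complementation_matrix(DEFAULT_COMPLEMENTATION)
        for a in matrix.mutants:
            assert matrix.fails_to_complement(a, a)
            for b in matrix.mutants:
                assert matrix.fails_to_complement(a, b) == matrix.fails_to_complement(b, a)


class TestGenotypeValidation:
    def test_x_slot_counts_enforced(self):
        with pytest.raises(ValueError):
            genotype(XO, eud_1=(FUNCTIONAL, FUNCTIONAL))  # males are hemizygous
        with pytest.raises(ValueError):
            genotype(XX, eud_1=(FUNCTIONAL,))

    def test_fathers_must_be_male(self):
        with pytest.raises(ValueError):
            cross(wildtype("P. pacificus"), wildtype("P. pacificus"))
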