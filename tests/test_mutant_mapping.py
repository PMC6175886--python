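"""Mapping cascade: filtering, background subtraction, impact calls, intersection."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

from oracles import oracle_impact
from polyswitch.models import GeneModel, GenomeAnnotation, VariantRecord, VariantTable
from polyswitch.mutant_mapping import (
    MappingInputs,
    ReferenceMismatchError,
    classify_impact,
    classify_table,
    harmful_subset,
    intersect_candidates,
    quality_filter,
    run_mapping,
    subtract_shared,
)
from polyswitch.synthetic_data import ScreenFixtureParams, gen_reference, gen_screen_dataset


def _v(pos, ref="A", alt="T", qual=50.0, depth=20, contig="c1", strain="s"):
    return VariantRecord(contig, pos, ref, alt, qual, depth, strain)


class TestQualityFilter:
    def test_zero_thresholds_identity(self):
        table = VariantTable(records=(_v(1), _v(2, qual=0, depth=0)))
        assert quality_filter(table, 0, 0).records == table.records

    def test_all_below_threshold_empty(self):
        table = VariantTable(records=(_v(1, qual=5), _v(2, qual=10)))
        assert len(quality_filter(table, 20, 5)) == 0

    def test_exact_retained_subset(self):
        keep1, keep2 = _v(1, qual=20, depth=5), _v(4, qual=55, depth=30)
        drop_q, drop_d = _v(2, qual=19.9, depth=50), _v(3, qual=50, depth=4)
        table = VariantTable(records=(keep1, drop_q, drop_d, keep2))
        assert quality_filter(table, 20, 5).records == (keep1, keep2)

    def test_idempotent(self):
        table = VariantTable(records=(_v(1, qual=25), _v(2, qual=15)))
        once = quality_filter(table, 20, 5)
        assert quality_filter(once, 20, 5).records == once.records


class TestSubtractShared:
    def test_no_backgrounds_identity(self):
        table = VariantTable(records=(_v(1), _v(2)))
        assert subtract_shared(table, []).records == table.records

    def test_self_subtraction_empty(self):
        table = VariantTable(records=(_v(1), _v(2)))
        assert len(subtract_shared(table, [table])) == 0

    def test_enumerated_subset(self):
        v1, v2, v3 = _v(1), _v(2), _v(3)
        bg = VariantTable(records=(_v(2, strain="bg"),))  # same site, other strain
        assert subtract_shared(VariantTable(records=(v1, v2, v3)), [bg]).records == (v1, v3)

    def test_order_independent_over_backgrounds(self):
        target = VariantTable(records=tuple(_v(i) for i in range(1, 8)))
        bg1 = VariantTable(records=(_v(2), _v(5)))
        bg2 = VariantTable(records=(_v(3),))
        assert (
            subtract_shared(target, [bg1, bg2]).records
            == subtract_shared(target, [bg2, bg1]).records
            == subtract_shared(subtract_shared(target, [bg1]), [bg2]).records
        )


class TestClassifyImpact:
    """A hand-built plus-strand gene: CDS = ATG AAA GAA TAA at positions 11..22."""

    genome = {"c1": "GGGGGGGGGG" + "ATGAAAGAATAA" + "GGGGGGGGGG"}
    gene = GeneModel("g1", "c1", "+", ((11, 22),), ((11, 22),))
    ann = GenomeAnnotation([gene])

    def test_nonsense_by_code(self):
        # codon 2 AAA -> TAA at its first base (position 14)
        call = classify_impact(_v(14, "A", "T"), self.ann, self.genome)
        assert call.impact == "nonsense" and call.aa_change == "K2*"

    def test_synonymous_by_code(self):
        # codon 3 GAA -> GAG at its third base (position 19)
        call = classify_impact(_v(19, "A", "G"), self.ann, self.genome)
        assert call.impact == "synonymous" and call.codon_index == 3

    def test_missense_by_code(self):
        call = classify_impact(_v(12, "T", "C"), self.ann, self.genome)  # ATG -> ACG
        assert call.impact == "missense" and call.aa_change == "M1T"

    def test_far_from_genes_noncoding(self):
        call = classify_impact(_v(3, "G", "A"), self.ann, self.genome)
        assert call.impact == "noncoding" and call.gene_id is None

    def test_ref_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            classify_impact(_v(11, "C", "T"), self.ann, self.genome)

    def test_splice_window(self):
        # two exons with intron 17..46 (GT...AG)
        genome = {"c2": "GGGGGGGGGG" + "ATGAAA" + "GT" + "C" * 26 + "AG" + "GAATAA" + "GGGG"}
        gene = GeneModel("g2", "c2", "+", ((11, 16), (47, 52)), ((11, 16), (47, 52)))
        ann = GenomeAnnotation([gene])
        donor = classify_impact(
            VariantRecord("c2", 17, "G", "A"), ann, genome
        )
        acceptor = classify_impact(
            VariantRecord("c2", 46, "G", "C"), ann, genome
        )
        deep = classify_impact(VariantRecord("c2", 30, "C", "T"), ann, genome)
        assert donor.impact == acceptor.impact == "splice_site"
        assert deep.impact == "noncoding"

    def test_agrees_with_full_cds_rebuild_oracle(self, small_dataset):
        """Single-codon classification equals translating the whole mutant CDS."""
        checked = 0
        for table in (small_dataset.tables["mutant_a"], small_dataset.tables["mutant_b"]):
            for rec in table:
                call = classify_impact(rec, small_dataset.annotation, small_dataset.genome)
                genes = small_dataset.annotation.genes_at(rec.contig, rec.position)
                if call.gene_id is not None:
                    gene = small_dataset.annotation[call.gene_id]
                    assert call.impact == oracle_impact(rec, gene, small_dataset.genome)
                    checked += 1
                elif genes:
                    assert oracle_impact(rec, genes[0], small_dataset.genome) == "noncoding"
        assert checked >= 2  # at least the two planted lesions are coding

    def test_minus_strand_oracle_agreement(self, small_dataset):
        """Every position of one minus-strand gene classifies like the oracle."""
        genome, ann = small_dataset.genome, small_dataset.annotation
        gene = next(g for g in ann.genes if g.strand == "-")
        s, e = gene.cds[0]
        for pos in range(s, min(s + 30, e + 1)):
            ref = genome[gene.contig][pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                rec = VariantRecord(gene.contig, pos, ref, alt)
                call = classify_impact(rec, ann, genome)
                assert call.impact == oracle_impact(rec, gene, genome)


class TestHarmfulAndIntersect:
    def _call(self, gene, pos, impact, strain="s"):
        from polyswitch.mutant_mapping import ImpactCall

        return ImpactCall(_v(pos, strain=strain), gene, impact)

    def test_all_synonymous_empty(self):
        calls = [self._call("g1", i, "synonymous") for i in range(1, 4)]
        assert harmful_subset(calls) == []

    def test_mixed_subset_and_order_invariance(self):
        calls = [
            self._call("g1", 1, "nonsense"),
            self._call("g1", 2, "synonymous"),
            self._call("g2", 3, "missense"),
            self._call(None, 4, "noncoding"),
            self._call("g3", 5, "splice_site"),
        ]
        kept = harmful_subset(calls)
        assert {c.variant.position for c in kept} == {1, 3, 5}
        reversed_kept = harmful_subset(list(reversed(calls)))
        assert {c.variant.key for c in reversed_kept} == {c.variant.key for c in kept}

    def test_empty_inputs_no_candidates(self):
        assert intersect_candidates([], []).qualifying_genes == ()

    def test_identical_variant_in_both_alleles_not_qualifying(self):
        a = [self._call("g1", 10, "missense", "A")]
        b = [self._call("g1", 10, "missense", "B")]  # same site, same change
        report = intersect_candidates(a, b)
        assert report.qualifying_genes == ()
        assert report["g1"].qualifying is False

    def test_distinct_lesions_qualify(self):
        a = [self._call("g1", 10, "nonsense", "A")]
        b = [self._call("g1", 99, "nonsense", "B")]
        assert intersect_candidates(a, b).qualifying_genes == ("g1",)

    def test_gene_hit_in_one_allele_only_not_qualifying(self):
        a = [self._call("g1", 10, "nonsense", "A"), self._call("g2", 20, "missense", "A")]
        b = [self._call("g1", 99, "missense", "B")]
        assert intersect_candidates(a, b).qualifying_genes == ("g1",)


class TestEndToEnd:
    def test_small_fixture_truth_recovery(self, small_dataset):
        result = run_mapping(
            MappingInputs(
                mutant_a=small_dataset.tables["mutant_a"],
                mutant_b=small_dataset.tables["mutant_b"],
                backgrounds=[small_dataset.tables["parental"], small_dataset.tables["marker"]],
                annotation=small_dataset.annotation,
                genome=small_dataset.genome,
            )
        )
        assert result.report.qualifying_genes == (small_dataset.truth.causal_gene,)
        reported = result.report[small_dataset.truth.causal_gene].positions
        planted = tuple(sorted(l.position for l in small_dataset.truth.lesions.values()))
        assert reported == planted

    def test_candidates_non_increasing_with_backgrounds(self, small_dataset):
        tables = small_dataset.tables

        def n_candidates(backgrounds):
            res = run_mapping(
                MappingInputs(
                    mutant_a=tables["mutant_a"],
                    mutant_b=tables["mutant_b"],
                    backgrounds=backgrounds,
                    annotation=small_dataset.annotation,
                    genome=small_dataset.genome,
                )
            )
            return len(res.report.qualifying_genes)

        n0 = n_candidates([])
        n1 = n_candidates([tables["parental"]])
        n2 = n_candidates([tables["parental"], tables["marker"]])
        assert n0 >= n1 >= n2 == 1

    def test_stage_counts_monotone(self, small_dataset):
        result = run_mapping(
            MappingInputs(
                mutant_a=small_dataset.tables["mutant_a"],
                mutant_b=small_dataset.tables["mutant_b"],
                backgrounds=[small_dataset.tables["parental"], small_dataset.tables["marker"]],
                annotation=small_dataset.annotation,
                genome=small_dataset.genome,
            )
        )
        by_allele = {"A": [], "B": []}
        for stage, label, n in result.stage_counts:
            if label in by_allele:
                by_allele[label].append(n)
        for counts in by_allele.values():
            assert counts == sorted(counts, reverse=True)


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_variant_record_rejects_degenerate_input(seed):
    """Property: records with ref == alt or bad positions never construct."""
    import numpy as np

    r = np.random.default_rng(seed)
    base = "ACGT"[r.integers(4)]
    with pytest.raises(ValueError):
        VariantRecord("c", int(r.integers(1, 100)), base, base)
    with pytest.raises(ValueError):
        VariantRecord("c", 0, "A", "T")
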