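"""12/6-type substitution spectra, strand bias, 96-class context spectra."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtduplex.reference import Reference, reverse_complement
from mtduplex.spectra import (
    COLLAPSED_TYPES,
    CONTEXT_CLASSES,
    SUBSTITUTION_TYPES,
    classify_context,
    compare_context_fractions,
    context_spectrum,
    pooled_context_spectrum,
    strand_bias_test,
    substitution_spectrum,
)
from mtduplex.stats import two_proportion_test
from mtduplex.tiers import PositionPileup, VariantCall


def variant(pos, ref, alt, count=1, depth=1000, tier="rare"):
    return VariantCall(pos, ref, alt, count, depth, tier)


class TestTypeEnumeration:
    def test_twelve_substitution_types(self):
        assert len(SUBSTITUTION_TYPES) == 12
        assert len(set(SUBSTITUTION_TYPES)) == 12

    def test_six_collapsed_pairs_cover_all_twelve(self):
        members = [t for pair in COLLAPSED_TYPES for t in pair.split("/")]
        assert sorted(members) == sorted(SUBSTITUTION_TYPES)


class TestSubstitutionSpectrum:
    def piles(self):
        # 3 positions with ref G, 2 with ref C, 1 with ref A; depth 1000 each
        refs = ["G", "G", "G", "C", "C", "A"]
        return {
            i + 1: PositionPileup(i + 1, r, {r: 1000}) for i, r in enumerate(refs)
        }

    def test_complementary_pair_collapse_counts(self):
        variants = [variant(1, "G", "A"), variant(2, "G", "A"), variant(4, "C", "T")]
        spec = substitution_spectrum(variants, self.piles())
        assert spec.rows["G>A"].unique_count == 2
        assert spec.rows["C>T"].unique_count == 1
        assert spec.collapsed_counts["C>T/G>A"] == 3

    def test_type_frequency_uses_source_base_denominator(self):
        piles = {i: PositionPileup(i, "A", {"A": 10_000}) for i in range(1, 11)}
        spec = substitution_spectrum([variant(3, "A", "G", depth=10_000)], piles)
        assert spec.rows["A>G"].denominator == 100_000
        assert spec.rows["A>G"].frequency == pytest.approx(1e-5)

    def test_collapsed_fractions_sum_to_100(self):
        variants = [variant(1, "G", "A"), variant(4, "C", "G"), variant(6, "A", "T")]
        spec = substitution_spectrum(variants, self.piles())
        assert sum(spec.collapsed_fraction_pct.values()) == pytest.approx(100.0)

    def test_empty_input_gives_all_zero_table(self):
        spec = substitution_spectrum([], self.piles())
        assert spec.total_mutations == 0
        assert all(r.unique_count == 0 for r in spec.rows.values())

    def test_twelve_type_counts_sum_into_six(self):
        variants = [
            variant(1, "G", "A"), variant(2, "G", "T"), variant(4, "C", "T"), variant(6, "A", "C")
        ]
        spec = substitution_spectrum(variants, self.piles())
        for label in COLLAPSED_TYPES:
            a, b = label.split("/")
            assert spec.collapsed_counts[label] == spec.rows[a].unique_count + spec.rows[b].unique_count


class TestStrandBias:
    def test_identical_rates_give_p_one(self):
        piles = {
            1: PositionPileup(1, "G", {"G": 10_000}),
            2: PositionPileup(2, "C", {"C": 10_000}),
        }
        spec = substitution_spectrum([variant(1, "G", "A"), variant(2, "C", "T")], piles)
        res = strand_bias_test(spec, "G>A", "C>T")
        assert res.p_value == 1.0

    def test_matches_direct_proportion_test(self):
        piles = {
            i: PositionPileup(i, "G" if i <= 30 else "C", {("G" if i <= 30 else "C"): 50_000})
            for i in range(1, 61)
        }
        variants = [variant(i, "G", "A") for i in range(1, 31)] + [
            variant(i, "C", "T") for i in range(31, 41)
        ]
        spec = substitution_spectrum(variants, piles)
        res = strand_bias_test(spec, "G>A", "C>T")
        direct = two_proportion_test(30, 30 * 50_000, 10, 30 * 50_000)
        assert res.p_value == pytest.approx(direct.p_value)

    def test_non_complementary_pair_rejected(self):
        spec = substitution_spectrum([], {1: PositionPileup(1, "G", {"G": 10})})
        with pytest.raises(ValueError):
            strand_bias_test(spec, "G>A", "T>C")


class TestContextClassification:
    def test_exactly_96_canonical_classes(self):
        assert len(CONTEXT_CLASSES) == 96
        assert len(set(CONTEXT_CLASSES)) == 96
        assert all(tri[1] in "CT" for tri, _ in CONTEXT_CLASSES)

    def test_pyrimidine_variant_kept_as_is(self):
        ref = Reference("r", "AACAA")
        assert classify_context(3, "C", "T", ref) == ("ACA", "C>T")

    def test_purine_variant_complemented(self):
        # G>A with L-strand trinucleotide TGT maps to (ACA, C>T)
        ref = Reference("r", "ATGTA")
        assert classify_context(3, "G", "A", ref) == ("ACA", "C>T")

    def test_terminal_position_uses_circular_neighbors(self):
        ref = Reference("r", "CAAAT")  # context of pos 1 is T|C|A
        tri, sub = classify_context(1, "C", "G", ref)
        assert tri == "TCA"
        assert sub == "C>G"

    def test_linear_reference_rejects_terminal_context(self):
        ref = Reference("r", "CAAAT", circular=False)
        with pytest.raises(IndexError):
            classify_context(1, "C", "G", ref)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.data())
    def test_strand_complement_representation_maps_to_same_class(self, data):
        seq = data.draw(
            st.text(alphabet="ACGT", min_size=10, max_size=30)
        )
        ref = Reference("r", seq)
        pos = data.draw(st.integers(1, len(seq)))
        ref_base = ref.base(pos)
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref_base]))
        cls = classify_context(pos, ref_base, alt, ref)
        # complementary representation: same locus described on the other strand
        rc_ref = Reference("r2", reverse_complement(seq))
        rc_pos = len(seq) - pos + 1
        comp = dict(zip("ACGT", "TGCA"))
        cls_rc = classify_context(rc_pos, comp[ref_base], comp[alt], rc_ref)
        assert cls == cls_rc
        assert cls in dict.fromkeys(CONTEXT_CLASSES)


class TestContextSpectrum:
    def test_single_mutation_is_100_percent(self):
        ref = Reference("r", "AACAA")
        ctx = context_spectrum([variant(3, "C", "T")], ref)
        assert ctx.total == 1
        assert ctx.fraction_pct(("ACA", "C>T")) == 100.0

    def test_pure_process_concentrates_in_one_class(self):
        # every C in ACA context mutated to T: the class holds all the mass
        seq = "ACA" * 20
        ref = Reference("r", seq)
        variants = [
            variant(i, "C", "T") for i in range(2, len(seq), 3)
        ]
        ctx = context_spectrum(variants, ref)
        assert ctx.fraction_pct(("ACA", "C>T")) == 100.0

    def test_duplicate_variant_keys_counted_once(self):
        ref = Reference("r", "AACAA")
        ctx = context_spectrum([variant(3, "C", "T"), variant(3, "C", "T", count=5)], ref)
        assert ctx.total == 1

    def test_fractions_sum_to_100(self, toy_genome):
        ref, _ = toy_genome
        variants = []
        for pos in range(2, 40, 3):
            b = ref.base(pos)
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[b]
            variants.append(variant(pos, b, alt))
        ctx = context_spectrum(variants, ref)
        assert sum(ctx.fractions().values()) == pytest.approx(100.0)


class TestContextComparison:
    def ctx(self, counts):
        base = {cls: 0 for cls in CONTEXT_CLASSES}
        base.update(counts)
        from mtduplex.spectra import ContextSpectrum

        return ContextSpectrum(base)

    def test_identical_spectra_fold_one_p_one(self):
        a = self.ctx({("ACA", "C>T"): 5, ("TCG", "C>G"): 5})
        fold, res = compare_context_fractions(a, a, ("ACA", "C>T"))
        assert fold == pytest.approx(1.0)
        assert res.p_value == 1.0

    def test_four_vs_one_in_hundred_gives_fold_four(self):
        a = self.ctx({("ACA", "C>T"): 4, ("TCG", "C>G"): 96})
        b = self.ctx({("ACA", "C>T"): 1, ("TCG", "C>G"): 99})
        fold, res = compare_context_fractions(a, b, ("ACA", "C>T"))
        assert fold == pytest.approx(4.0)
        direct = two_proportion_test(4, 100, 1, 100)
        assert res.p_value == pytest.approx(direct.p_value)

    def test_class_empty_on_both_sides_not_estimable(self):
        a = self.ctx({("TCG", "C>G"): 10})
        fold, res = compare_context_fractions(a, a, ("ACA", "C>T"))
        assert fold is None
        assert res.p_value == 1.0

    def test_unknown_class_rejected(self):
        a = self.ctx({("TCG", "C>G"): 10})
        with pytest.raises(KeyError):
            compare_context_fractions(a, a, ("AAA", "A>T"))

    def test_pooling_sums_counts_across_samples(self):
        a = self.ctx({("ACA", "C>T"): 2})
        b = self.ctx({("ACA", "C>T"): 3, ("TCG", "C>G"): 5})
        pooled = pooled_context_spectrum([a, b])
        assert pooled.counts[("ACA", "C>T")] == 5
        assert pooled.total == 10
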