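"""Reference, annotation, mito genetic code and the by-chance NS expectation."""

import pytest

from mtduplex.reference import (
    GeneRecord,
    Reference,
    codon_changes,
    expected_ns_fraction,
    load_reference,
    noncoding_fraction,
    translate_mt,
)

# Vertebrate mitochondrial code (NCBI table 2), written out by hand as an
# independent fixture: differs from the standard code at TGA=W, ATA=M,
# AGA/AGG=stop.
TABLE2 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "M", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "*", "AGG": "*",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def brute_force_ns_fraction(annotation, reference):
    """Independent oracle: mutate every coding position to every alt base."""
    ns = total = 0
    for gene in annotation:
        if gene.category != "protein":
            continue
        cds = gene.coding_sequence(reference)
        n_codons = (gene.span - gene.frame_offset) // 3
        for i in range(gene.frame_offset, gene.frame_offset + 3 * n_codons):
            for alt in "ACGT":
                if alt == cds[i]:
                    continue
                mutated = cds[: i] + alt + cds[i + 1 :]
                ci = (i - gene.frame_offset) // 3
                lo = gene.frame_offset + 3 * ci
                total += 1
                if TABLE2[mutated[lo : lo + 3]] != TABLE2[cds[lo : lo + 3]]:
                    ns += 1
    return ns / total


class TestReferenceBasics:
    def test_tiny_fasta_roundtrip(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">r\nacgt\n")
        ref = load_reference(p)
        assert ref.length == 4
        assert ref.sequence == "ACGT"  # upper-cased
        assert ref.circular

    def test_multi_record_fasta_rejected(self, tmp_path):
        p = tmp_path / "two.fa"
        p.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="single mitochondrial contig"):
            load_reference(p)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            Reference("x", "")

    def test_circular_alias_resolves_to_same_base(self, rcrs):
        for p in (1, 17, rcrs.length):
            assert rcrs.base(p) == rcrs.base(p + rcrs.length)
        assert rcrs.base(rcrs.length + 1) == rcrs.base(1)

    def test_linear_mode_rejects_out_of_bounds(self):
        ref = Reference("x", "ACGT", circular=False)
        with pytest.raises(IndexError):
            ref.base(5)


class TestPackagedAnnotation:
    def test_gene_complement_counts(self, rcrs, rcrs_annotation):
        genes = [g for g in rcrs_annotation if g.category != "noncoding"]
        assert len(genes) == 37
        by_cat = {c: sum(g.category == c for g in genes) for c in ("tRNA", "rRNA", "protein")}
        assert by_cat == {"tRNA": 22, "rRNA": 2, "protein": 13}

    def test_reference_length(self, rcrs):
        assert rcrs.length == 16569

    def test_noncoding_under_seven_percent(self, rcrs, rcrs_annotation):
        assert 0 < 100 * noncoding_fraction(rcrs_annotation, rcrs) < 7

    def test_records_sorted_and_in_bounds(self, rcrs, rcrs_annotation):
        starts = [g.start for g in rcrs_annotation]
        assert starts == sorted(starts)
        assert all(1 <= g.start <= g.end <= rcrs.length for g in rcrs_annotation)

    def test_protein_genes_have_whole_codons_after_stop_trimming(self, rcrs_annotation):
        for g in rcrs_annotation:
            if g.category == "protein":
                assert (g.span - g.frame_offset) // 3 >= 50  # every mt protein has >= 50 codons

    def test_fully_coding_toy_genome_has_zero_noncoding(self):
        ref = Reference("t", "ATG" + "CTT" * 9)
        ann = [GeneRecord("P1", "protein", 1, 30)]
        assert noncoding_fraction(ann, ref) == 0.0


class TestTranslation:
    def test_table2_specifics(self):
        assert translate_mt("ATG") == "M"
        assert translate_mt("TGA") == "W"
        assert translate_mt("AGA") == "*"
        assert translate_mt("ATA") == "M"

    def test_agrees_with_hand_written_table_on_all_64_codons(self):
        for codon, aa in TABLE2.items():
            assert translate_mt(codon) == aa, codon

    @pytest.mark.parametrize("bad", ["AT", "ATGA", "AXG", "atu"])
    def test_invalid_codons_rejected(self, bad):
        with pytest.raises(ValueError):
            translate_mt(bad)


class TestCodonChange:
    @pytest.fixture()
    def toy(self):
        # L-strand gene: ATG AAA TGT TAA  (M K C *)
        ref = Reference("t", "ATGAAATGTTAA" + "ACGT" * 5)
        genes = [
            GeneRecord("P1", "protein", 1, 12),
            GeneRecord("T1", "tRNA", 13, 20),
        ]
        return ref, genes

    def test_synonymous_third_position(self, toy):
        ref, genes = toy
        # AAA -> AAG, Lys -> Lys
        (change,) = codon_changes(6, "A", "G", genes, ref)
        assert (change.ref_codon, change.alt_codon) == ("AAA", "AAG")
        assert change.effect == "synonymous"

    def test_nonsynonymous_first_position(self, toy):
        ref, genes = toy
        # AAA -> CAA, Lys -> Gln
        (change,) = codon_changes(4, "A", "C", genes, ref)
        assert (change.ref_aa, change.alt_aa) == ("K", "Q")
        assert change.effect == "nonsynonymous"

    def test_trna_position_yields_no_codon_change(self, toy):
        ref, genes = toy
        assert codon_changes(14, ref.base(14), "A" if ref.base(14) != "A" else "C", genes, ref) == []

    def test_out_of_range_position_rejected(self, toy):
        ref, genes = toy
        with pytest.raises(IndexError):
            codon_changes(999, "A", "C", genes, ref)

    def test_ref_mismatch_rejected(self, toy):
        ref, genes = toy
        with pytest.raises(ValueError, match="mismatch"):
            codon_changes(1, "C", "G", genes, ref)

    def test_h_strand_gene_uses_complemented_codon(self):
        # gene on H strand: L-strand CAT TTT -> coding strand AAA ATG read 3'->5'
        ref = Reference("t", "CATTTT")
        gene = GeneRecord("P1", "protein", 1, 6, coding_strand="H")
        # L-strand position 6 (T) is the first base of the coding codon (A)
        (change,) = codon_changes(6, "T", "C", [gene], ref)
        assert change.ref_codon == "AAA"
        assert change.alt_codon == "GAA"
        assert change.effect == "nonsynonymous"

    def test_overlapping_genes_yield_one_change_per_gene(self):
        ref = Reference("t", "ATGAAATTTGGG")
        genes = [
            GeneRecord("P1", "protein", 1, 9),
            GeneRecord("P2", "protein", 4, 12),
        ]
        changes = codon_changes(6, "A", "T", genes, ref)
        assert {c.gene for c in changes} == {"P1", "P2"}


class TestExpectedNSFraction:
    def test_single_lysine_codon_is_eight_ninths(self):
        ref = Reference("t", "AAA" + "C" * 57)  # pad to length >= 60
        ann = [GeneRecord("P1", "protein", 1, 3)]
        assert expected_ns_fraction(ann, ref) == pytest.approx(8 / 9)

    def test_two_fold_leucine_codons_give_six_ninths(self):
        # CTT/CTC: only the three third-position changes are synonymous
        ref = Reference("t", "CTTCTC" + "A" * 54)
        ann = [GeneRecord("P1", "protein", 1, 6)]
        assert expected_ns_fraction(ann, ref) == pytest.approx(6 / 9)

    def test_no_protein_genes_rejected(self):
        ref = Reference("t", "ACGT" * 20)
        with pytest.raises(ValueError):
            expected_ns_fraction([GeneRecord("T1", "tRNA", 1, 10)], ref)

    def test_matches_brute_force_oracle_on_toy_genomes(self, toy_genome):
        ref, ann = toy_genome
        assert expected_ns_fraction(ann, ref) == pytest.approx(brute_force_ns_fraction(ann, ref))

    def test_matches_brute_force_oracle_on_packaged_genome(self, rcrs, rcrs_annotation):
        assert expected_ns_fraction(rcrs_annotation, rcrs) == pytest.approx(
            brute_force_ns_fraction(rcrs_annotation, rcrs)
        )
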