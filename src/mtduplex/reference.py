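"""Circular mitochondrial reference, gene annotation, and the mito genetic code.

Coordinates are 1-based inclusive on the light (L) strand throughout, and
variant names follow the HGVS-like ``m.{pos}{ref}>{alt}`` convention.  Protein
genes encoded on the heavy (H) strand (MT-ND6 and eight tRNAs in the human
annotation) are read as the reverse complement of the L-strand slice.

Translation uses the vertebrate mitochondrial code (NCBI table 2): TGA = Trp,
ATA = Met, AGA/AGG = stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "Reference",
    "GeneRecord",
    "CodonChange",
    "load_reference",
    "load_annotation",
    "packaged_reference",
    "packaged_annotation",
    "translate_mt",
    "complement",
    "reverse_complement",
    "codon_changes",
    "expected_ns_fraction",
    "noncoding_fraction",
]

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# NCBI translation table 2 (vertebrate mitochondrial); stops mapped to '*'.
_TABLE2 = CodonTable.unambiguous_dna_by_id[2]
MT_CODON_TABLE: dict[str, str] = dict(_TABLE2.forward_table)
MT_CODON_TABLE.update({codon: "*" for codon in _TABLE2.stop_codons})


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_mt(codon: str) -> str:
    """Translate one codon under the vertebrate mitochondrial code.

    Returns a single-letter amino acid, or ``'*'`` for a stop codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"codon must be a 3-mer over ACGT, got {codon!r}")
    return MT_CODON_TABLE[codon]


@dataclass(frozen=True)
class Reference:
    """A (by default circular) mitochondrial reference sequence."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty reference sequence")
        bad = set(self.sequence) - (_BASES | {"N"})
        if bad:
            raise ValueError(f"reference contains non-ACGTN characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def wrap(self, position: int) -> int:
        """Map a 1-based position onto [1, length] via circular wrapping."""
        if self.circular:
            return (position - 1) % self.length + 1
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside linear reference of length {self.length}")
        return position

    def base(self, position: int) -> str:
        """1-based base lookup; position length+1 aliases position 1 when circular."""
        return self.sequence[self.wrap(position) - 1]

    def context(self, position: int) -> str:
        """Trinucleotide centred on ``position`` (5' neighbour, base, 3' neighbour)."""
        return self.base(position - 1) + self.base(position) + self.base(position + 1)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated feature on the mitochondrial genome.

    ``coding_strand`` is 'L' when the coding sequence reads directly off the
    reference (light) strand and 'H' when it is the reverse complement.
    """

    gene: str
    category: str  # protein | tRNA | rRNA | noncoding
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    coding_strand: str = "L"
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.category not in {"protein", "tRNA", "rRNA", "noncoding"}:
            raise ValueError(f"unknown category {self.category!r}")
        if self.coding_strand not in {"L", "H"}:
            raise ValueError(f"coding_strand must be 'L' or 'H', got {self.coding_strand!r}")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0-2")

    @property
    def span(self) -> int:
        return self.end - self.start + 1  # wrapping records not used in the human table

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end

    def coding_sequence(self, reference: Reference) -> str:
        seq = reference.sequence[self.start - 1 : self.end]
        return reverse_complement(seq) if self.coding_strand == "H" else seq

    def codon_index_of(self, position: int) -> Optional[tuple[int, int]]:
        """(codon_index >= 1, offset 0-2 within codon) for a protein-gene position.

        Returns None when the position falls in the frame-offset leader or in
        the trailing incomplete codon (completed by polyadenylation in vivo,
        hence excluded from codon arithmetic).
        """
        if self.category != "protein" or not self.covers(position):
            return None
        if self.coding_strand == "L":
            idx = position - self.start - self.frame_offset
        else:
            idx = self.end - position - self.frame_offset
        if idx < 0:
            return None
        n_codons = (self.span - self.frame_offset) // 3
        if idx >= 3 * n_codons:
            return None
        return idx // 3 + 1, idx % 3


@dataclass(frozen=True)
class CodonChange:
    gene: str
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str = field(init=False)
    alt_aa: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_aa", translate_mt(self.ref_codon))
        object.__setattr__(self, "alt_aa", translate_mt(self.alt_codon))

    @property
    def effect(self) -> str:
        return "synonymous" if self.ref_aa == self.alt_aa else "nonsynonymous"


def load_reference(fasta_path, circular: bool = True) -> Reference:
    """Load a single-contig mitochondrial reference from FASTA."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected single mitochondrial contig, found {len(records)} records")
    seq = str(records[0].seq).upper()
    return Reference(name=records[0].id, sequence=seq, circular=circular)


def load_annotation(tsv_path, reference: Reference) -> list[GeneRecord]:
    """Load the gene-annotation table (TSV) and validate it against the reference.

    Required columns: gene, category, start, end, coding_strand; frame_offset
    is optional (default 0).  Records are returned sorted by start.  Overlaps
    between protein genes are legitimate in mtDNA (ATP8/ATP6, ND4L/ND4) and
    are allowed.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    required = {"gene", "category", "start", "end", "coding_strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    if "frame_offset" not in df.columns:
        df["frame_offset"] = 0
    records = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if not (1 <= start <= reference.length and 1 <= end <= reference.length):
            raise ValueError(f"{row.gene}: coordinates [{start}, {end}] outside [1, {reference.length}]")
        records.append(
            GeneRecord(
                gene=str(row.gene),
                category=str(row.category),
                start=start,
                end=end,
                coding_strand=str(row.coding_strand),
                frame_offset=int(row.frame_offset),
            )
        )
    return sorted(records, key=lambda g: (g.start, g.end))


def packaged_reference() -> Reference:
    """The bundled mitochondrial reference fixture.

    The sequence is a clearly-labelled synthetic stand-in for the human rCRS:
    same length (16,569 bp), same base composition, and valid reading frames
    under the authentic NC_012920 gene coordinates, but not the real sequence
    (which is not redistributable inside this package).
    """
    path = resources.files("mtduplex.data") / "synthetic_rcrs.fa"
    with resources.as_file(path) as p:
        return load_reference(p)


def packaged_annotation(reference: Optional[Reference] = None) -> list[GeneRecord]:
    """The bundled 37-gene NC_012920 coordinate table (plus control-region records)."""
    if reference is None:
        reference = packaged_reference()
    path = resources.files("mtduplex.data") / "nc012920_genes.tsv"
    with resources.as_file(path) as p:
        return load_annotation(p, reference)


def noncoding_fraction(annotation: Iterable[GeneRecord], reference: Reference) -> float:
    """Fraction of the genome in annotated noncoding records (the control region)."""
    nc = sum(g.span for g in annotation if g.category == "noncoding")
    return nc / reference.length


def _codon_change_in_gene(
    gene: GeneRecord, position: int, ref_base: str, alt_base: str, reference: Reference
) -> Optional[CodonChange]:
    loc = gene.codon_index_of(position)
    if loc is None:
        return None
    codon_index, offset = loc
    cds = gene.coding_sequence(reference)
    base_idx = gene.frame_offset + 3 * (codon_index - 1)
    ref_codon = cds[base_idx : base_idx + 3]
    if gene.coding_strand == "H":
        ref_b, alt_b = complement(ref_base), complement(alt_base)
    else:
        ref_b, alt_b = ref_base, alt_base
    if ref_codon[offset] != ref_b:
        raise ValueError(
            f"reference mismatch at m.{position} in {gene.gene}: codon has {ref_codon[offset]}, caller says {ref_b}"
        )
    alt_codon = ref_codon[:offset] + alt_b + ref_codon[offset + 1 :]
    return CodonChange(gene=gene.gene, codon_index=codon_index, ref_codon=ref_codon, alt_codon=alt_codon)


def codon_changes(
    position: int,
    ref_base: str,
    alt_base: str,
    annotation: Iterable[GeneRecord],
    reference: Reference,
) -> list[CodonChange]:
    """Codon-level consequences of an L-strand substitution.

    Returns one :class:`CodonChange` per protein gene whose reading frame
    covers the position (overlapping genes yield several records), and an
    empty list for tRNA/rRNA/noncoding positions.
    """
    if not 1 <= position <= reference.length:
        raise IndexError(f"position {position} outside reference of length {reference.length}")
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if reference.base(position) != ref_base:
        raise ValueError(
            f"ref base mismatch at m.{position}: reference has {reference.base(position)}, got {ref_base}"
        )
    if alt_base == ref_base or alt_base not in _BASES:
        raise ValueError(f"invalid alt base {alt_base!r}")
    out = []
    for gene in annotation:
        if gene.category == "protein" and gene.covers(position):
            change = _codon_change_in_gene(gene, position, ref_base, alt_base, reference)
            if change is not None:
                out.append(change)
    return out


def expected_ns_fraction(annotation: Iterable[GeneRecord], reference: Reference) -> float:
    """By-chance nonsynonymous fraction over all protein-coding substitutions.

    Every position of every complete codon of every protein gene is mutated to
    each of the 3 alternative bases with equal weight; stop gains and losses
    count as nonsynonymous; a position inside two overlapping genes contributes
    once per gene.  Returns nonsynonymous / total as a fraction in [0, 1].
    """
    ns = total = 0
    genes = [g for g in annotation if g.category == "protein"]
    if not genes:
        raise ValueError("annotation contains no protein genes")
    for gene in genes:
        cds = gene.coding_sequence(reference)
        n_codons = (gene.span - gene.frame_offset) // 3
        for ci in range(n_codons):
            codon = cds[gene.frame_offset + 3 * ci : gene.frame_offset + 3 * ci + 3]
            aa = translate_mt(codon)
            for offset in range(3):
                for alt in "ACGT":
                    if alt == codon[offset]:
                        continue
                    alt_codon = codon[:offset] + alt + codon[offset + 1 :]
                    total += 1
                    if translate_mt(alt_codon) != aa:
                        ns += 1
    return ns / total
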