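"""Substitution spectra: 12 L-strand types, 6 collapsed types, 96 contexts.

The 12 substitution types are counted in L-strand orientation (the strand the
reference coordinates follow) because strand bias — unequal rates of
complementary pairs such as G>A versus C>T — is only visible before collapse.
The 6-type view groups each substitution with its complement
(pyrimidine-first labels, e.g. ``C>T/G>A``) and reports fractions of all
point mutations.

Trinucleotide context classes follow the COSMIC convention: the mutated base
plus its immediate 5' and 3' neighbours, re-expressed on the strand whose
central base is a pyrimidine (purine-centred mutations are complemented and
their context reverse-complemented), giving 6 substitutions x 16 flank pairs
= 96 canonical classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .reference import Reference, reverse_complement
from .stats import TestResult, two_proportion_test, wilson_interval
from .tiers import PositionPileup, VariantCall

__all__ = [
    "SUBSTITUTION_TYPES",
    "COLLAPSED_TYPES",
    "CONTEXT_CLASSES",
    "TypeSpectrumRow",
    "SpectrumTable",
    "ContextSpectrum",
    "substitution_spectrum",
    "strand_bias_test",
    "classify_context",
    "context_spectrum",
    "compare_context_fractions",
]

#: the 12 point-substitution types in L-strand orientation
SUBSTITUTION_TYPES: tuple[str, ...] = tuple(
    f"{ref}>{alt}" for ref in "ACGT" for alt in "ACGT" if ref != alt
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _complement_type(subst: str) -> str:
    ref, alt = subst.split(">")
    return f"{_COMP[ref]}>{_COMP[alt]}"


#: the 6 collapsed (complement-grouped) types, pyrimidine member first
COLLAPSED_TYPES: tuple[str, ...] = (
    "C>A/G>T", "C>G/G>C", "C>T/G>A", "T>A/A>T", "T>C/A>G", "T>G/A>C",
)

_PYR_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: fixed canonical order of the 96 context classes:
#: substitution major, then 5' base, then 3' base (A,C,G,T)
CONTEXT_CLASSES: tuple[tuple[str, str], ...] = tuple(
    (five + sub[0] + three, sub)
    for sub in _PYR_SUBS
    for five in "ACGT"
    for three in "ACGT"
)


@dataclass(frozen=True)
class TypeSpectrumRow:
    substitution: str
    unique_count: int
    denominator: int  # sequenced nt whose reference base is the source base
    ci_low: float
    ci_high: float

    @property
    def frequency(self) -> float:
        return self.unique_count / self.denominator if self.denominator else 0.0


@dataclass(frozen=True)
class SpectrumTable:
    """12-type counts/frequencies plus the 6-type collapsed fractions."""

    rows: dict[str, TypeSpectrumRow]
    collapsed_counts: dict[str, int]
    collapsed_fraction_pct: dict[str, float]

    @property
    def total_mutations(self) -> int:
        return sum(r.unique_count for r in self.rows.values())


def substitution_spectrum(
    variants: Sequence[VariantCall],
    pileups: Mapping[int, PositionPileup],
    confidence: float = 0.95,
) -> SpectrumTable:
    """12-type spectrum with per-type frequencies and the 6-type collapse.

    The denominator of type X>Y is the summed depth over covered positions
    whose reference base is X, so each type frequency is mutations per
    sequenced source nucleotide.  Collapsed fractions are percentages of all
    point mutations and sum to 100 when any mutation exists.
    """
    base_depth = {b: 0 for b in "ACGT"}
    for pile in pileups.values():
        if pile.ref_base in base_depth:
            base_depth[pile.ref_base] += pile.depth

    unique: dict[str, set] = {t: set() for t in SUBSTITUTION_TYPES}
    for v in variants:
        unique[f"{v.ref_base}>{v.alt_base}"].add(v.key)

    rows = {}
    for t in SUBSTITUTION_TYPES:
        k = len(unique[t])
        n = base_depth[t[0]]
        low, high = wilson_interval(k, n, confidence) if n else (0.0, 0.0)
        rows[t] = TypeSpectrumRow(t, k, n, low, high)

    collapsed_counts = {}
    for label in COLLAPSED_TYPES:
        a, b = label.split("/")
        collapsed_counts[label] = rows[a].unique_count + rows[b].unique_count
    total = sum(collapsed_counts.values())
    collapsed_fraction = {
        label: (100.0 * c / total if total else 0.0) for label, c in collapsed_counts.items()
    }
    return SpectrumTable(rows, collapsed_counts, collapsed_fraction)


def strand_bias_test(spectrum: SpectrumTable, type_a: str, type_b: str) -> TestResult:
    """Test a complementary pair (e.g. G>A vs C>T) for unequal L-strand rates.

    Two-sample proportion test with continuity correction on
    (count_a, denom_a) vs (count_b, denom_b).
    """
    if _complement_type(type_a) != type_b:
        raise ValueError(f"{type_a} and {type_b} are not a complementary pair")
    ra, rb = spectrum.rows[type_a], spectrum.rows[type_b]
    if ra.denominator == 0 or rb.denominator == 0:
        raise ValueError("zero denominator for strand-bias test")
    return two_proportion_test(ra.unique_count, ra.denominator, rb.unique_count, rb.denominator)


def classify_context(position: int, ref_base: str, alt_base: str, reference: Reference) -> tuple[str, str]:
    """Canonical (trinucleotide, substitution) class of one point mutation.

    The trinucleotide is the L-strand context with the mutated base in the
    middle; when the reference base is a purine the mutation and its context
    are complemented onto the pyrimidine-centred representation.  Neighbours
    at the genome termini come from circular wrapping (an error when the
    reference is linear).
    """
    tri = reference.context(position)
    if tri[1] != ref_base:
        raise ValueError(f"ref base mismatch at m.{position}: context {tri}, caller says {ref_base}")
    if ref_base in "AG":
        tri = reverse_complement(tri)
        sub = _complement_type(f"{ref_base}>{alt_base}")
    else:
        sub = f"{ref_base}>{alt_base}"
    return (tri, sub)


@dataclass(frozen=True)
class ContextSpectrum:
    counts: dict[tuple[str, str], int]  # keyed by (trinucleotide, substitution)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction_pct(self, cls: tuple[str, str]) -> float:
        if cls not in self.counts:
            raise KeyError(f"unknown context class {cls}")
        return 100.0 * self.counts[cls] / self.total if self.total else 0.0

    def fractions(self) -> dict[tuple[str, str], float]:
        return {cls: self.fraction_pct(cls) for cls in CONTEXT_CLASSES}


def context_spectrum(variants: Sequence[VariantCall], reference: Reference) -> ContextSpectrum:
    """Count unique point mutations into the 96 canonical context classes."""
    counts = {cls: 0 for cls in CONTEXT_CLASSES}
    seen = set()
    for v in variants:
        if v.key in seen:
            continue
        seen.add(v.key)
        counts[classify_context(v.position, v.ref_base, v.alt_base, reference)] += 1
    return ContextSpectrum(counts)


def compare_context_fractions(
    spectrum_a: ContextSpectrum,
    spectrum_b: ContextSpectrum,
    cls: tuple[str, str],
) -> tuple[Optional[float], TestResult]:
    """Fold change (A over B) and proportion test for one context class.

    The fold is None ("not estimable") when either side has a zero fraction.
    """
    if cls not in spectrum_a.counts or cls not in spectrum_b.counts:
        raise KeyError(f"unknown context class {cls}")
    ka, na = spectrum_a.counts[cls], spectrum_a.total
    kb, nb = spectrum_b.counts[cls], spectrum_b.total
    if na == 0 or nb == 0:
        raise ValueError("context spectra must have nonzero totals")
    fa, fb = ka / na, kb / nb
    fold = (fa / fb) if (fa > 0 and fb > 0) else None
    if ka * nb == kb * na:
        # equal proportions (covers the degenerate all-zero / all-full tables)
        result = TestResult(0.0, 1.0, "2-sample test for equality of proportions with continuity correction", 0.0)
    else:
        result = two_proportion_test(ka, na, kb, nb)
    return fold, result


def pooled_context_spectrum(spectra: Sequence[ContextSpectrum]) -> ContextSpectrum:
    """Pool samples by summing unique-variant counts (count-weighted pooling;
    a variant shared by two samples contributes once per sample)."""
    counts = {cls: 0 for cls in CONTEXT_CLASSES}
    for sp in spectra:
        for cls, c in sp.counts.items():
            counts[cls] += c
    return ContextSpectrum(counts)
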