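"""Cross-sample variant set algebra, known-variant lookup, and burden tables.

Variant identity for set operations is the (position, ref, alt) triple —
clonality may differ between samples without breaking a match; tier
stratification happens upstream, before the set algebra.  A variant inside
two overlapping protein genes (e.g. m.8567T>C in ATP8 and ATP6) is listed
once per gene in per-gene tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .reference import GeneRecord, Reference, codon_changes
from .stats import TestResult, rank_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "SampleVariantSet",
    "KnownVariantRecord",
    "GScoreRecord",
    "variant_name",
    "parse_variant_name",
    "common_variants",
    "exclusive_variants",
    "load_known_variants",
    "flag_new_variants",
    "gene_ns_burden",
    "load_gscores",
    "aggregate_gscores",
]

VariantKey = tuple[int, str, str]  # (position, ref, alt)


def variant_name(key: VariantKey) -> str:
    pos, ref, alt = key
    return f"m.{pos}{ref}>{alt}"


def parse_variant_name(name: str) -> VariantKey:
    """Parse ``m.12684G>A`` (or bare ``A13105G``) into (position, ref, alt)."""
    s = name.strip()
    if s.startswith("m."):
        s = s[2:]
    if ">" in s:
        left, alt = s.split(">")
        pos, ref = int(left[:-1]), left[-1]
    else:  # GenBank-style A13105G
        ref, pos, alt = s[0], int(s[1:-1]), s[-1]
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"unparseable variant name {name!r}")
    return (pos, ref, alt)


@dataclass
class SampleVariantSet:
    sample_id: str
    cell_type: str  # e.g. "stem" | "non_stem"
    woman_id: str
    variants: set[VariantKey] = field(default_factory=set)


def _select(sets: Sequence[SampleVariantSet], group_filter) -> list[SampleVariantSet]:
    if group_filter is None:
        return list(sets)
    return [s for s in sets if group_filter(s)]


def common_variants(sets: Sequence[SampleVariantSet], group_filter=None) -> set[VariantKey]:
    """Variants present in every selected sample set (identity = pos/ref/alt)."""
    chosen = _select(sets, group_filter)
    if not chosen:
        raise ValueError("empty sample selection")
    out = set(chosen[0].variants)
    for s in chosen[1:]:
        out &= s.variants
    return out


def exclusive_variants(
    in_group: Sequence[SampleVariantSet],
    not_in_group: Sequence[SampleVariantSet],
) -> set[VariantKey]:
    """Variants in all of ``in_group`` and in none of ``not_in_group``."""
    if not in_group or not not_in_group:
        raise ValueError("both groups must be nonempty (use common_variants for a plain intersection)")
    in_ids = {id(s) for s in in_group}
    if any(id(s) in in_ids for s in not_in_group):
        raise ValueError("overlapping group definitions")
    core = common_variants(in_group)
    union = set()
    for s in not_in_group:
        union |= s.variants
    return core - union


@dataclass(frozen=True)
class KnownVariantRecord:
    name: str
    gb_frequency_pct: float  # share of GenBank full-length sequences carrying it
    associations: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.gb_frequency_pct <= 100.0:
            raise ValueError("gb_frequency_pct must be within [0, 100]")


def load_known_variants(tsv_path) -> dict[VariantKey, KnownVariantRecord]:
    """Load a MITOMAP-style lookup TSV (columns: name, gb_frequency_pct, associations).

    Malformed rows are skipped with a warning rather than failing the load.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    out: dict[VariantKey, KnownVariantRecord] = {}
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            key = parse_variant_name(str(row.name))
            out[key] = KnownVariantRecord(
                name=variant_name(key),
                gb_frequency_pct=float(row.gb_frequency_pct),
                associations=str(getattr(row, "associations", "") or ""),
            )
        except (ValueError, IndexError, TypeError):
            skipped += 1
    if skipped:
        logger.warning("skipped %d malformed known-variant rows", skipped)
    return out


def flag_new_variants(
    variants: Iterable[VariantKey],
    known_records: Mapping[VariantKey, KnownVariantRecord],
) -> pd.DataFrame:
    """Annotate each variant as previously reported (with GenBank frequency) or new.

    Purely additive: the variant set itself is never altered.
    """
    rows = []
    for key in sorted(variants):
        rec = known_records.get(key)
        rows.append(
            {
                "name": variant_name(key),
                "position": key[0],
                "ref": key[1],
                "alt": key[2],
                "status": "reported" if rec else "new",
                "gb_frequency_pct": rec.gb_frequency_pct if rec else None,
                "associations": rec.associations if rec else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "position", "ref", "alt", "status", "gb_frequency_pct", "associations"],
    )


def gene_ns_burden(
    variants: Iterable[VariantKey],
    annotation: Sequence[GeneRecord],
    reference: Reference,
) -> tuple[pd.DataFrame, Optional[TestResult]]:
    """Per-protein-gene nonsynonymous/synonymous burden and its size correlation.

    Each unique variant contributes once per overlapping protein gene.
    Returns the per-gene table (gene, size_bp, ns_count, s_count) and the
    Pearson correlation of gene size with nonsynonymous count (None — not
    estimable — with fewer than 3 protein genes or zero variance).
    """
    genes = [g for g in annotation if g.category == "protein"]
    ns = {g.gene: 0 for g in genes}
    syn = {g.gene: 0 for g in genes}
    for key in set(variants):
        pos, ref, alt = key
        for change in codon_changes(pos, ref, alt, genes, reference):
            if change.effect == "nonsynonymous":
                ns[change.gene] += 1
            else:
                syn[change.gene] += 1
    table = pd.DataFrame(
        {
            "gene": [g.gene for g in genes],
            "size_bp": [g.span for g in genes],
            "ns_count": [ns[g.gene] for g in genes],
            "s_count": [syn[g.gene] for g in genes],
        }
    )
    corr: Optional[TestResult] = None
    if len(genes) >= 3:
        try:
            corr = rank_correlation(table["size_bp"], table["ns_count"], method="pearson")
        except ValueError:
            corr = None  # zero variance: not estimable
    return table, corr


@dataclass(frozen=True)
class GScoreRecord:
    """MutPred-style pathogenicity probability for one nonsynonymous variant."""

    name: str
    gene: str
    g_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.g_score <= 1.0:
            raise ValueError(f"g score outside [0, 1]: {self.g_score}")


def load_gscores(tsv_path) -> list[GScoreRecord]:
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    return [
        GScoreRecord(name=str(r.name), gene=str(r.gene), g_score=float(r.g_score))
        for r in df.itertuples(index=False)
    ]


def aggregate_gscores(
    records: Iterable[GScoreRecord],
    protein_genes: Sequence[str],
) -> tuple[dict[str, float], float]:
    """Per-gene g-score sums and their average over all protein genes.

    Genes with no scored mutation contribute a sum of 0 to the average (the
    pooled average is over the full 13-gene complement, not just hit genes).
    """
    sums = {g: 0.0 for g in protein_genes}
    for rec in records:
        if rec.gene not in sums:
            raise ValueError(f"g-score record for unknown gene {rec.gene!r}")
        sums[rec.gene] += rec.g_score
    average = sum(sums.values()) / len(sums) if sums else 0.0
    return sums, average
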