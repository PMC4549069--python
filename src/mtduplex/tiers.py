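"""Per-position pileup of duplex consensus calls, clonality tiers, frequencies.

Clonality is the percentage of duplex consensus molecules at a position that
carry a given alternate allele.  Variants are stratified into four tiers:

* rare            0 < clonality <= 0.5 %
* low_het         0.5 < clonality <= 20 %
* high_het        20 < clonality < 95 %
* homoplasmic     clonality >= 95 %

The overall mutation frequency of a tier is the number of distinct mutated
(position, alt) pairs — each scored once regardless of how many molecules
carry it — divided by the total number of sequenced (evaluable) nucleotides.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .consensus import ConsensusSequence, IndelEvent
from .reference import Reference
from .stats import wilson_interval

__all__ = [
    "TIER_NAMES",
    "TierCutoffs",
    "PositionPileup",
    "VariantCall",
    "IndelCall",
    "FrequencySummary",
    "classify_clonality",
    "pileup",
    "call_variants",
    "call_indels",
    "mutation_frequency",
    "tier_distribution",
]

TIER_NAMES = ("rare", "low_het", "high_het", "homoplasmic")


@dataclass(frozen=True)
class TierCutoffs:
    """Clonality (%) boundaries of the four tiers; defaults follow the study."""

    rare_max: float = 0.5
    low_het_max: float = 20.0
    homoplasmic_min: float = 95.0

    def __post_init__(self) -> None:
        if not 0 < self.rare_max < self.low_het_max < self.homoplasmic_min <= 100:
            raise ValueError("cutoffs must be strictly increasing within (0, 100]")


DEFAULT_CUTOFFS = TierCutoffs()


def classify_clonality(clonality_pct: float, cutoffs: TierCutoffs = DEFAULT_CUTOFFS) -> str:
    """Map a clonality percentage in (0, 100] to its tier."""
    if not 0.0 < clonality_pct <= 100.0:
        raise ValueError(f"clonality must be in (0, 100], got {clonality_pct}")
    if clonality_pct <= cutoffs.rare_max:
        return "rare"
    if clonality_pct <= cutoffs.low_het_max:
        return "low_het"
    if clonality_pct < cutoffs.homoplasmic_min:
        return "high_het"
    return "homoplasmic"


@dataclass
class PositionPileup:
    position: int  # 1-based
    ref_base: str
    counts: dict[str, int] = field(default_factory=dict)  # base -> DCS calls
    indel_events: dict[IndelEvent, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        """Non-N consensus calls covering this position."""
        return sum(self.counts.values())


@dataclass(frozen=True)
class VariantCall:
    position: int
    ref_base: str
    alt_base: str
    mutant_count: int
    depth: int
    tier: str

    @property
    def clonality_pct(self) -> float:
        return 100.0 * self.mutant_count / self.depth

    @property
    def name(self) -> str:
        return f"m.{self.position}{self.ref_base}>{self.alt_base}"

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class IndelCall:
    """Insertions/deletions are tiered by the same cutoffs but kept apart from
    point-mutation spectra and frequencies."""

    position: int
    kind: str
    payload: str
    mutant_count: int
    depth: int
    tier: str

    @property
    def clonality_pct(self) -> float:
        return 100.0 * self.mutant_count / self.depth


@dataclass(frozen=True)
class FrequencySummary:
    tier: str
    unique_mutation_count: int
    total_sequenced_nt: int
    ci_low: float
    ci_high: float

    @property
    def frequency(self) -> float:
        return self.unique_mutation_count / self.total_sequenced_nt


def pileup(
    consensus_records: Iterable[ConsensusSequence],
    reference: Reference,
) -> dict[int, PositionPileup]:
    """Column-wise tally of consensus base calls against the reference.

    N calls contribute nothing.  Coordinates wrap circularly when the
    reference is circular; in linear mode a record running past the end is an
    error.  Returns a dict keyed by 1-based position (only covered positions
    are present).
    """
    piles: dict[int, PositionPileup] = {}
    for rec in consensus_records:
        end = rec.start + len(rec.bases) - 1
        if not reference.circular and (rec.start < 1 or end > reference.length):
            raise ValueError(f"consensus at [{rec.start}, {end}] outside linear reference")
        for offset, base in enumerate(rec.bases):
            if base == "N":
                continue
            pos = reference.wrap(rec.start + offset)
            pile = piles.get(pos)
            if pile is None:
                pile = piles[pos] = PositionPileup(pos, reference.base(pos))
            pile.counts[base] = pile.counts.get(base, 0) + 1
        for ev in rec.indels:
            pos = reference.wrap(ev.position)
            ev = IndelEvent(pos, ev.kind, ev.payload)
            pile = piles.get(pos)
            if pile is None:
                pile = piles[pos] = PositionPileup(pos, reference.base(pos))
            pile.indel_events[ev] = pile.indel_events.get(ev, 0) + 1
    return piles


def call_variants(
    pileups: Mapping[int, PositionPileup],
    min_depth: int = 100,
    cutoffs: TierCutoffs = DEFAULT_CUTOFFS,
) -> list[VariantCall]:
    """One tiered call per (position, alt) with at least one mutant molecule.

    Positions below ``min_depth`` still count toward denominators elsewhere
    but yield no tiered calls (clonality is too noisy to classify there).
    Two different alternate alleles at one position are two distinct calls.
    """
    calls = []
    for pos in sorted(pileups):
        pile = pileups[pos]
        depth = pile.depth
        if depth < min_depth:
            continue
        for alt in "ACGT":
            if alt == pile.ref_base:
                continue
            n = pile.counts.get(alt, 0)
            if n >= 1:
                tier = classify_clonality(100.0 * n / depth, cutoffs)
                calls.append(VariantCall(pos, pile.ref_base, alt, n, depth, tier))
    return calls


def call_indels(
    pileups: Mapping[int, PositionPileup],
    min_depth: int = 100,
    cutoffs: TierCutoffs = DEFAULT_CUTOFFS,
) -> list[IndelCall]:
    calls = []
    for pos in sorted(pileups):
        pile = pileups[pos]
        depth = pile.depth
        if depth < min_depth:
            continue
        for ev, n in sorted(pile.indel_events.items(), key=lambda kv: (kv[0].kind, kv[0].payload)):
            tier = classify_clonality(min(100.0, 100.0 * n / depth), cutoffs)
            calls.append(IndelCall(pos, ev.kind, ev.payload, n, depth, tier))
    return calls


def mutation_frequency(
    variants: Sequence[VariantCall],
    pileups: Mapping[int, PositionPileup],
    tier: Optional[str] = None,
    confidence: float = 0.95,
) -> FrequencySummary:
    """Tier-specific overall mutation frequency with a Wilson interval.

    numerator: distinct (position, alt) pairs in the tier, each once;
    denominator: total evaluable sequenced nucleotides (sum of depths over
    every covered position, regardless of tier).
    """
    if tier is not None and tier not in TIER_NAMES:
        raise ValueError(f"unknown tier {tier!r}")
    denominator = sum(p.depth for p in pileups.values())
    if denominator == 0:
        raise ValueError("zero sequenced nucleotides: no denominator")
    keys = {v.key for v in variants if tier is None or v.tier == tier}
    k = len(keys)
    low, high = wilson_interval(k, denominator, confidence)
    return FrequencySummary(
        tier=tier or "all",
        unique_mutation_count=k,
        total_sequenced_nt=denominator,
        ci_low=low,
        ci_high=high,
    )


def tier_distribution(variants: Sequence[VariantCall]) -> dict[str, float]:
    """Percentage of unique variants falling in each tier (sums to 100)."""
    keys_by_tier: dict[str, set] = defaultdict(set)
    for v in variants:
        keys_by_tier[v.tier].add(v.key)
    total = sum(len(s) for s in keys_by_tier.values())
    if total == 0:
        raise ValueError("tier_distribution requires at least one variant")
    return {t: 100.0 * len(keys_by_tier.get(t, ())) / total for t in TIER_NAMES}
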