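"""Duplex-consensus building: read families, SSCS, DCS, and end clipping.

A duplex tag is a random double-stranded barcode whose two halves (alpha,
beta) read in the two orders alpha+beta and beta+alpha on reads deriving from
the two strands of one source molecule.  All reads sharing one (tag, strand
order) form a read family; the per-position majority call over a family is a
single-strand consensus sequence (SSCS), which removes independent sequencing
errors.  Pairing the two complementary SSCS of one molecule and keeping only
positions where they agree yields the duplex consensus sequence (DCS), which
additionally removes strand-lineage (PCR) artifacts: a true mutation is
present as complementary substitutions on both strands, an artifact is not.

Reads arrive aligned, so both strand families are already in reference
orientation and DCS agreement is plain base equality.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TaggedRead",
    "ReadFamily",
    "ConsensusSequence",
    "IndelEvent",
    "canonical_tag",
    "group_reads_by_tag",
    "build_sscs",
    "build_dcs",
    "clip_ends",
    "consensus_pipeline",
    "read_tagged_sam",
    "write_consensus_sam",
]

CLIP_5P = 5  # bases masked at the 5' end of each consensus
CLIP_3P = 6  # bases masked at the 3' end

_CODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass(frozen=True)
class IndelEvent:
    """An insertion/deletion relative to the reference, anchored 1-based.

    ``position`` is the reference base immediately left of the event;
    insertions carry the inserted sequence, deletions the deleted length.
    """

    position: int
    kind: str  # "ins" | "del"
    payload: str  # inserted sequence, or str(deleted length)

    def __post_init__(self) -> None:
        if self.kind not in {"ins", "del"}:
            raise ValueError(f"indel kind must be ins/del, got {self.kind!r}")


@dataclass(frozen=True)
class TaggedRead:
    """One aligned raw read carrying a duplex tag."""

    name: str
    tag: str
    strand_order: str  # "ab" | "ba"
    start: int  # 1-based reference start
    bases: str
    indels: tuple[IndelEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.strand_order not in {"ab", "ba"}:
            raise ValueError(f"strand_order must be ab/ba, got {self.strand_order!r}")
        if len(self.tag) % 2 != 0 or not self.tag:
            raise ValueError("tag must have two equal-length halves")


@dataclass
class ReadFamily:
    tag: str
    strand_order: str
    start: int
    members: list[TaggedRead] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsensusSequence:
    """An SSCS or DCS in reference coordinates; N marks uncallable positions."""

    kind: str  # "SSCS" | "DCS"
    tag: str  # canonical tag
    start: int
    bases: str
    family_sizes: tuple[int, ...]
    indels: tuple[IndelEvent, ...] = ()

    @property
    def evaluable_length(self) -> int:
        return sum(1 for b in self.bases if b != "N")

    def positions(self) -> range:
        return range(self.start, self.start + len(self.bases))


def canonical_tag(tag: str) -> str:
    """Lexicographically smaller of alpha+beta and beta+alpha."""
    half = len(tag) // 2
    swapped = tag[half:] + tag[:half]
    return min(tag, swapped)


def parse_read_name(name: str) -> Optional[tuple[str, str]]:
    """Extract (tag, strand_order) from a read name like ``mol12#ACGT.../ab``."""
    if "#" not in name:
        return None
    tail = name.rsplit("#", 1)[1]
    if "/" not in tail:
        return None
    tag, order = tail.rsplit("/", 1)
    if order not in {"ab", "ba"} or not tag or len(tag) % 2 or set(tag) - set("ACGTN"):
        return None
    return tag, order


def group_reads_by_tag(reads: Iterable[TaggedRead]) -> tuple[list[ReadFamily], int]:
    """Partition reads into families keyed by (tag, strand order, start).

    Families mixing alignment starts are split rather than averaged.  Returns
    the families plus the count of reads dropped for unparseable tags (reads
    constructed through :class:`TaggedRead` always parse; the counter matters
    for SAM input, where :func:`read_tagged_sam` funnels through here).
    """
    families: dict[tuple[str, str, int], ReadFamily] = {}
    dropped = 0
    for read in reads:
        if read is None:
            dropped += 1
            continue
        key = (read.tag, read.strand_order, read.start)
        fam = families.get(key)
        if fam is None:
            fam = families[key] = ReadFamily(read.tag, read.strand_order, read.start)
        fam.members.append(read)
    if dropped:
        logger.warning("dropped %d reads with unparseable tags", dropped)
    return list(families.values()), dropped


def _stack(family: ReadFamily) -> np.ndarray:
    width = max(len(r.bases) for r in family.members)
    mat = np.full((len(family), width), ord("N"), dtype=np.uint8)
    for i, read in enumerate(family.members):
        if read.start != family.start:
            raise ValueError("family not co-aligned")
        row = np.frombuffer(read.bases.encode(), dtype=np.uint8)
        mat[i, : row.size] = row
    return mat


def build_sscs(
    family: ReadFamily,
    min_family_size: int = 3,
    consensus_threshold: float = 0.7,
) -> Optional[ConsensusSequence]:
    """Single-strand consensus of one read family.

    Per position the most frequent non-N base is called when its fraction of
    covering reads reaches ``consensus_threshold``; otherwise N.  Families
    below ``min_family_size`` yield no consensus.  Indel events follow the
    same threshold rule.
    """
    if min_family_size < 1:
        raise ValueError("min_family_size must be >= 1")
    if not 0.5 < consensus_threshold <= 1.0:
        raise ValueError("consensus_threshold must be in (0.5, 1]")
    if len(family) < min_family_size:
        return None
    mat = _stack(family)
    counts = np.stack([(mat == ord(b)).sum(axis=0) for b in "ACGT"])  # 4 x width
    covering = counts.sum(axis=0)
    best = counts.argmax(axis=0)
    best_n = counts.max(axis=0)
    ok = (covering > 0) & (best_n >= consensus_threshold * covering)
    out = np.where(ok, _CODE[best], ord("N")).astype(np.uint8)

    indel_counts = Counter(ev for read in family.members for ev in read.indels)
    kept = tuple(
        ev for ev, c in sorted(indel_counts.items(), key=lambda kv: (kv[0].position, kv[0].kind))
        if c >= consensus_threshold * len(family)
    )
    return ConsensusSequence(
        kind="SSCS",
        tag=canonical_tag(family.tag),
        start=family.start,
        bases=out.tobytes().decode(),
        family_sizes=(len(family),),
        indels=kept,
    )


def build_dcs(sscs_ab: ConsensusSequence, sscs_ba: ConsensusSequence) -> Optional[ConsensusSequence]:
    """Duplex consensus of the two complementary single-strand consensuses.

    Over the reference overlap the DCS carries a base only where both SSCS
    agree; a disagreement cannot be scored and becomes N.  Indels must be
    present in both strands.  Returns None when the inputs do not overlap.
    """
    if sscs_ab.tag != sscs_ba.tag:
        raise ValueError("SSCS pair must share a canonical tag")
    lo = max(sscs_ab.start, sscs_ba.start)
    hi = min(sscs_ab.start + len(sscs_ab.bases), sscs_ba.start + len(sscs_ba.bases))
    if hi <= lo:
        return None
    a = np.frombuffer(sscs_ab.bases.encode(), dtype=np.uint8)[lo - sscs_ab.start : hi - sscs_ab.start]
    b = np.frombuffer(sscs_ba.bases.encode(), dtype=np.uint8)[lo - sscs_ba.start : hi - sscs_ba.start]
    agree = (a == b) & (a != ord("N"))
    out = np.where(agree, a, ord("N")).astype(np.uint8)
    indels = tuple(sorted(set(sscs_ab.indels) & set(sscs_ba.indels),
                          key=lambda ev: (ev.position, ev.kind)))
    return ConsensusSequence(
        kind="DCS",
        tag=sscs_ab.tag,
        start=lo,
        bases=out.tobytes().decode(),
        family_sizes=sscs_ab.family_sizes + sscs_ba.family_sizes,
        indels=indels,
    )


def clip_ends(consensus: ConsensusSequence, clip_5p: int = CLIP_5P, clip_3p: int = CLIP_3P) -> ConsensusSequence:
    """Mask the first ``clip_5p`` and last ``clip_3p`` bases (end-repair and
    ligation artifacts concentrate there); masked positions are N and drop out
    of all downstream counting.  A length-L consensus keeps max(0, L-11)
    evaluable bases at the defaults."""
    n = len(consensus.bases)
    if n <= clip_5p + clip_3p:
        masked = "N" * n
    else:
        masked = "N" * clip_5p + consensus.bases[clip_5p : n - clip_3p] + "N" * clip_3p
    lo = consensus.start + clip_5p
    hi = consensus.start + n - clip_3p
    indels = tuple(ev for ev in consensus.indels if lo <= ev.position < hi)
    return replace(consensus, bases=masked, indels=indels)


def pair_sscs(sscs_list: Sequence[tuple[str, ConsensusSequence]]) -> tuple[list[ConsensusSequence], int]:
    """Pair (strand_order, SSCS) items by canonical tag + start into DCS.

    Returns (dcs_list, unpaired_count); unpaired SSCS are excluded from DCS
    depth entirely.
    """
    by_key: dict[tuple[str, int], dict[str, ConsensusSequence]] = defaultdict(dict)
    for order, sscs in sscs_list:
        if order in by_key[(sscs.tag, sscs.start)]:
            raise ValueError(f"two SSCS with same strand order for tag {sscs.tag}")
        by_key[(sscs.tag, sscs.start)][order] = sscs
    dcs = []
    unpaired = 0
    for orders in by_key.values():
        if len(orders) == 2:
            d = build_dcs(orders["ab"], orders["ba"])
            if d is not None:
                dcs.append(d)
        else:
            unpaired += 1
    if unpaired:
        logger.info("%d unpaired SSCS excluded from DCS depth", unpaired)
    return dcs, unpaired


def consensus_pipeline(
    reads: Iterable[TaggedRead],
    min_family_size: int = 3,
    consensus_threshold: float = 0.7,
    clip: bool = True,
) -> dict:
    """Raw tagged reads -> clipped SSCS and DCS, with family bookkeeping.

    Returns a dict with keys ``sscs``, ``dcs`` (lists of clipped
    :class:`ConsensusSequence`), ``families``, ``dropped_reads``,
    ``unpaired_sscs``, ``family_size_counts``.
    """
    families, dropped = group_reads_by_tag(reads)
    sscs_tagged = []
    for fam in families:
        s = build_sscs(fam, min_family_size, consensus_threshold)
        if s is not None:
            sscs_tagged.append((fam.strand_order, s))
    dcs, unpaired = pair_sscs(sscs_tagged)
    sscs = [s for _, s in sscs_tagged]
    if clip:
        sscs = [clip_ends(s) for s in sscs]
        dcs = [clip_ends(d) for d in dcs]
    return {
        "sscs": sscs,
        "dcs": dcs,
        "families": len(families),
        "dropped_reads": dropped,
        "unpaired_sscs": unpaired,
        "family_size_counts": Counter(len(f) for f in families),
    }


# ---------------------------------------------------------------------------
# SAM I/O (text SAM; the duplex tag travels in the read name as ...#TAG/ab)
# ---------------------------------------------------------------------------

def read_tagged_sam(path) -> tuple[list[TaggedRead], int]:
    """Read aligned tagged reads from a SAM file.

    Only aligned records with match-only CIGARs are converted; reads whose
    names carry no parseable ``#TAG/order`` suffix are counted as dropped.
    Indels in the CIGAR are captured as anchored :class:`IndelEvent` items.
    """
    import pysam

    reads: list[TaggedRead] = []
    dropped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                dropped += 1
                continue
            parsed = parse_read_name(rec.query_name)
            if parsed is None:
                dropped += 1
                continue
            tag, order = parsed
            bases = []
            indels = []
            qpos = 0
            rpos = rec.reference_start + 1  # to 1-based
            for op, ln in rec.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X
                    bases.append(rec.query_sequence[qpos : qpos + ln])
                    qpos += ln
                    rpos += ln
                elif op == 1:  # I
                    indels.append(IndelEvent(rpos - 1, "ins", rec.query_sequence[qpos : qpos + ln]))
                    qpos += ln
                elif op == 2:  # D
                    indels.append(IndelEvent(rpos - 1, "del", str(ln)))
                    bases.append("N" * ln)  # deleted span uncallable in this read
                    rpos += ln
                elif op == 4:  # soft clip
                    qpos += ln
                else:
                    raise ValueError(f"unsupported CIGAR op {op} in {rec.query_name}")
            reads.append(
                TaggedRead(
                    name=rec.query_name,
                    tag=tag,
                    strand_order=order,
                    start=rec.reference_start + 1,
                    bases="".join(bases),
                    indels=tuple(indels),
                )
            )
    if dropped:
        logger.warning("dropped %d unaligned/untagged SAM records", dropped)
    return reads, dropped


def write_consensus_sam(consensuses: Sequence[ConsensusSequence], reference, path) -> None:
    """Write consensus sequences as an aligned text SAM against ``reference``."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference.name, "LN": reference.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, cons in enumerate(consensuses):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = f"{cons.kind.lower()}{i}#{cons.tag}/ab"
            rec.query_sequence = cons.bases
            rec.reference_id = 0
            rec.reference_start = cons.start - 1
            rec.mapping_quality = 60
            rec.cigartuples = [(0, len(cons.bases))]
            rec.flag = 0
            fh.write(rec)
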