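"""Synthetic duplex-sequencing data with planted truth.

The generator emulates the physical hierarchy of a duplex library:

* a population of source molecules (fragments of a circular reference), each
  independently carrying planted variants with probability clonality/100;
* per molecule, two strand lineages (tag orders ``ab``/``ba``); PCR lineage
  errors hit a strand template once and are inherited by every read of that
  strand family — they survive single-strand consensus but not duplex
  consensus;
* per read, independent sequencing errors at the conventional NGS background
  rate (1e-2 to 1e-3 per base), which majority voting inside a family
  removes.

Everything is driven by one ``numpy.random.Generator``; a fixed seed makes
all outputs bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .consensus import IndelEvent, TaggedRead
from .reference import GeneRecord, Reference, MT_CODON_TABLE
from .tiers import DEFAULT_CUTOFFS, TierCutoffs, classify_clonality

__all__ = [
    "PlantedVariant",
    "SimulationConfig",
    "Molecule",
    "TruthTable",
    "make_toy_reference",
    "simulate_population",
    "simulate_duplex_reads",
    "simulate_reads",
    "write_reads_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SENSE_CODONS = sorted(c for c, aa in MT_CODON_TABLE.items() if aa != "*")


@dataclass(frozen=True)
class PlantedVariant:
    position: int  # 1-based, L strand
    ref: str
    alt: str
    clonality_pct: float  # planted molecule fraction x 100

    def __post_init__(self) -> None:
        if not 0.0 < self.clonality_pct <= 100.0:
            raise ValueError(f"clonality must be in (0, 100], got {self.clonality_pct}")
        if self.ref == self.alt or self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"invalid substitution {self.ref}>{self.alt}")

    def expected_tier(self, cutoffs: TierCutoffs = DEFAULT_CUTOFFS) -> str:
        return classify_clonality(self.clonality_pct, cutoffs)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study's conditions.

    ``read_length`` doubles as the fragment length (reads cover their source
    fragment end to end).  Family sizes are drawn from a discretised
    log-normal around ``family_size_mean`` unless ``family_size_constant``
    pins them.
    """

    n_molecules: int = 1000
    read_length: int = 150
    family_size_mean: float = 3.0
    family_size_sigma: float = 0.4
    family_size_constant: Optional[int] = None
    pcr_error_rate: float = 1e-4  # per base per strand lineage
    seq_error_rate: float = 1e-2  # per base per read
    indel_error_rate: float = 0.0  # per read: one single-base ins/del
    tag_half_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pcr_error_rate", "seq_error_rate", "indel_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if self.n_molecules < 1 or self.read_length < 1 or self.tag_half_length < 1:
            raise ValueError("n_molecules, read_length and tag_half_length must be positive")


@dataclass(frozen=True)
class Molecule:
    """One source fragment: reference window plus the variants it carries."""

    molecule_id: int
    start: int  # 1-based reference start
    length: int
    variants: tuple[PlantedVariant, ...] = ()


@dataclass
class TruthTable:
    """Planted truth and injected-error bookkeeping for recovery tests."""

    planted: list[PlantedVariant] = field(default_factory=list)
    realized_counts: dict[tuple[int, str, str], int] = field(default_factory=dict)
    n_molecules: int = 0
    pcr_errors_injected: int = 0
    seq_errors_injected: int = 0

    def expected_tiers(self, cutoffs: TierCutoffs = DEFAULT_CUTOFFS) -> dict[tuple[int, str, str], str]:
        return {(v.position, v.ref, v.alt): v.expected_tier(cutoffs) for v in self.planted}


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_toy_reference(
    length: int,
    gene_layout: Sequence[tuple[str, float]],
    seed: int,
) -> tuple[Reference, list[GeneRecord]]:
    """Random circular reference with a simple end-to-end gene layout.

    ``gene_layout`` is a sequence of (category, size) segments placed from
    position 1; a size in (0, 1] is a fraction of ``length``, larger values
    are base pairs.  Protein segments are trimmed to whole codons and filled
    with sense codons (ATG first), so toy genes translate cleanly.  Any
    remainder becomes one annotated noncoding record.  Deterministic under
    ``seed``.
    """
    if length < 60:
        raise ValueError("toy reference length must be >= 60")
    sizes = []
    for category, size in gene_layout:
        bp = int(round(size * length)) if 0 < size <= 1 else int(size)
        sizes.append((category, bp))
    if sum(bp for _, bp in sizes) > length:
        raise ValueError("gene layout exceeds reference length")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, length)
    records: list[GeneRecord] = []
    counters = {"protein": 0, "tRNA": 0, "rRNA": 0, "noncoding": 0}
    prefix = {"protein": "P", "tRNA": "T", "rRNA": "R", "noncoding": "NC"}
    cursor = 1
    for category, bp in sizes:
        if category == "protein":
            bp -= bp % 3
            if bp < 3:
                raise ValueError("protein gene shorter than one codon")
            codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=bp // 3)]
            codons[0] = "ATG"
            seq[cursor - 1 : cursor - 1 + bp] = list("".join(codons))
        counters[category] += 1
        records.append(
            GeneRecord(
                gene=f"{prefix[category]}{counters[category]}",
                category=category,
                start=cursor,
                end=cursor + bp - 1,
            )
        )
        cursor += bp
    if cursor <= length:
        records.append(GeneRecord(gene="NC-tail", category="noncoding", start=cursor, end=length))
    return Reference(name=f"toy{length}", sequence="".join(seq)), records


def simulate_population(
    reference: Reference,
    planted_variants: Sequence[PlantedVariant],
    n_molecules: int,
    rng: np.random.Generator,
    fragment_length: Optional[int] = None,
    uniform_starts: bool = True,
) -> tuple[list[Molecule], TruthTable]:
    """Draw the molecule population; carriage of each variant is independent
    Bernoulli(clonality/100) per molecule, so realized counts are binomial.

    Fragments start uniformly on the circle (or all at position 1 when
    ``uniform_starts`` is false) and span ``fragment_length`` bases (whole
    genome by default, capped at the genome length).
    """
    positions = [v.position for v in planted_variants]
    if len(set(positions)) != len(positions):
        raise ValueError("planted positions must be distinct")
    for v in planted_variants:
        if reference.base(v.position) != v.ref:
            raise ValueError(f"planted ref mismatch at m.{v.position}")
    frag = min(fragment_length or reference.length, reference.length)
    starts = (
        rng.integers(1, reference.length + 1, size=n_molecules)
        if uniform_starts
        else np.ones(n_molecules, dtype=int)
    )
    carried: list[list[PlantedVariant]] = [[] for _ in range(n_molecules)]
    truth = TruthTable(planted=list(planted_variants), n_molecules=n_molecules)
    for v in planted_variants:
        carriers = np.flatnonzero(rng.random(n_molecules) < v.clonality_pct / 100.0)
        truth.realized_counts[(v.position, v.ref, v.alt)] = int(carriers.size)
        for i in carriers:
            carried[i].append(v)
    molecules = [
        Molecule(i, int(starts[i]), frag, tuple(carried[i])) for i in range(n_molecules)
    ]
    return molecules, truth


def _draw_family_size(rng: np.random.Generator, config: SimulationConfig) -> int:
    if config.family_size_constant is not None:
        return config.family_size_constant
    mu = np.log(config.family_size_mean)
    return max(1, int(round(rng.lognormal(mean=mu, sigma=config.family_size_sigma))))


def _random_tag(rng: np.random.Generator, half: int) -> tuple[str, str]:
    alpha = bytes(_BASES[rng.integers(0, 4, size=half)]).decode()
    beta = bytes(_BASES[rng.integers(0, 4, size=half)]).decode()
    return alpha, beta


def simulate_duplex_reads(
    molecules: Sequence[Molecule],
    config: SimulationConfig,
    reference: Reference,
    rng: np.random.Generator,
    truth: Optional[TruthTable] = None,
) -> list[TaggedRead]:
    """Emit tagged reads for both strand families of every molecule.

    Per molecule: one random duplex tag; per strand: PCR lineage errors
    mutate the strand template once (shared by the whole family), then each
    read copies the template with independent sequencing errors.
    """
    if config.read_length > reference.length:
        raise ValueError("read_length exceeds molecule (reference) length")
    refcode = np.frombuffer(reference.sequence.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    ref_idx = lut[refcode]  # 0..3 per position
    L = config.read_length
    reads: list[TaggedRead] = []
    pcr_total = 0
    seq_total = 0
    for mol in molecules:
        span = (mol.start - 1 + np.arange(min(L, mol.length))) % reference.length
        template = ref_idx[span].copy()
        for v in mol.variants:
            offset = (v.position - mol.start) % reference.length
            if offset < template.size:
                template[offset] = int(lut[ord(v.alt)])
        alpha, beta = _random_tag(rng, config.tag_half_length)
        for order, tag in (("ab", alpha + beta), ("ba", beta + alpha)):
            strand = template.copy()
            n_pcr = rng.binomial(strand.size, config.pcr_error_rate)
            if n_pcr:
                pos = rng.choice(strand.size, size=n_pcr, replace=False)
                strand[pos] = (strand[pos] + 1 + rng.integers(0, 3, size=n_pcr)) % 4
                pcr_total += n_pcr
            k = _draw_family_size(rng, config)
            fam = np.tile(strand, (k, 1))
            if config.seq_error_rate > 0:
                err = rng.random(fam.shape) < config.seq_error_rate
                n_err = int(err.sum())
                if n_err:
                    fam[err] = (fam[err] + 1 + rng.integers(0, 3, size=n_err)) % 4
                    seq_total += n_err
            for j in range(k):
                indels: tuple[IndelEvent, ...] = ()
                if config.indel_error_rate > 0 and rng.random() < config.indel_error_rate:
                    at = int(rng.integers(1, strand.size))
                    if rng.random() < 0.5:
                        ins = "ACGT"[int(rng.integers(0, 4))]
                        indels = (IndelEvent(mol.start + at - 1, "ins", ins),)
                    else:
                        indels = (IndelEvent(mol.start + at - 1, "del", "1"),)
                reads.append(
                    TaggedRead(
                        name=f"mol{mol.molecule_id}.{j}#{tag}/{order}",
                        tag=tag,
                        strand_order=order,
                        start=mol.start,
                        bases=bytes(_BASES[fam[j]]).decode(),
                        indels=indels,
                    )
                )
    if truth is not None:
        truth.pcr_errors_injected += pcr_total
        truth.seq_errors_injected += seq_total
    return reads


def simulate_reads(
    reference: Reference,
    planted_variants: Sequence[PlantedVariant],
    config: SimulationConfig,
) -> tuple[list[TaggedRead], TruthTable]:
    """Population + read simulation in one call, seeded from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    molecules, truth = simulate_population(
        reference,
        planted_variants,
        config.n_molecules,
        rng,
        fragment_length=config.read_length,
    )
    reads = simulate_duplex_reads(molecules, config, reference, rng, truth)
    return reads, truth


def write_reads_sam(reads: Sequence[TaggedRead], reference: Reference, path) -> None:
    """Write simulated tagged reads as aligned text SAM (tag in the read name).

    Reads crossing the circular origin are wrapped to start inside
    [1, length]; the alignment is emitted as a plain match over the read.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference.name, "LN": reference.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = read.name
            rec.query_sequence = read.bases
            rec.reference_id = 0
            rec.reference_start = reference.wrap(read.start) - 1
            rec.mapping_quality = 60
            rec.cigartuples = [(0, len(read.bases))]
            rec.flag = 0
            fh.write(rec)
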