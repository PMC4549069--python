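"""Build the packaged synthetic rCRS-like reference sequence (one-off, deterministic).

The human rCRS sequence itself is not redistributable inside this package, so
the bundled FASTA is a synthetic stand-in constructed to share the properties
the analyses depend on:

* 16,569 bp, circular, L-strand coordinates;
* the authentic NC_012920 gene layout (``nc012920_genes.tsv``);
* rCRS L-strand base composition (A 0.309, C 0.313, G 0.131, T 0.247);
* inside protein genes, complete codons are sense codons of the vertebrate
  mitochondrial code sampled with composition-product weights on the gene's
  coding strand (a fully constrained codon inside a gene-gene overlap keeps
  whatever the earlier gene wrote, stop or not).

Run from the repository root:  python scripts/build_synthetic_rcrs.py
"""

from __future__ import annotations

import sys
from itertools import product
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mtduplex.reference import MT_CODON_TABLE, Reference, load_annotation, reverse_complement

SEED = 20150825  # fixed once; the fixture is part of the package, not re-rolled
LENGTH = 16569
# rCRS L-strand base composition
COMP = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}
SENSE_CODONS = sorted(c for c, aa in MT_CODON_TABLE.items() if aa != "*")
OUT = Path(__file__).resolve().parents[1] / "src" / "mtduplex" / "data" / "synthetic_rcrs.fa"


def strand_composition(strand: str) -> dict[str, float]:
    if strand == "L":
        return COMP
    comp = str.maketrans("ACGT", "TGCA")
    return {b.translate(comp): f for b, f in COMP.items()}


def sample_codon(rng: np.random.Generator, pattern: str, freqs: dict[str, float]) -> str:
    """Sample a sense codon matching ``pattern`` ('.' = free position)."""
    candidates = []
    weights = []
    free = [i for i, ch in enumerate(pattern) if ch == "."]
    for fill in product("ACGT", repeat=len(free)):
        codon = list(pattern)
        for i, b in zip(free, fill):
            codon[i] = b
        codon = "".join(codon)
        if MT_CODON_TABLE[codon] != "*":
            candidates.append(codon)
            weights.append(np.prod([freqs[b] for b in codon]))
    if not candidates:  # constrained pattern forces a stop; keep it as-is
        return pattern.replace(".", "A")
    w = np.asarray(weights, dtype=float)
    return candidates[rng.choice(len(candidates), p=w / w.sum())]


def main() -> None:
    rng = np.random.default_rng(SEED)
    bases = np.array(list("ACGT"))
    probs = np.array([COMP[b] for b in "ACGT"])
    seq = list(rng.choice(bases, size=LENGTH, p=probs))
    written = np.zeros(LENGTH, dtype=bool)

    scaffold = Reference("scaffold", "".join(seq))
    genes = load_annotation(Path(OUT).parent / "nc012920_genes.tsv", scaffold)

    for gene in genes:
        if gene.category != "protein":
            continue
        freqs = strand_composition(gene.coding_strand)
        n_codons = (gene.span - gene.frame_offset) // 3
        for ci in range(n_codons):
            if gene.coding_strand == "L":
                lpos = [gene.start - 1 + gene.frame_offset + 3 * ci + k for k in range(3)]
                pattern = "".join(seq[p] if written[p] else "." for p in lpos)
            else:
                # coding codon runs 3' -> 5' on the L strand
                lpos = [gene.end - 1 - gene.frame_offset - 3 * ci - k for k in range(3)]
                pattern = "".join(
                    reverse_complement(seq[p])[0] if written[p] else "." for p in lpos
                )
            if "." not in pattern:
                continue  # fully constrained by an earlier (overlapping) gene
            if ci == 0 and pattern == "...":
                codon = "ATG"
            else:
                codon = sample_codon(rng, pattern, freqs)
            for p, b in zip(lpos, codon):
                if not written[p]:
                    seq[p] = b if gene.coding_strand == "L" else reverse_complement(b)
                    written[p] = True

    sequence = "".join(seq)
    with open(OUT, "w") as fh:
        fh.write(">synthetic_rCRS NC_012920-layout synthetic stand-in, 16569 bp, circular\n")
        for i in range(0, LENGTH, 70):
            fh.write(sequence[i : i + 70] + "\n")
    counts = {b: sequence.count(b) for b in "ACGT"}
    print(f"wrote {OUT} ({LENGTH} bp), composition: "
          + ", ".join(f"{b}={c / LENGTH:.3f}" for b, c in counts.items()))


if __name__ == "__main__":
    main()
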