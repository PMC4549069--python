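# Methods

## Consensus model

A duplex library tags each source fragment with a two-half random barcode
(αβ). Reads from the two strands of one molecule carry the tag in opposite
half-order, so after alignment the reads partition into families keyed by
(tag, strand order, alignment start). Families that mix alignment starts are
split, never averaged. The pairing key between the two strand families is
the *canonical tag*, the lexicographically smaller of αβ and βα.

**SSCS.** Per aligned column of a family of ≥ `min_family_size` reads
(default 3), the most frequent base is called when its fraction of covering
reads reaches `consensus_threshold` (default 0.7); otherwise N. These
defaults follow the published duplex-sequencing protocol family; both are
config-exposed. Majority voting removes independent per-read sequencing
errors (at 10⁻² per base, a 3-read family passes a wrong base only if all
three reads err identically, ~4×10⁻⁸ per position).

**DCS.** Over the reference overlap of the two strand-family consensuses,
the DCS carries a base only where both agree (reads are aligned, so both
SSCS are already in reference orientation and agreement is plain equality);
disagreements and N propagate as N. A PCR error that arose in one strand
lineage appears in exactly one SSCS, so it becomes N in the DCS rather than
a false mutation — a duplex false call requires the *same* error
independently in both strands, which is why the duplex background sits below
5×10⁻⁸ while the single-strand background sits near the PCR lineage rate.

**End clipping.** The first 5 and last 6 bases of every consensus are masked
to N before counting (end-repair and ligation artifacts concentrate at
fragment termini), so a length-L consensus contributes max(0, L−11)
evaluable nucleotides. Denominators everywhere use this clipped, non-N
depth.

**Indels** are carried as anchored events on reads, kept in a consensus under
the same threshold rule (and both-strand rule for DCS), tiered by the same
clonality cutoffs, but excluded from point-mutation spectra and frequencies
and reported as their own class.

## Variant tiers and frequencies

Clonality is 100·(mutant count)/(DCS depth) at a position. Tiers partition
(0, 100]: rare ≤ 0.5 < low-het ≤ 20 < high-het < 95 ≤ homoplasmic. Positions
below `min_depth` (default 100 DCS calls — below that a clonality estimate
is too noisy to tier) contribute to denominators but yield no tiered calls.
The overall frequency of a tier counts each distinct (position, alt) once,
regardless of multiplicity; two different alternate alleles at one position
are two mutations (type-resolved spectra require alt-resolved counting).
Wilson score intervals (95% by default) accompany every frequency.

## Spectra

The 12 substitution types are counted in L-strand orientation; the frequency
denominator of type X>Y is the summed depth over covered positions whose
reference base is X. Complementary pairs collapse into 6 types for
fraction-of-all-mutations views. Strand bias between a complementary pair
(e.g. G>A vs C>T) is a Yates-corrected two-proportion test on the
(count, denominator) pairs. Trinucleotide contexts are canonicalised
pyrimidine-centred (purine-centred mutations are complemented, their context
reverse-complemented), giving 6×16 = 96 classes in fixed order (substitution
major, then 5′ base, then 3′ base); terminal positions take circular
neighbours. Pooling across samples sums unique-variant counts (a variant
shared by k samples contributes k — count-weighted, matching per-sample
panels summing to the pooled panel).

## Coding consequences

Coordinates are 1-based on the L strand; variants are named `m.{pos}{ref}>{alt}`.
Translation uses NCBI table 2 (TGA=W, ATA=M, AGA/AGG=stop) via Biopython's
codon table. Genes encoded on the H strand (MT-ND6 and eight tRNAs) are read
as the reverse complement. Trailing incomplete stop codons (completed by
polyadenylation in vivo) are excluded from codon arithmetic; a variant inside
two overlapping genes (ATP8/ATP6, ND4L/ND4) is evaluated once per gene. The
by-chance nonsynonymous expectation enumerates all 3 alternative bases at
every complete-codon position with equal weight, counting stop gains/losses
as nonsynonymous.

## The bundled reference fixture

The gene table (`nc012920_genes.tsv`) carries the authentic NC_012920 (rCRS)
coordinates: 13 protein genes, 22 tRNAs, 2 rRNAs, plus the two control-region
segments annotated as noncoding. The *noncoding fraction* is defined as the
share of bases in annotated noncoding records (the 1,122-bp control region,
6.77%), the convention behind the familiar "<7% noncoding" figure; the ~90 bp
of unannotated intergenic spacers are not counted.

The sequence (`synthetic_rcrs.fa`) is a clearly-labelled **synthetic
stand-in** for the rCRS, built once by `scripts/build_synthetic_rcrs.py`
(fixed seed): 16,569 bp with rCRS L-strand base composition (A .309, C .313,
G .131, T .247); inside protein genes, complete codons are sense codons of
table 2 sampled with composition-product weights on the gene's coding
strand, ATG first; codons fully constrained by an earlier overlapping gene
keep the earlier gene's bases. Consequences: length, gene complement,
noncoding share and all reading-frame machinery match the real genome, but
sequence-dependent quantities do not reproduce the real rCRS values — the
enumerated nonsynonymous expectation on the stand-in is 77.1%, whereas the
real rCRS codon usage gives 75.7%. The codon-weighting scheme was fixed
before that number was computed and is deliberately not adjusted toward it.

## Synthetic duplex generator

The generator mirrors the physical error hierarchy: each molecule is a
fragment (uniform start on the circle, length = `read_length`) carrying each
planted variant independently with probability clonality/100 (realized
counts binomial, recorded in a truth table); per strand lineage, PCR errors
at `pcr_error_rate` (default 10⁻⁴) mutate the strand template once and are
inherited by the whole family — creating exactly the SSCS-level artifact
class the DCS removes; per read, independent sequencing errors at
`seq_error_rate` (default 10⁻², the conventional NGS background).
Substitutions are uniform over the three alternatives by default; family
sizes follow a discretised log-normal around `family_size_mean` (true study
family-size distributions are unreported) or a constant. All randomness
flows through one seeded generator; outputs are bit-identical under a fixed
seed. Not modelled: quality scores, context-dependent error profiles beyond
an optional transition bias, indel errors beyond a single per-read rate, and
alignment artifacts (reads are emitted pre-aligned) — so passing tests
demonstrate the consensus/counting logic, not robustness to mapping error.

## Statistics

All tests are two-sided by default (matching the R defaults of `prop.test`,
`wilcox.test`, `cor.test`): Wilson score intervals in closed form (exact 0/1
endpoints at k=0/k=n); the 2-sample proportion test as the Yates-corrected
χ² on the 2×2 table with the correction floored at zero, df=1; Mann-Whitney
U with midrank ties, by exact enumeration of rank assignments when both
groups have ≤8 observations (C(16,8)=12,870 assignments at most) and by the
tie-corrected normal approximation with continuity correction otherwise;
Spearman/Pearson correlations via scipy. Raw p-values are reported
throughout; a Benjamini-Hochberg helper exists but defaults off. Exactly
equal proportions short-circuit to p=1 in report comparisons, because the χ²
formula degenerates when a table margin is zero.

## Problem sizes

Simulated checks run at desk scale by design: the background-floor check uses
16,000 molecules × 139 evaluable nt × 2 strand families (≈2.1×10⁶ duplex
nucleotides, enough that a 5×10⁻⁸ floor corresponds to ≲0.1 expected events),
tier-recovery uses 5,000 molecules over a 300-bp toy genome (binomial
fluctuation of a 0.2% plant stays within the rare tier with probability
≈1−10⁻⁵), and the null calibration of the proportion test uses 10⁴ replicates
of n=200 per arm.

## Known limitations

* No alignment or local realignment: inputs must arrive aligned, and
  coordinate errors upstream propagate.
* No NUMT filtering, haplogroup calling, copy-number inference, or
  cross-position phasing of heteroplasmies.
* The MITOMAP-style lookup and MutPred g-scores are user-supplied static
  files; nothing is fetched.
* Reads crossing the circular origin are handled by coordinate wrapping in
  pileups, but the emitted SAM records them as linear matches starting near
  the end of the contig.
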