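"""End-to-end orchestration: reads -> consensus -> calls -> spectra -> report.

A :class:`SampleReport` is the in-memory bundle every stage feeds; written to
disk it becomes a directory of TSVs plus ``summary.json`` so that two runs
can be compared (:func:`compare_samples`) without recomputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import consensus as cx
from .cohort import flag_new_variants, load_known_variants
from .reference import Reference, codon_changes, load_annotation, load_reference
from .spectra import (
    CONTEXT_CLASSES,
    ContextSpectrum,
    SpectrumTable,
    SUBSTITUTION_TYPES,
    TypeSpectrumRow,
    compare_context_fractions,
    context_spectrum,
    substitution_spectrum,
)
from .stats import TestResult, two_proportion_test
from .tiers import (
    TIER_NAMES,
    TierCutoffs,
    call_indels,
    call_variants,
    mutation_frequency,
    pileup,
    tier_distribution,
)

__all__ = ["PipelineConfig", "PipelineError", "SampleReport", "run_pipeline", "compare_samples"]


def _safe_prop_test(k1: int, n1: int, k2: int, n2: int):
    """Proportion test that short-circuits exactly-equal proportions to p=1
    (the Yates formula degenerates when a margin of the 2x2 table is zero)."""
    if k1 * n2 == k2 * n1:
        return TestResult(
            0.0, 1.0,
            "2-sample test for equality of proportions with continuity correction",
            k1 / n1 - k2 / n2,
        )
    return two_proportion_test(k1, n1, k2, n2)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    reference_path: str
    annotation_path: str
    reads_path: str
    known_variants_path: Optional[str] = None
    min_family_size: int = 3
    consensus_threshold: float = 0.7
    clip_5p: int = 5
    clip_3p: int = 6
    min_depth: int = 100
    rare_max: float = 0.5
    low_het_max: float = 20.0
    homoplasmic_min: float = 95.0
    confidence: float = 0.95
    seed: int = 0

    @property
    def cutoffs(self) -> TierCutoffs:
        return TierCutoffs(self.rare_max, self.low_het_max, self.homoplasmic_min)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        self.cutoffs  # raises if not strictly increasing
        for name in ("reference_path", "annotation_path", "reads_path", "known_variants_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError("validate", f"missing path for {name}: {value}")
        if not 0.5 < self.consensus_threshold <= 1.0:
            raise PipelineError("validate", "consensus_threshold must be in (0.5, 1]")


@dataclass
class SampleReport:
    reference_name: str
    variants: pd.DataFrame
    indels: pd.DataFrame
    spectrum12: pd.DataFrame
    context96: pd.DataFrame
    summary: dict = field(default_factory=dict)

    # -- round-trip -------------------------------------------------------
    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.indels.to_csv(out / "indels.tsv", sep="\t", index=False)
        self.spectrum12.to_csv(out / "spectrum_12type.tsv", sep="\t", index=False)
        self.context96.to_csv(out / "context_96class.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, out_dir) -> "SampleReport":
        out = Path(out_dir)
        with open(out / "summary.json") as fh:
            summary = json.load(fh)
        return cls(
            reference_name=summary["reference_name"],
            variants=pd.read_csv(out / "variants.tsv", sep="\t"),
            indels=pd.read_csv(out / "indels.tsv", sep="\t"),
            spectrum12=pd.read_csv(out / "spectrum_12type.tsv", sep="\t"),
            context96=pd.read_csv(out / "context_96class.tsv", sep="\t"),
            summary=summary,
        )

    # -- typed accessors --------------------------------------------------
    def context_counts(self, tier: str = "rare") -> ContextSpectrum:
        sub = self.context96[self.context96["tier"] == tier]
        counts = {cls: 0 for cls in CONTEXT_CLASSES}
        for row in sub.itertuples(index=False):
            counts[(row.trinucleotide, row.substitution)] = int(row.unique_count)
        return ContextSpectrum(counts)

    def spectrum_table(self, tier: str = "rare") -> SpectrumTable:
        sub = self.spectrum12[self.spectrum12["tier"] == tier]
        rows = {}
        for row in sub.itertuples(index=False):
            rows[row.substitution] = TypeSpectrumRow(
                row.substitution, int(row.unique_count), int(row.denominator),
                float(row.ci_low), float(row.ci_high),
            )
        for t in SUBSTITUTION_TYPES:
            rows.setdefault(t, TypeSpectrumRow(t, 0, 0, 0.0, 0.0))
        from .spectra import COLLAPSED_TYPES  # local to avoid cycle at import

        collapsed = {}
        for label in COLLAPSED_TYPES:
            a, b = label.split("/")
            collapsed[label] = rows[a].unique_count + rows[b].unique_count
        total = sum(collapsed.values())
        frac = {k: (100.0 * v / total if total else 0.0) for k, v in collapsed.items()}
        return SpectrumTable(rows, collapsed, frac)


def _annotate_variant(v, annotation, reference) -> tuple[str, str, str]:
    changes = codon_changes(v.position, v.ref_base, v.alt_base, annotation, reference)
    if changes:
        genes = ";".join(c.gene for c in changes)
        effects = ";".join(c.effect for c in changes)
        aa = ";".join(f"{c.ref_aa}{c.codon_index}{c.alt_aa}" for c in changes)
        return genes, effects, aa
    covering = [g.gene for g in annotation if g.category != "noncoding" and g.covers(v.position)]
    return (";".join(covering), "", "") if covering else ("", "", "")


def run_pipeline(config: PipelineConfig, out_dir=None) -> SampleReport:
    """Execute every stage on an aligned tagged SAM and assemble the report.

    Deterministic given the inputs; any stage failure raises
    :class:`PipelineError` labelled with the stage name.
    """
    config.validate()

    try:
        reference = load_reference(config.reference_path)
        annotation = load_annotation(config.annotation_path, reference)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage labelling
        raise PipelineError("load_reference", str(exc)) from exc

    try:
        reads, dropped = cx.read_tagged_sam(config.reads_path)
        bundle = cx.consensus_pipeline(
            reads,
            min_family_size=config.min_family_size,
            consensus_threshold=config.consensus_threshold,
        )
    except Exception as exc:
        raise PipelineError("consensus", str(exc)) from exc

    try:
        dcs_piles = pileup(bundle["dcs"], reference)
        sscs_piles = pileup(bundle["sscs"], reference)
        variants = call_variants(dcs_piles, config.min_depth, config.cutoffs)
        indel_calls = call_indels(dcs_piles, config.min_depth, config.cutoffs)
        sscs_variants = call_variants(sscs_piles, config.min_depth, config.cutoffs)
    except Exception as exc:
        raise PipelineError("call", str(exc)) from exc

    try:
        tier_tables12 = []
        tier_tables96 = []
        for tier in TIER_NAMES:
            tier_vars = [v for v in variants if v.tier == tier]
            spec = substitution_spectrum(tier_vars, dcs_piles, config.confidence)
            for t, row in spec.rows.items():
                tier_tables12.append(
                    {
                        "tier": tier, "substitution": t, "unique_count": row.unique_count,
                        "denominator": row.denominator, "frequency": row.frequency,
                        "ci_low": row.ci_low, "ci_high": row.ci_high,
                    }
                )
            ctx = context_spectrum(tier_vars, reference)
            for (tri, sub) in CONTEXT_CLASSES:
                tier_tables96.append(
                    {
                        "tier": tier, "trinucleotide": tri, "substitution": sub,
                        "unique_count": ctx.counts[(tri, sub)],
                        "fraction_pct": ctx.fraction_pct((tri, sub)),
                    }
                )
    except Exception as exc:
        raise PipelineError("spectrum", str(exc)) from exc

    try:
        var_rows = []
        known = load_known_variants(config.known_variants_path) if config.known_variants_path else {}
        flags = flag_new_variants([v.key for v in variants], known) if known or variants else None
        status = (
            {tuple(k): s for k, s in zip(flags[["position", "ref", "alt"]].itertuples(index=False, name=None), flags["status"])}
            if flags is not None and len(flags)
            else {}
        )
        for v in variants:
            genes, effects, aa = _annotate_variant(v, annotation, reference)
            var_rows.append(
                {
                    "name": v.name, "position": v.position, "ref": v.ref_base, "alt": v.alt_base,
                    "mutant_count": v.mutant_count, "depth": v.depth,
                    "clonality_pct": v.clonality_pct, "tier": v.tier,
                    "gene": genes, "effect": effects, "aa_change": aa,
                    "status": status.get(v.key, "new" if known else ""),
                }
            )
        variants_df = pd.DataFrame(
            var_rows,
            columns=["name", "position", "ref", "alt", "mutant_count", "depth",
                     "clonality_pct", "tier", "gene", "effect", "aa_change", "status"],
        )
        indels_df = pd.DataFrame(
            [
                {
                    "position": c.position, "kind": c.kind, "payload": c.payload,
                    "mutant_count": c.mutant_count, "depth": c.depth,
                    "clonality_pct": c.clonality_pct, "tier": c.tier,
                }
                for c in indel_calls
            ],
            columns=["position", "kind", "payload", "mutant_count", "depth", "clonality_pct", "tier"],
        )
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc

    try:
        dcs_nt = sum(p.depth for p in dcs_piles.values())
        sscs_nt = sum(p.depth for p in sscs_piles.values())
        freqs = {}
        for tier in TIER_NAMES:
            if dcs_nt:
                s = mutation_frequency(variants, dcs_piles, tier, config.confidence)
                freqs[tier] = {
                    "unique_mutations": s.unique_mutation_count,
                    "sequenced_nt": s.total_sequenced_nt,
                    "frequency": s.frequency,
                    "ci_low": s.ci_low, "ci_high": s.ci_high,
                }
        sscs_rare = (
            mutation_frequency(sscs_variants, sscs_piles, "rare", config.confidence).frequency
            if sscs_nt else 0.0
        )
        dcs_rare = freqs.get("rare", {}).get("frequency", 0.0)
        summary = {
            "reference_name": reference.name,
            "reference_length": reference.length,
            "families": bundle["families"],
            "dropped_reads": dropped + bundle["dropped_reads"],
            "unpaired_sscs": bundle["unpaired_sscs"],
            "sscs_count": len(bundle["sscs"]),
            "dcs_count": len(bundle["dcs"]),
            "mean_sscs_depth": sscs_nt / reference.length,
            "mean_dcs_depth": dcs_nt / reference.length,
            "sscs_sequenced_nt": sscs_nt,
            "dcs_sequenced_nt": dcs_nt,
            "sscs_rare_frequency": sscs_rare,
            "dcs_rare_frequency": dcs_rare,
            "sscs_dcs_ratio": (sscs_rare / dcs_rare) if dcs_rare else None,
            "tier_frequencies": freqs,
            "tier_distribution_pct": tier_distribution(variants) if variants else {},
            "n_point_variants": len({v.key for v in variants}),
            "n_indel_calls": len(indel_calls),
        }
    except Exception as exc:
        raise PipelineError("summarize", str(exc)) from exc

    report = SampleReport(
        reference_name=reference.name,
        variants=variants_df,
        indels=indels_df,
        spectrum12=pd.DataFrame(tier_tables12),
        context96=pd.DataFrame(tier_tables96),
        summary=summary,
    )
    if out_dir is not None:
        report.write(out_dir)
        cx.write_consensus_sam(bundle["dcs"], reference, Path(out_dir) / "dcs.sam")
    return report


def compare_samples(report_a: SampleReport, report_b: SampleReport, tier: str = "rare") -> dict:
    """Per-tier frequency, per-type and per-context comparison of two samples."""
    if report_a.reference_name != report_b.reference_name:
        raise ValueError("reports reference different genomes")
    out: dict = {"tier": tier}

    fa = report_a.summary["tier_frequencies"].get(tier)
    fb = report_b.summary["tier_frequencies"].get(tier)
    if fa and fb:
        test = _safe_prop_test(
            fa["unique_mutations"], fa["sequenced_nt"], fb["unique_mutations"], fb["sequenced_nt"]
        )
        out["frequency_test"] = {
            "freq_a": fa["frequency"], "freq_b": fb["frequency"],
            "statistic": test.statistic, "p_value": test.p_value,
        }

    spec_a, spec_b = report_a.spectrum_table(tier), report_b.spectrum_table(tier)
    type_tests = {}
    for t in SUBSTITUTION_TYPES:
        ra, rb = spec_a.rows[t], spec_b.rows[t]
        if ra.denominator and rb.denominator and (ra.unique_count or rb.unique_count):
            test = _safe_prop_test(ra.unique_count, ra.denominator, rb.unique_count, rb.denominator)
            type_tests[t] = {"p_value": test.p_value, "statistic": test.statistic}
    out["type_tests"] = type_tests

    ctx_a, ctx_b = report_a.context_counts(tier), report_b.context_counts(tier)
    context_tests = {}
    if ctx_a.total and ctx_b.total:
        for cls in CONTEXT_CLASSES:
            if ctx_a.counts[cls] or ctx_b.counts[cls]:
                fold, test = compare_context_fractions(ctx_a, ctx_b, cls)
                context_tests["".join(cls[0]) + ":" + cls[1]] = {
                    "fold_a_over_b": fold, "p_value": test.p_value,
                }
    out["context_tests"] = context_tests

    keys_a = set(report_a.variants.loc[report_a.variants["tier"] == tier, "name"])
    keys_b = set(report_b.variants.loc[report_b.variants["tier"] == tier, "name"])
    out["shared_variants"] = sorted(keys_a & keys_b)
    out["only_a"] = sorted(keys_a - keys_b)
    out["only_b"] = sorted(keys_b - keys_a)
    return out
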