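"""The custom variant-filtering cascade.

Four rule families reduce raw calls to the analyzable set:

1. quality — PHRED mapping quality >= 20, depth >= 20, alternate-allele
   depth >= 5 (inclusive minima).  For INDELs only the alternate-depth rule
   applies: small-indel mapping quality and total depth are unreliable, and
   the stated INDEL criterion is the supporting-read minimum alone.
2. population MAF — folded minor-allele frequency min(af, 1-af) >= 10% in
   any consulted reference panel excludes the variant; absent entries
   contribute nothing.
3. gene phenotype — the gene must carry a listed HGMD/OMIM phenotype and not
   be a non-disease-trait-only entry.  The exact variant need not be listed.
4. cohort frequency — an allele key carried by >= 10% of samples is removed
   from all carriers (local-artifact control).  Carriers are counted on the
   full input set, which keeps the cascade monotone in its thresholds and
   order-independent, and matches the rule's artifact-recurrence motivation
   (recurrent artifacts are recurrent regardless of per-call quality).

Missing quality fields fail closed (the quality rule is recorded).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .types import FilterConfig, GeneAnnotation, INDEL, VariantCall

__all__ = [
    "FilterOutcome",
    "quality_failures",
    "passes_quality",
    "passes_population_maf",
    "passes_gene_phenotype",
    "cohort_frequency_filter",
    "apply_filters",
]


@dataclass
class FilterOutcome:
    """Per-variant filter verdict: passed iff no rule failed."""

    key: tuple[str, int, str, str]
    sample_id: str
    passed: bool
    failed_rules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_rules):
            raise ValueError("passed must hold iff failed_rules is empty")


def quality_failures(v: VariantCall, cfg: FilterConfig) -> list[str]:
    """Names of violated quality sub-rules (MQ/DP skipped for INDELs)."""
    failed: list[str] = []
    if v.vclass != INDEL:
        if v.map_quality is None or v.map_quality < cfg.min_map_quality:
            failed.append("quality_mq")
        if v.depth is None or v.depth < cfg.min_depth:
            failed.append("quality_dp")
    if v.alt_depth is None or v.alt_depth < cfg.min_alt_depth:
        failed.append("quality_altdp")
    return failed


def passes_quality(v: VariantCall, cfg: FilterConfig) -> bool:
    return not quality_failures(v, cfg)


def passes_population_maf(v: VariantCall, cfg: FilterConfig) -> bool:
    """True unless the folded MAF reaches ``max_maf`` in any consulted panel."""
    panels = v.pop_af if cfg.reference_panels is None else {
        p: v.pop_af[p] for p in cfg.reference_panels if p in v.pop_af}
    for panel, af in panels.items():
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} for panel {panel!r} outside [0,1]")
        # panels report frequencies at <= 6 decimals; rounding the folded
        # value keeps the boundary exact (1 - 0.9 must fold to 0.1)
        if round(min(af, 1.0 - af), 9) >= cfg.max_maf:
            return False
    return True


def passes_gene_phenotype(v: VariantCall,
                          ann: Mapping[str, GeneAnnotation]) -> tuple[bool, str | None]:
    """Gene-level disease-annotation rule.

    Returns (passed, failed_rule_name); distinguishes a gene with no listed
    phenotype from one annotated only with non-disease traits.
    """
    a = ann.get(v.gene)
    if a is None or not a.has_hgmd_omim_phenotype:
        return False, "no_phenotype_gene"
    if a.is_non_disease_trait_only:
        return False, "non_disease_trait"
    return True, None


def cohort_frequency_filter(variants: Iterable[VariantCall],
                            n_samples: int,
                            cfg: FilterConfig) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls by cohort recurrence of their allele key.

    A key is removed from *all* carriers when distinct carriers / n_samples
    >= ``max_cohort_fraction``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    variants = list(variants)
    carriers = _carrier_counts(variants)
    retained, removed = [], []
    for v in variants:
        (removed if carriers[v.key] / n_samples >= cfg.max_cohort_fraction
         else retained).append(v)
    return retained, removed


def _carrier_counts(variants: Iterable[VariantCall]) -> Counter:
    seen = {(v.sample_id,) + v.key for v in variants}
    return Counter(t[1:] for t in seen)


def apply_filters(variants: Iterable[VariantCall],
                  ann: Mapping[str, GeneAnnotation],
                  cfg: FilterConfig,
                  n_samples: int) -> tuple[list[VariantCall], list[FilterOutcome]]:
    """Run the full cascade; one :class:`FilterOutcome` per input call.

    Every rule is evaluated for every variant (the outcome lists all
    violations, not just the first), so the retained set is independent of
    rule order.  Cohort-recurrence is counted on the full input set.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    variants = list(variants)
    carriers = _carrier_counts(variants)

    retained: list[VariantCall] = []
    outcomes: list[FilterOutcome] = []
    for v in variants:
        failed = quality_failures(v, cfg)
        if not passes_population_maf(v, cfg):
            failed.append("population_maf")
        ok, rule = passes_gene_phenotype(v, ann)
        if not ok:
            failed.append(rule)
        if carriers[v.key] / n_samples >= cfg.max_cohort_fraction:
            failed.append("cohort_frequency")
        outcomes.append(FilterOutcome(key=v.key, sample_id=v.sample_id,
                                      passed=not failed, failed_rules=failed))
        if not failed:
            retained.append(v)
    return retained, outcomes
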