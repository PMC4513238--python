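"""Gene-panel subsetting, per-person burden statistics, and the
cancer-vs-non-cancer carrier comparison.

Two panels are shipped: the 56-gene ACMG secondary-findings list, and a
57-gene cancer-predisposition panel (the 23 cancer-linked ACMG genes plus 34
genes common on clinical cancer NGS panels).  Manual pathogenicity scores
(1 = neutral … 5 = pathogenic) are an input table; the burden comparison
builds a carriers-of-score>=4 by cancer-status 2×2 table and attaches a
self-implemented two-sided Fisher exact p-value (minimum-likelihood
convention: sum hypergeometric probabilities of all tables with the observed
margins that are no more probable than the observed one).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .types import PanelDefinition, Participant, ScoredVariant

__all__ = [
    "ACMG56_GENES",
    "CANCER57_GENES",
    "acmg56_panel",
    "cancer57_panel",
    "subset_to_panel",
    "PerPersonCounts",
    "per_person_counts",
    "fisher_exact_2x2",
    "BurdenComparison",
    "compare_burden",
]

# ACMG secondary-findings v1.0 list (56 genes).
ACMG56_GENES = (
    "APC", "MYH11", "ACTA2", "TMEM43", "DSP", "PKP2", "DSG2", "DSC2",
    "SCN5A", "RYR2", "LMNA", "MYBPC3", "MYH7", "TNNT2", "TNNI3", "TPM1",
    "MYL3", "ACTC1", "PRKAG2", "GLA", "MYL2", "LDLR", "APOB", "PCSK9",
    "BRCA1", "BRCA2", "TP53", "STK11", "MLH1", "MSH2", "MSH6", "PMS2",
    "MUTYH", "VHL", "MEN1", "RET", "NTRK1", "PTEN", "RB1", "SDHD",
    "SDHAF2", "SDHC", "SDHB", "TSC1", "TSC2", "WT1", "NF2", "COL3A1",
    "FBN1", "TGFBR1", "TGFBR2", "SMAD3", "KCNQ1", "KCNH2", "RYR1",
    "CACNA1S",
)

# The 23 cancer-linked genes within the ACMG list.
_ACMG_CANCER = (
    "APC", "BRCA1", "BRCA2", "TP53", "STK11", "MLH1", "MSH2", "MSH6",
    "PMS2", "MUTYH", "VHL", "MEN1", "RET", "PTEN", "RB1", "SDHD",
    "SDHAF2", "SDHC", "SDHB", "TSC1", "TSC2", "WT1", "NF2",
)

# 34 additional genes from clinical cancer-predisposition NGS panels.
_EXTRA_CANCER = (
    "ATM", "ATR", "BRIP1", "PALB2", "CHEK2", "CDH1", "CDKN2A", "CDK4",
    "BAP1", "BARD1", "BMPR1A", "SMAD4", "EPCAM", "FANCA", "FANCC",
    "FLCN", "GREM1", "HOXB13", "KIT", "MAX", "MET", "MITF", "NBN",
    "NF1", "PDGFRA", "POLD1", "POLE", "PRKAR1A", "PTCH1", "RAD51C",
    "RAD51D", "SMARCA4", "SUFU", "XRCC2",
)

CANCER57_GENES = _ACMG_CANCER + _EXTRA_CANCER

assert len(set(ACMG56_GENES)) == 56
assert len(set(CANCER57_GENES)) == 57
assert set(_ACMG_CANCER) <= set(ACMG56_GENES)


def acmg56_panel() -> PanelDefinition:
    return PanelDefinition(name="acmg56", genes=frozenset(ACMG56_GENES))


def cancer57_panel() -> PanelDefinition:
    return PanelDefinition(name="cancer57", genes=frozenset(CANCER57_GENES))


def subset_to_panel(scored: Sequence[ScoredVariant],
                    panel: PanelDefinition) -> list[ScoredVariant]:
    """Variants whose gene belongs to the panel, order preserved."""
    if not panel.genes:
        raise ValueError(f"panel {panel.name!r} is empty")
    return [s for s in scored if s.variant.gene in panel.genes]


@dataclass
class PerPersonCounts:
    """Per-person variant-count summary over the whole cohort (zero-variant
    participants included in the denominator)."""

    mean: float          # one decimal place
    mean_exact: float
    median: float
    min: int
    max: int
    n_zero: int
    n_participants: int
    n_variants: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def per_person_counts(variants: Sequence[ScoredVariant],
                      participants: Sequence[Participant]) -> PerPersonCounts:
    if not participants:
        raise ValueError("participants must be nonempty")
    counts = {p.sample_id: 0 for p in participants}
    for s in variants:
        sid = s.variant.sample_id
        if sid in counts:
            counts[sid] += 1
    vals = sorted(counts.values())
    n = len(vals)
    median = (vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2)
    mean_exact = sum(vals) / n
    return PerPersonCounts(
        mean=round(mean_exact, 1), mean_exact=mean_exact, median=float(median),
        min=vals[0], max=vals[-1], n_zero=sum(1 for v in vals if v == 0),
        n_participants=n, n_variants=sum(vals))


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact test on a 2×2 contingency table.

    The p-value sums hypergeometric probabilities, over all tables with the
    observed margins, of outcomes no more probable than the observed one
    (with a 1e-7 relative tolerance for probability ties) — the convention
    of standard statistical software.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(int(x) != x for x in cells):
        raise ValueError("table cells must be integers")
    a, b, c, d = (int(x) for x in cells)
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("at least one margin must be positive")
    r1, c1 = a + b, a + c

    def logp(x: int) -> float:
        return (_log_comb(r1, x) + _log_comb(n - r1, c1 - x) - _log_comb(n, c1))

    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    lp_obs = logp(a)
    cutoff = lp_obs + 1e-7          # relative tolerance in log space
    p = sum(math.exp(lp) for x in range(lo, hi + 1)
            if (lp := logp(x)) <= cutoff)
    return min(p, 1.0)


@dataclass
class BurdenComparison:
    """Cancer vs non-cancer panel-variant burden with a Fisher carrier test."""

    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    per_person: tuple[PerPersonCounts, PerPersonCounts]
    threshold: int
    contingency: tuple[tuple[int, int], tuple[int, int]]
    fisher_p: float

    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "group_sizes": list(self.group_sizes),
            "per_person": [pp.to_dict() for pp in self.per_person],
            "threshold": self.threshold,
            "contingency": [list(r) for r in self.contingency],
            "fisher_p": self.fisher_p,
        }


def compare_burden(scored_panel_variants: Sequence[ScoredVariant],
                   participants: Sequence[Participant],
                   pathogenicity: Mapping[tuple, int],
                   threshold: int = 4) -> BurdenComparison:
    """Split the cohort by invasive-cancer status and compare panel burden.

    Carriers are participants with at least one panel variant whose manual
    pathogenicity score reaches ``threshold`` (default 4, likely pathogenic);
    participants absent from the variant list count as zero-variant
    non-carriers.
    """
    for score in pathogenicity.values():
        if not 1 <= score <= 5:
            raise ValueError(f"pathogenicity score {score} outside 1..5")
    cancer = [p for p in participants if p.has_invasive_cancer]
    control = [p for p in participants if not p.has_invasive_cancer]
    carriers: set[str] = set()
    for s in scored_panel_variants:
        if pathogenicity.get(s.variant.key, 0) >= threshold:
            carriers.add(s.variant.sample_id)
    k_cancer = sum(1 for p in cancer if p.sample_id in carriers)
    k_control = sum(1 for p in control if p.sample_id in carriers)
    table = ((k_cancer, len(cancer) - k_cancer),
             (k_control, len(control) - k_control))
    return BurdenComparison(
        group_labels=("cancer", "non_cancer"),
        group_sizes=(len(cancer), len(control)),
        per_person=(per_person_counts(scored_panel_variants, cancer),
                    per_person_counts(scored_panel_variants, control)),
        threshold=threshold,
        contingency=table,
        fisher_p=fisher_exact_2x2(table),
    )
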