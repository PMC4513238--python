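"""Cross-tabulation, cohort summaries, rendering, and pipeline orchestration.

The central product is the cross-tabulation of scored variants: four panels
(tier × variant class), each split by inheritance class, each cell carrying
total / match / no-match / cannot-assess counts.  The text renderer mirrors
the conventional presentation in which the two GWAS-SNP sub-rows (novel vs
exact allele) are also shown aggregated as an "All SNP" row.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .types import (
    INDEL,
    INHERITANCE_CLASSES,
    SNV,
    Participant,
    ScoredVariant,
)
from .scoring import PhenotypeView

__all__ = [
    "CellCounts",
    "CrossTab",
    "CohortSummary",
    "build_crosstab",
    "summarize_cohort",
    "render",
    "parse_crosstab_json",
]

PANELS = ((1, SNV), (1, INDEL), (2, SNV), (2, INDEL))


@dataclass
class CellCounts:
    n: int = 0
    n_yes: int = 0
    n_no: int = 0
    n_x: int = 0

    def check(self) -> None:
        if self.n != self.n_yes + self.n_no + self.n_x:
            raise ValueError("cell total must equal yes+no+x")


@dataclass
class CrossTab:
    """(tier, vclass, inheritance class) → Yes/No/X counts, plus totals."""

    cells: dict[tuple[int, str, str], CellCounts] = field(default_factory=dict)

    def cell(self, tier: int, vclass: str, inh: str) -> CellCounts:
        return self.cells.setdefault((tier, vclass, inh), CellCounts())

    def panel_total(self, tier: int, vclass: str) -> CellCounts:
        out = CellCounts()
        for inh in INHERITANCE_CLASSES:
            c = self.cells.get((tier, vclass, inh), CellCounts())
            out.n += c.n
            out.n_yes += c.n_yes
            out.n_no += c.n_no
            out.n_x += c.n_x
        return out

    def grand_total(self) -> CellCounts:
        out = CellCounts()
        for tier, vclass in PANELS:
            p = self.panel_total(tier, vclass)
            out.n += p.n
            out.n_yes += p.n_yes
            out.n_no += p.n_no
            out.n_x += p.n_x
        return out

    def tier_total(self, tier: int) -> int:
        return sum(self.panel_total(tier, vc).n for vc in (SNV, INDEL))

    def percentages(self) -> dict[str, int]:
        """Nearest-integer percentages of the grand Yes/No/X split."""
        g = self.grand_total()
        if g.n == 0:
            return {"yes": 0, "no": 0, "x": 0}
        return {
            "yes": round(100 * g.n_yes / g.n),
            "no": round(100 * g.n_no / g.n),
            "x": round(100 * g.n_x / g.n),
        }

    def validate(self) -> None:
        for c in self.cells.values():
            c.check()


def build_crosstab(scored: Iterable[ScoredVariant]) -> CrossTab:
    """Aggregate scored variants into the cross-tabulation (all cells kept,
    zeros included, so rendering is shape-stable)."""
    ct = CrossTab()
    for tier, vclass in PANELS:
        for inh in INHERITANCE_CLASSES:
            ct.cell(tier, vclass, inh)
    for s in scored:
        c = ct.cell(s.tiered.tier, s.variant.vclass, s.inh_class)
        c.n += 1
        if s.score == "YES":
            c.n_yes += 1
        elif s.score == "NO":
            c.n_no += 1
        else:
            c.n_x += 1
    ct.validate()
    return ct


@dataclass
class CohortSummary:
    """Headline cohort counts after filtering/classification/scoring."""

    n_participants: int
    n_tier1: int
    n_tier2: int
    n_total: int
    per_person_mean: float            # one decimal place
    per_person_mean_exact: float
    per_person_min: int
    per_person_max: int
    n_yes: int
    n_no: int
    n_x: int
    pct: dict[str, int]
    n_phenotypes: int | None = None
    n_phenotypes_matched: int | None = None
    n_participants_no_match: int | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize_cohort(scored: Sequence[ScoredVariant],
                     participants: Sequence[Participant],
                     crosstab: CrossTab,
                     phenotype_view: PhenotypeView | None = None) -> CohortSummary:
    if not participants:
        raise ValueError("participants must be nonempty")
    per_person = {p.sample_id: 0 for p in participants}
    for s in scored:
        per_person[s.variant.sample_id] += 1
    g = crosstab.grand_total()
    counts = list(per_person.values())
    mean_exact = len(scored) / len(participants)
    return CohortSummary(
        n_participants=len(participants),
        n_tier1=crosstab.tier_total(1),
        n_tier2=crosstab.tier_total(2),
        n_total=g.n,
        per_person_mean=round(mean_exact, 1),
        per_person_mean_exact=mean_exact,
        per_person_min=min(counts),
        per_person_max=max(counts),
        n_yes=g.n_yes,
        n_no=g.n_no,
        n_x=g.n_x,
        pct=crosstab.percentages(),
        n_phenotypes=phenotype_view.n_phenotypes if phenotype_view else None,
        n_phenotypes_matched=phenotype_view.n_matched if phenotype_view else None,
        n_participants_no_match=(phenotype_view.n_participants_no_match
                                 if phenotype_view else None),
    )


# ---------------------------------------------------------------------------
# rendering

_ROW_ORDER = ["AD", "AD_AR", "DIGENIC", "AR", "XLR", "XLD",
              "SNP_all", "SNP_novel", "SNP_exact", "OTHERS"]

_ROW_LABEL = {
    "AD": "AD", "AD_AR": "AD/AR", "DIGENIC": "Digenic", "AR": "AR",
    "XLR": "XLR", "XLD": "XLD", "SNP_all": "All SNP",
    "SNP_novel": "Novel SNP in gene", "SNP_exact": "Exact variant",
    "OTHERS": "Others",
}


def _crosstab_to_obj(ct: CrossTab) -> dict:
    cells = {}
    for (tier, vclass, inh), c in sorted(ct.cells.items(), key=lambda kv: str(kv[0])):
        cells[f"{tier}|{vclass}|{inh}"] = [c.n, c.n_yes, c.n_no, c.n_x]
    g = ct.grand_total()
    return {
        "cells": cells,
        "panel_totals": {f"{t}|{vc}": [p.n, p.n_yes, p.n_no, p.n_x]
                         for t, vc in PANELS for p in [ct.panel_total(t, vc)]},
        "grand_total": [g.n, g.n_yes, g.n_no, g.n_x],
        "percentages": ct.percentages(),
    }


def parse_crosstab_json(doc: str) -> CrossTab:
    """Inverse of the JSON renderer; round-trips an identical CrossTab."""
    obj = json.loads(doc)
    ct = CrossTab()
    for key, (n, y, no, x) in obj["cells"].items():
        tier, vclass, inh = key.split("|")
        ct.cells[(int(tier), vclass, inh)] = CellCounts(n, y, no, x)
    ct.validate()
    return ct


def _render_tsv(ct: CrossTab) -> str:
    lines = ["tier\tvclass\tinh_class\tn\tn_yes\tn_no\tn_x"]
    for (tier, vclass) in PANELS:
        for inh in INHERITANCE_CLASSES:
            c = ct.cells.get((tier, vclass, inh), CellCounts())
            lines.append(f"{tier}\t{vclass}\t{inh}\t{c.n}\t{c.n_yes}\t{c.n_no}\t{c.n_x}")
        p = ct.panel_total(tier, vclass)
        lines.append(f"{tier}\t{vclass}\tTOTAL\t{p.n}\t{p.n_yes}\t{p.n_no}\t{p.n_x}")
    g = ct.grand_total()
    lines.append(f"ALL\tALL\tTOTAL\t{g.n}\t{g.n_yes}\t{g.n_no}\t{g.n_x}")
    return "\n".join(lines) + "\n"


def _render_text(ct: CrossTab) -> str:
    out = []
    for tier, vclass in PANELS:
        out.append(f"Tier-{tier} {vclass}".ljust(24)
                   + "variants   match  no-match  cannot-assess")
        for row in _ROW_ORDER:
            if row == "SNP_all":
                a = ct.cells.get((tier, vclass, "SNP_novel"), CellCounts())
                b = ct.cells.get((tier, vclass, "SNP_exact"), CellCounts())
                c = CellCounts(a.n + b.n, a.n_yes + b.n_yes,
                               a.n_no + b.n_no, a.n_x + b.n_x)
            else:
                c = ct.cells.get((tier, vclass, row), CellCounts())
            out.append(f"  {_ROW_LABEL[row]:<22}{c.n:>8}{c.n_yes:>8}{c.n_no:>10}{c.n_x:>15}")
        p = ct.panel_total(tier, vclass)
        out.append(f"  {'Total':<22}{p.n:>8}{p.n_yes:>8}{p.n_no:>10}{p.n_x:>15}")
        out.append("")
    g = ct.grand_total()
    pct = ct.percentages()
    out.append(f"Grand total {g.n}: match {g.n_yes} ({pct['yes']}%), "
               f"no-match {g.n_no} ({pct['no']}%), "
               f"cannot-assess {g.n_x} ({pct['x']}%)")
    return "\n".join(out) + "\n"


def render(crosstab: CrossTab,
           summary: CohortSummary | None = None,
           format: str = "text") -> str:
    """Render the cross-tabulation as ``tsv``, ``json`` or ``text``."""
    if format == "json":
        obj = _crosstab_to_obj(crosstab)
        if summary is not None:
            obj["summary"] = summary.to_dict()
        return json.dumps(obj, indent=2, sort_keys=True) + "\n"
    if format == "tsv":
        return _render_tsv(crosstab)
    if format == "text":
        doc = _render_text(crosstab)
        if summary is not None:
            doc += (f"\nCohort: {summary.n_participants} participants, "
                    f"{summary.n_total} variants "
                    f"(~{round(summary.per_person_mean_exact)}/person, "
                    f"{summary.n_tier1} Tier-1, {summary.n_tier2} Tier-2)\n")
        return doc
    raise ValueError(f"unknown render format {format!r}; use tsv, json or text")


# ---------------------------------------------------------------------------
# pipeline orchestration

def run_pipeline(cohort,
                 out_dir: str | os.PathLike | None = None,
                 filter_config=None,
                 lexicon=None,
                 panels: Mapping[str, object] | None = None,
                 pathogenicity: Mapping[tuple, int] | None = None) -> dict:
    """Filter → classify → score → cross-tabulate → (optional) panel stats.

    ``cohort`` is a :class:`~exophen.simulate.SyntheticCohort` or any object
    with ``variants``, ``annotations``, ``participants`` attributes.  Stage
    counts are logged and the conservation identity (inputs = removed +
    unclassified + scored) is asserted.  Returns a dict with the scored
    variants, cross-tab, summary, phenotype view, panel reports and stage
    log; artifacts are written under ``out_dir`` when given.
    """
    from . import io as eio
    from .filters import apply_filters
    from .scoring import phenotype_centric_view, score_cohort
    from .tiers import classify_all
    from .types import FilterConfig
    from .panels import compare_burden, per_person_counts, subset_to_panel

    cfg = filter_config or FilterConfig()
    variants = list(cohort.variants)
    participants = list(cohort.participants)
    anns = cohort.annotations

    retained, outcomes = apply_filters(variants, anns, cfg, len(participants))
    tiered = classify_all(retained)
    scored = score_cohort(tiered, anns, participants, lex=lexicon)
    crosstab = build_crosstab(scored)
    view = phenotype_centric_view(scored, participants, anns, lex=lexicon)
    summary = summarize_cohort(scored, participants, crosstab, view)

    n_removed = sum(1 for o in outcomes if not o.passed)
    n_unclassified = len(retained) - len(tiered)
    log = [
        {"stage": "input", "n": len(variants)},
        {"stage": "filtered_out", "n": n_removed,
         "by_rule": _rule_counts(outcomes)},
        {"stage": "retained", "n": len(retained)},
        {"stage": "unclassified", "n": n_unclassified},
        {"stage": "scored", "n": len(scored)},
    ]
    if len(variants) != n_removed + n_unclassified + len(scored):
        raise AssertionError("variant conservation violated across stages")

    panel_reports = {}
    for name, panel in (panels or {}).items():
        sub = subset_to_panel(scored, panel)
        rep = {"n_variants": len(sub),
               "n_tier1": sum(1 for s in sub if s.tiered.tier == 1),
               "n_tier2": sum(1 for s in sub if s.tiered.tier == 2),
               "per_person": per_person_counts(sub, participants).to_dict()}
        if pathogenicity is not None:
            rep["burden"] = compare_burden(sub, participants, pathogenicity).to_dict()
        panel_reports[name] = rep

    result = {"scored": scored, "crosstab": crosstab, "summary": summary,
              "phenotype_view": view, "outcomes": outcomes,
              "panel_reports": panel_reports, "stage_log": log}

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        eio.write_result_table(scored, os.path.join(out_dir, "scored.tsv"))
        for fmt, fname in (("json", "crosstab.json"), ("tsv", "crosstab.tsv"),
                           ("text", "crosstab.txt")):
            with open(os.path.join(out_dir, fname), "w", encoding="utf-8",
                      newline="\n") as fh:
                fh.write(render(crosstab, summary, format=fmt))
        with open(os.path.join(out_dir, "stage_log.json"), "w",
                  encoding="utf-8", newline="\n") as fh:
            json.dump(log, fh, indent=2)
        with open(os.path.join(out_dir, "panel_reports.json"), "w",
                  encoding="utf-8", newline="\n") as fh:
            json.dump(panel_reports, fh, indent=2)
    return result


def _rule_counts(outcomes) -> dict[str, int]:
    counts: dict[str, int] = {}
    for o in outcomes:
        for r in o.failed_rules:
            counts[r] = counts.get(r, 0) + 1
    return counts
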