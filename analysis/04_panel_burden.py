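#!/usr/bin/env python
"""Gene-panel subsetting and cancer-burden comparison.

Subsets the scored variants to the ACMG-56 and cancer-57 panels, summarizes
per-person burden, and tests whether likely-pathogenic carriers are enriched
among participants with invasive cancer (two-sided Fisher exact test).

Usage: python analysis/04_panel_burden.py [--cohort DIR] [--scored TSV] [--out JSON]
"""
import argparse
import json
import os

from exophen import compare_burden, per_person_counts, subset_to_panel
from exophen import io as eio
from exophen.simulate import read_cohort_inputs


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--scored", default="results/scored.tsv")
    ap.add_argument("--out", default="results/panel_report.json")
    args = ap.parse_args()

    cohort = read_cohort_inputs(args.cohort)
    scored = eio.read_result_table(args.scored)

    report = {}
    for name, panel in cohort.panels.items():
        sub = subset_to_panel(scored, panel)
        pp = per_person_counts(sub, cohort.participants)
        report[name] = {
            "n_variants": len(sub),
            "n_tier1": sum(1 for s in sub if s.tiered.tier == 1),
            "n_tier2": sum(1 for s in sub if s.tiered.tier == 2),
            "per_person": pp.to_dict(),
        }
        print(f"{name}: {len(sub)} variants "
              f"({report[name]['n_tier1']} Tier-1), "
              f"mean {pp.mean}/person (median {pp.median:g}, "
              f"range {pp.min}-{pp.max}, {pp.n_zero} with none)")
        if name == "cancer57" and cohort.pathogenicity:
            b = compare_burden(sub, cohort.participants, cohort.pathogenicity)
            report[name]["burden"] = b.to_dict()
            (k1, m1), (k2, m2) = b.contingency
            print(f"  likely-pathogenic carriers: {k1}/{k1 + m1} with cancer "
                  f"vs {k2}/{k2 + m2} without; Fisher p = {b.fisher_p:.2f}")

    os.makedirs(os.path.dirname(os.path.abspath(args.out)), exist_ok=True)
    with open(args.out, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    print(f"report written to {args.out}")


if __name__ == "__main__":
    main()
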