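#!/usr/bin/env python
"""Apply the custom filter cascade to the simulated cohort.

Reads results/cohort/, applies the quality / population-MAF /
gene-phenotype / cohort-recurrence rules, reports per-rule removals, and
writes the retained annotated calls plus per-variant outcomes.

Usage: python analysis/02_filter_variants.py [--in DIR] [--out DIR]
"""
import argparse
import csv
import os
from collections import Counter

from exophen import FilterConfig, apply_filters
from exophen.simulate import read_cohort_inputs
from exophen import io as eio


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="in_dir", default="results/cohort")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cohort = read_cohort_inputs(args.in_dir)
    cfg = FilterConfig()
    retained, outcomes = apply_filters(cohort.variants, cohort.annotations,
                                       cfg, len(cohort.participants))

    os.makedirs(args.out, exist_ok=True)
    eio.write_variant_annotations(retained,
                                  os.path.join(args.out, "filtered_annotations.tsv"))
    with open(os.path.join(args.out, "filter_outcomes.tsv"), "w",
              encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, dialect="excel-tab", lineterminator="\n")
        w.writerow(["sample_id", "chrom", "pos", "ref", "alt", "passed",
                    "failed_rules"])
        for o in outcomes:
            w.writerow([o.sample_id, *o.key, o.passed, ",".join(o.failed_rules)])

    by_rule = Counter(r for o in outcomes for r in o.failed_rules)
    print(f"calls in      : {len(outcomes)}")
    print(f"calls retained: {len(retained)}")
    print(f"calls removed : {sum(1 for o in outcomes if not o.passed)}")
    for rule, n in sorted(by_rule.items()):
        print(f"  {rule:<20} {n}")


if __name__ == "__main__":
    main()
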