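# Methods

## Scope and data model

`exophen` models a retrospective WES cohort analysis in which the unit of
observation is a *per-sample variant call* annotated with gene-level disease
knowledge. Three input tables drive everything:

* **Calls** (VCF 4.2): genotype, total depth, alternate-allele depth and
  PHRED mapping quality per sample. Multi-allelic records are split into
  per-ALT calls (a `1/2` genotype yields two heterozygous calls); a haploid
  genotype on X/Y maps to hemizygous. Coordinates are 1-based as in VCF and
  INDELs are taken as given, without re-normalization. Functional
  annotations (consequence, SIFT/PolyPhen calls, gene symbol, per-panel
  allele frequencies) live in a sidecar TSV keyed by allele, which decouples
  the analysis from any annotation engine.
* **Gene annotations** (TSV): an HGMD/OMIM-style digest per gene —
  pipe-delimited phenotype descriptions, a disease-association flag, a
  non-disease-trait flag, the curated inheritance mode, and, for
  GWAS-association-only genes, the exact associated alleles.
* **Participants** (TSV): sex, free-text chart-review diagnoses, invasive
  cancer status.

## Filter cascade

Four independent predicates; a call is retained iff all pass, and every
violated rule is recorded per call:

| rule | pass condition | default |
|---|---|---|
| quality | MQ ≥ `min_map_quality`, DP ≥ `min_depth`, altDP ≥ `min_alt_depth` (inclusive minima) | 20 / 20 / 5 |
| population MAF | folded MAF `min(af, 1−af)` < `max_maf` in every consulted panel | 0.10 |
| gene phenotype | gene has a listed disease phenotype and is not trait-only | — |
| cohort recurrence | distinct carriers / n_samples < `max_cohort_fraction` | 0.10 |

Numerical choices: for INDELs only the alternate-depth rule applies (the
mapping-quality and depth criteria are stated for SNVs; the INDEL criterion
is the supporting-read minimum alone). Missing quality fields fail closed.
The folded MAF is rounded to 9 decimals before the boundary comparison so
that `1 − 0.9` folds to exactly 0.10 (panel frequencies carry at most ~6
significant decimals). Absent panel entries contribute nothing, and a call
with no frequency data passes — the filter acts only on reported
frequencies. The MAF rule is any-panel ("or" semantics).

Cohort recurrence counts *distinct carrier samples of the exact allele key*
on the **full input set**, not the quality-passing subset. This was a
genuinely open design point; the full-set convention was chosen because it
keeps the cascade monotone (tightening any threshold can only shrink the
retained set — counting on the quality-passing subset would let a stricter
mapping-quality threshold re-admit previously removed recurrent calls) and
order-independent, and because a recurrent artifact is recurrent regardless
of per-call quality.

## Tier classification

Pure function of (variant class, consequence, in-silico calls):
Tier-1 SNV = stop gain/loss, start loss, splice site; Tier-2 SNV = missense
with SIFT *or* PolyPhen damaging (both missing/benign ⇒ dropped); Tier-1
INDEL = frameshift or splice site; Tier-2 INDEL = in-frame codon change or
codon insertion/deletion. Everything else is non-reportable. The in-silico
requirement applies to missense SNVs only. Splice-site membership comes
from the annotated consequence (transcript models are out of scope); a
variant annotated both splice and missense would arrive as splice-site and
take Tier-1, the higher tier.

## Inheritance classes and Yes/No/X scoring

Mendelian modes pass through (AD, AD/AR, AR, XLR, XLD, digenic). SNP-mode
genes split into `SNP_exact` when the observed allele is in the gene's
recorded GWAS set, else `SNP_novel`. Y-linked genes, protective-only genes
and non-Mendelian genes with no medically observable phenotype collapse
into `OTHERS` (Y-linked and protective variants are inherently
cannot-assess in a chart-review design).

The verdict cascade is an explicit precedence order (the original judgment
was manual and examples, not a precedence, were recorded; this order is a
documented design choice):

1. OTHERS class → X
2. protective-only gene → X
3. sex-limited gene in the incompatible sex → X
4. phenotype not observable in a medical record → X
5. phenotype overlap → **YES**
6. monoallelic recessive genotype (heterozygous in an AR gene; heterozygous
   female for XLR) → X, *unless* the participant has a biallelic genotype
   in the gene (homozygous, or ≥ 2 distinct variants — a potential compound
   heterozygote; phasing is not modeled)
7. otherwise → **NO**

Overlap (5) precedes the carrier rule (6) so a matching recessive-gene
carrier scores YES; consequently AR rows can contain matches but never
no-match entries, reproducing the cross-tabulation's recessive pattern.
Hemizygous males in XLR genes are fully genotyped and assessable. Digenic
variants score by the same overlap rules as AD.

Overlap itself is codified as normalized keyword matching: lowercase, strip
punctuation, drop a small stopword list (articles/connectives plus generic
qualifiers such as "association", "susceptibility", "risk", "type"), then
test token-set intersection between any diagnosis and any gene phenotype.
A shipped synonym lexicon bridges the clinically evidenced pairs with no
shared token (deafness ↔ hearing loss, arrhythmogenic right ventricular
cardiomyopathy ↔ ventricular tachycardia, glaucoma ↔ glaucoma suspect,
nephropathy ↔ chronic renal failure, aneurysm ↔ abdominal aortic aneurysm,
osteoarthritis ↔ degenerative joint disease); the lexicon is closed
symmetrically. This is a deliberately lenient matcher, mirroring "overlapped
in some way"; it does not attempt clinical NLP or ontology mapping.

The phenotype-centric view inverts the question: a diagnosis counts as
explained when ≥ 1 YES-scored variant of that participant overlaps it
(set semantics — one diagnosis matched by several variants counts once).

## Panels and burden

The ACMG-56 secondary-findings panel and a 57-gene cancer-predisposition
panel (its 23 cancer-linked ACMG genes plus 34 genes common on clinical
cancer NGS panels) are shipped as plain gene lists. Burden summaries report
per-person counts with zero-variant participants in the denominator (mean
to one decimal, median, range, number with none). Manual pathogenicity
scores (1 = neutral … 5 = pathogenic) are an *input* table — curation is
not reproducible computation — validated to the 1–5 scale and applied at a
carrier threshold of ≥ 4 (likely pathogenic).

Fisher's exact test is self-implemented (log-gamma hypergeometric terms;
two-sided by the minimum-likelihood convention — sum over all tables with
the observed margins whose probability does not exceed the observed one,
with a 1e-7 relative tie tolerance). The test suite checks it cell-by-cell
against an exact rational-arithmetic enumeration oracle and against an
independent library implementation.

## The synthetic cohort generator

The generator emulates the inputs of such a study, not its sequencing: no
reads, no linkage disequilibrium, no mutation-rate model. Its contract is
*label recovery*: for any feasible cell specification, running the real
pipeline on the generated cohort reproduces the requested per-cell counts
exactly, and every spiked decoy fails exactly its named filter rule and is
eliminated. Determinism is per-seed; different seeds vary sampled positions
and identifiers, never counts. Construction details worth knowing:

* Vocabularies are disjoint (`MatchtermN` planted matches, `GenetraitN`
  gene-phenotype filler, `AilmentN` diagnosis filler), so no accidental
  keyword overlap can blur a cell.
* Cannot-assess cells are realized by the mechanism appropriate to the
  class: heterozygous carriers for AR, heterozygous females for XLR,
  unobservable-phenotype genes for the autosomal dominant family,
  sex-limited genes in incompatible carriers for the SNP classes, Y-linked
  (SNV) or protective-only (INDEL) genes for Others.
* Quality values are drawn comfortably inside the passing region (MQ 40–60,
  DP 30–99, altDP = DP/2) and allele frequencies inside the rare region,
  so cells are separated from filter boundaries; the boundaries themselves
  are exercised by dedicated unit tests.

### The fixture cohort

`reference_cohort_fixture()` is the deterministic 89-participant cohort whose cell
counts equal the published cross-tabulation: 7046 filtered variants
(644 Tier-1, 6402 Tier-2) with grand totals 202 match / 3710 no-match /
3134 cannot-assess. The published table is internally inconsistent in three
places (the GWAS-SNP sub-rows of both SNV panels do not sum to the printed
aggregate row that the printed panel and grand totals use, and the Tier-1
INDEL panel totals differ from their printed cell sums by six variants
shifted between no-match and cannot-assess). The fixture resolves this by
keeping the "novel" sub-rows exactly as printed and absorbing the
discrepancies into the "exact variant" sub-rows — the unique minimal
adjustment that makes every printed panel total and grand total reproduce;
the residual freedom is exactly which SNP sub-cell carries the difference.

Panel structure is planted on top: 161 variants in ACMG-only gene symbols
(13 Tier-1; per-person distribution with mean 1.8, median 2, range 0–6 and
15 zero-variant participants) and 115 in cancer-panel-only symbols
(3 Tier-1), with the two likely-pathogenic score-4 variants — a frameshift
and a missense — carried by two distinct cancer-group participants, giving
the 2/39 vs 0/50 carrier table (Fisher p = 0.189). With 115 total panel
variants, the cancer-group mean of 1.3 (range 0–3) forces the non-cancer
group to ~1.28 per person; a non-cancer mean of 1.1 is arithmetically
incompatible with the total and was not targeted. Diagnoses are shaped so
that the 73 participants carrying YES variants hold 636 diagnoses of which
146 (23%) are matched (two distinct matches each; additional YES variants
re-hit an existing match), and 16 participants have no match at all.

## What passing tests do and do not show

Exact label recovery on synthetic cohorts verifies the *rules* — the
cascade's boundary behavior, the precedence order, the counting conventions
— not the clinical judgment they stand in for. Real chart reviews contain
paraphrase, negation and context that keyword matching cannot see; real
annotation databases contain conflicting inheritance assignments; real
callsets contain quality pathologies the generator does not emulate.
Results on real cohorts therefore depend on the annotation and lexicon
supplied, and the shipped lexicon should be extended for any serious
application.

## Problem sizes

The fixture pipeline (≈ 7.1k calls, 7.2k gene annotations, 89 participants)
runs end to end in a few seconds; property suites use cohorts of ≤ 100
variants and Fisher tables with margins ≤ 12 (where exhaustive enumeration
is exact and instant). Note that label-recovery tests use cohorts of ≥ 11
participants: below that, a single carrier already exceeds the 10% cohort
recurrence threshold and the cascade removes every singleton — itself a
documented property of the threshold, not a bug.
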