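"""Inheritance classification and Yes/No/X genotype–phenotype scoring.

Each tiered variant is first mapped to an inheritance class.  Mendelian
modes (AD, AD/AR, AR, XLR, XLD, digenic) pass through; GWAS-association-only
(SNP) genes split by whether the observed allele is the exact associated
variant or merely falls in the same gene; Y-linked genes, protective-only
genes and non-Mendelian genes whose phenotype is not observable in a medical
record collapse into OTHERS.

The manual geneticist judgment — "does any reported phenotype of this gene
overlap the participant's diagnosis list?" — is codified as normalized
keyword overlap, optionally bridged by a synonym lexicon (e.g. deafness ↔
hearing loss).  The verdict is produced by an explicit decision cascade:

1. OTHERS class                       → X (others_category)
2. protective-only gene               → X (protective_variant)
3. sex-limited gene, incompatible sex → X (sex_incompatible)
4. phenotype not observable in EMR    → X (unobservable_phenotype)
5. phenotype overlap                  → YES
6. monoallelic recessive genotype     → X (heterozygous in an AR gene, or a
   heterozygous female for an XLR gene); skipped when the participant has a
   biallelic genotype in that gene (homozygous, or two distinct variants)
7. otherwise                          → NO

Overlap (5) is tested before the carrier rule (6) so that a recessive-gene
carrier whose chart matches the gene's phenotype scores YES: recessive rows
therefore never score NO, only YES or X.
"""
from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .types import (
    GeneAnnotation,
    Participant,
    ScoredVariant,
    TieredVariant,
)

__all__ = [
    "MatchLexicon",
    "default_lexicon",
    "normalize",
    "phenotype_overlap",
    "assign_inheritance",
    "score_variant",
    "score_cohort",
    "phenotype_centric_view",
    "PhenotypeView",
]

# Generic tokens that carry no phenotype identity on their own.
_STOPWORDS = frozenset({
    "a", "an", "and", "the", "of", "in", "with", "to", "for", "on", "by",
    "due", "or", "type", "association", "associated", "susceptibility",
    "risk", "increased", "reduced", "familial", "hereditary",
})

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def normalize(text: str) -> str:
    """Lowercase, strip punctuation, drop stopwords; returns a phrase."""
    tokens = [t for t in _TOKEN_RE.findall(text.lower()) if t not in _STOPWORDS]
    return " ".join(tokens)


def _tokens(text: str) -> frozenset[str]:
    return frozenset(normalize(text).split())


@dataclass
class MatchLexicon:
    """Symmetric synonym map between normalized phenotype phrases.

    ``pairs`` holds normalized phrase ↔ phrase links; the symmetric closure
    is taken at construction.  A phrase matches a free-text string when the
    phrase appears as a token subsequence of the normalized string.
    """

    pairs: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        closed: dict[str, set[str]] = defaultdict(set)
        for k, syns in self.pairs.items():
            nk = normalize(k)
            for s in syns:
                ns = normalize(s)
                if ns != nk:
                    closed[nk].add(ns)
                    closed[ns].add(nk)
        self.pairs = dict(closed)

    def synonyms(self, phrase: str) -> set[str]:
        return self.pairs.get(normalize(phrase), set())

    @classmethod
    def from_yaml(cls, path) -> "MatchLexicon":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls({k: set(v) for k, v in raw.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump({k: sorted(v) for k, v in sorted(self.pairs.items())},
                           fh, sort_keys=True)


def default_lexicon() -> MatchLexicon:
    """Synonym pairs covering the clinically evidenced bridges."""
    return MatchLexicon({
        "deafness": {"hearing loss"},
        "arrhythmogenic right ventricular cardiomyopathy": {"ventricular tachycardia"},
        "glaucoma": {"glaucoma suspect"},
        "nephropathy": {"chronic renal failure"},
        "aneurysm": {"abdominal aortic aneurysm"},
        "osteoarthritis": {"degenerative joint disease"},
    })


def _phrase_in(phrase: str, normalized_text: str) -> bool:
    return phrase in normalized_text.split() or f" {phrase} " in f" {normalized_text} "


def phenotype_overlap(gene_phenotypes: Sequence[str],
                      diagnoses: Sequence[str],
                      lex: MatchLexicon | None = None) -> bool:
    """True if any diagnosis shares a keyword with any gene phenotype.

    Sharing is direct token overlap after normalization, or a lexicon link:
    a synonym pair (p, d) with p contained in the phenotype and d in the
    diagnosis (or vice versa — the lexicon is symmetric).
    """
    if not gene_phenotypes or not diagnoses:
        return False
    pheno_norm = [normalize(p) for p in gene_phenotypes]
    diag_norm = [normalize(d) for d in diagnoses]
    pheno_tok = frozenset().union(*(frozenset(p.split()) for p in pheno_norm))
    for d in diag_norm:
        if pheno_tok & frozenset(d.split()):
            return True
    if lex is not None:
        for phrase, syns in lex.pairs.items():
            in_pheno = any(_phrase_in(phrase, p) for p in pheno_norm)
            in_diag = any(_phrase_in(phrase, d) for d in diag_norm)
            for syn in syns:
                if in_pheno and any(_phrase_in(syn, d) for d in diag_norm):
                    return True
                if in_diag and any(_phrase_in(syn, p) for p in pheno_norm):
                    return True
    return False


def assign_inheritance(v: TieredVariant, ann: GeneAnnotation) -> str:
    """Map a variant's gene annotation to a scoring inheritance class."""
    mode = ann.inheritance
    if mode == "YL" or ann.protective_only:
        return "OTHERS"
    if mode == "SNP":
        if not ann.observable_in_emr:
            return "OTHERS"
        return ("SNP_exact" if v.variant.key in ann.gwas_exact_positions
                else "SNP_novel")
    return mode


def _sex_incompatible(ann: GeneAnnotation, p: Participant) -> bool:
    return ((ann.sex_limited == "male_only" and p.sex == "F")
            or (ann.sex_limited == "female_only" and p.sex == "M"))


def score_variant(v: TieredVariant,
                  inh: str,
                  ann: GeneAnnotation,
                  p: Participant,
                  lex: MatchLexicon | None = None,
                  biallelic: bool = False) -> ScoredVariant:
    """Apply the Yes/No/X decision cascade to a single variant."""
    if inh == "OTHERS":
        return ScoredVariant(v, inh, "X", "others_category")
    if ann.protective_only:
        return ScoredVariant(v, inh, "X", "protective_variant")
    if _sex_incompatible(ann, p):
        return ScoredVariant(v, inh, "X", "sex_incompatible")
    if not ann.observable_in_emr:
        return ScoredVariant(v, inh, "X", "unobservable_phenotype")
    if phenotype_overlap(ann.phenotypes, p.diagnoses, lex):
        return ScoredVariant(v, inh, "YES", "phenotype_overlap")
    monoallelic = (
        (inh == "AR" and v.variant.zygosity == "heterozygous")
        or (inh == "XLR" and p.sex == "F" and v.variant.zygosity == "heterozygous"))
    if monoallelic and not biallelic:
        return ScoredVariant(v, inh, "X", "monoallelic_recessive")
    return ScoredVariant(v, inh, "NO", "no_overlap")


def _biallelic_genes(variants: Sequence[TieredVariant]) -> set[tuple[str, str]]:
    """(sample, gene) pairs with a biallelic genotype: homozygous, or two
    distinct variants in the gene (potential compound heterozygote; phasing
    is not modeled)."""
    keys: dict[tuple[str, str], set] = defaultdict(set)
    hom: set[tuple[str, str]] = set()
    for t in variants:
        v = t.variant
        keys[(v.sample_id, v.gene)].add(v.key)
        if v.zygosity == "homozygous_alt":
            hom.add((v.sample_id, v.gene))
    return hom | {sg for sg, ks in keys.items() if len(ks) >= 2}


def score_cohort(variants: Sequence[TieredVariant],
                 anns: Mapping[str, GeneAnnotation],
                 participants: Sequence[Participant],
                 lex: MatchLexicon | None = None) -> list[ScoredVariant]:
    """Score every tiered variant; deterministic and order-preserving."""
    by_id = {p.sample_id: p for p in participants}
    biallelic = _biallelic_genes(variants)
    out: list[ScoredVariant] = []
    for t in variants:
        v = t.variant
        p = by_id.get(v.sample_id)
        if p is None:
            raise KeyError(f"variant sample {v.sample_id!r} has no participant record")
        ann = anns.get(v.gene)
        if ann is None:
            raise KeyError(f"gene {v.gene!r} lacks an annotation (should be pre-filtered)")
        inh = assign_inheritance(t, ann)
        out.append(score_variant(t, inh, ann, p, lex,
                                 biallelic=(v.sample_id, v.gene) in biallelic))
    return out


@dataclass
class PhenotypeView:
    """Phenotype-centric summary: which diagnoses any YES variant explains."""

    per_participant: list[dict]
    n_phenotypes: int
    n_matched: int
    n_participants_no_match: int


def phenotype_centric_view(scored: Sequence[ScoredVariant],
                           participants: Sequence[Participant],
                           anns: Mapping[str, GeneAnnotation],
                           lex: MatchLexicon | None = None) -> PhenotypeView:
    """Count, per participant, diagnoses explained by >= 1 YES variant.

    A diagnosis is matched when at least one YES-scored variant of that
    participant has a gene phenotype overlapping it; a diagnosis matched by
    several variants counts once.
    """
    yes_genes: dict[str, set[str]] = defaultdict(set)
    for s in scored:
        if s.score == "YES":
            yes_genes[s.variant.sample_id].add(s.variant.gene)
    per_participant: list[dict] = []
    total_d = total_m = none_matched = 0
    for p in participants:
        matched = []
        for d in p.diagnoses:
            if any(phenotype_overlap(anns[g].phenotypes, [d], lex)
                   for g in sorted(yes_genes.get(p.sample_id, ()))):
                matched.append(d)
        per_participant.append({
            "sample_id": p.sample_id,
            "n_phenotypes": len(p.diagnoses),
            "n_matched": len(matched),
            "matched": matched,
        })
        total_d += len(p.diagnoses)
        total_m += len(matched)
        if not matched:
            none_matched += 1
    return PhenotypeView(per_participant=per_participant,
                         n_phenotypes=total_d,
                         n_matched=total_m,
                         n_participants_no_match=none_matched)
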