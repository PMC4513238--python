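"""Synthetic annotated-cohort generation.

The generator builds cohorts with the statistical structure the downstream
analysis assumes: for every requested (tier × variant-class × inheritance
class × score) cell it constructs variants, gene annotations and participant
diagnoses such that the real pipeline — filtering, tier classification,
inheritance assignment, Yes/No/X scoring — lands exactly the requested
number of variants in that cell.  Generator and pipeline are therefore
mutual oracles: label recovery is an exact, testable property.

Mechanics per cell:

* YES cells plant a controlled-vocabulary keyword shared between the gene's
  phenotype list and the carrier's diagnosis list (phenotype matching was a
  manual judgment in the underlying study; shared keywords make it
  deterministic here).
* AR / female-XLR cannot-assess cells use heterozygous carrier genotypes;
  autosomal-dominant-family cannot-assess cells use genes whose phenotype is
  not observable in a medical record; GWAS-SNP cannot-assess cells use
  sex-limited genes in carriers of the incompatible sex.
* "Others" cells use Y-linked genes (SNVs, hemizygous males) or
  protective-only genes (INDELs).
* SNP_exact vs SNP_novel is realized by placing the variant at, or away
  from, the gene's recorded GWAS position.

Decoys are constructed to fail exactly one named filter each; removing the
violated threshold re-admits them.

Vocabularies are disjoint by construction (``MatchtermN`` for planted
matches, ``GenetraitN`` for gene-phenotype filler, ``AilmentN`` for
diagnosis filler), so no accidental overlap can blur a cell.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .types import (
    INDEL,
    INHERITANCE_CLASSES,
    SCORES,
    SNV,
    FilterConfig,
    GeneAnnotation,
    PanelDefinition,
    Participant,
    VariantCall,
)
from . import io as eio
from .panels import ACMG56_GENES, CANCER57_GENES, acmg56_panel, cancer57_panel

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "spike_decoys",
    "reference_cohort_fixture",
    "REFERENCE_CELLS",
    "write_cohort",
    "read_cohort_inputs",
]

AUTOSOMES = [str(i) for i in range(1, 23)]

# (tier, vclass, inheritance class) -> (yes, no, x) — the published
# cross-tabulation.  Three cells deviate minimally from the printed sub-rows
# to restore internal consistency (the printed sub-rows do not sum to the
# printed aggregate rows that the published panel and grand totals use); see
# docs/methods.md for the reconciliation.
REFERENCE_CELLS: dict[tuple[int, str, str], tuple[int, int, int]] = {
    (1, SNV, "AD"): (3, 55, 2),
    (1, SNV, "AD_AR"): (1, 11, 1),
    (1, SNV, "DIGENIC"): (0, 2, 0),
    (1, SNV, "AR"): (2, 0, 90),
    (1, SNV, "XLR"): (1, 2, 8),
    (1, SNV, "XLD"): (0, 2, 0),
    (1, SNV, "SNP_novel"): (10, 122, 15),
    (1, SNV, "SNP_exact"): (1, 30, 3),
    (1, SNV, "OTHERS"): (0, 0, 13),
    (1, INDEL, "AD"): (4, 34, 1),
    (1, INDEL, "AD_AR"): (1, 16, 0),
    (1, INDEL, "DIGENIC"): (1, 6, 0),
    (1, INDEL, "AR"): (0, 0, 84),
    (1, INDEL, "XLR"): (0, 0, 0),
    (1, INDEL, "XLD"): (0, 0, 0),
    (1, INDEL, "SNP_novel"): (4, 97, 13),
    (1, INDEL, "SNP_exact"): (0, 6, 0),
    (1, INDEL, "OTHERS"): (0, 0, 3),
    (2, SNV, "AD"): (27, 861, 26),
    (2, SNV, "AD_AR"): (15, 145, 17),
    (2, SNV, "DIGENIC"): (4, 50, 4),
    (2, SNV, "AR"): (2, 0, 2127),
    (2, SNV, "XLR"): (0, 12, 39),
    (2, SNV, "XLD"): (0, 8, 3),
    (2, SNV, "SNP_novel"): (97, 1788, 285),
    (2, SNV, "SNP_exact"): (10, 109, 37),
    (2, SNV, "OTHERS"): (0, 0, 37),
    (2, INDEL, "AD"): (2, 179, 31),
    (2, INDEL, "AD_AR"): (4, 2, 0),
    (2, INDEL, "DIGENIC"): (0, 0, 0),
    (2, INDEL, "AR"): (2, 0, 111),
    (2, INDEL, "XLR"): (0, 11, 24),
    (2, INDEL, "XLD"): (0, 1, 0),
    (2, INDEL, "SNP_novel"): (11, 161, 26),
    (2, INDEL, "SNP_exact"): (0, 0, 0),
    (2, INDEL, "OTHERS"): (0, 0, 134),
}


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``cell_counts`` maps (tier, vclass, inheritance class, score) to the
    number of variants the pipeline must land in that cell.  Decoy counts add
    variants that each violate exactly one filter.  ``n_match_participants``
    restricts YES-variant carriers to the first k participants;
    ``matches_per_participant`` caps how many *distinct* planted diagnoses a
    carrier receives (further YES variants re-use an existing one).
    """

    n_participants: int
    seed: int = 0
    cell_counts: dict[tuple[int, str, str, str], int] = field(default_factory=dict)
    n_quality_fail_decoys: int = 0
    n_common_af_decoys: int = 0
    n_cohort_recurrent_decoys: int = 0
    n_no_phenotype_gene_decoys: int = 0
    n_non_disease_trait_decoys: int = 0
    fraction_cancer: float = 0.44
    fraction_male: float = 51 / 89
    n_match_participants: int | None = None
    matches_per_participant: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0 <= self.fraction_cancer <= 1:
            raise ValueError("fraction_cancer must be in [0,1]")
        for (tier, vclass, inh, score), count in self.cell_counts.items():
            if tier not in (1, 2) or vclass not in (SNV, INDEL):
                raise ValueError(f"bad cell key ({tier},{vclass},{inh},{score})")
            if inh not in INHERITANCE_CLASSES or score not in SCORES:
                raise ValueError(f"bad cell key ({tier},{vclass},{inh},{score})")
            if count < 0:
                raise ValueError("cell counts must be non-negative")
            if inh == "OTHERS" and score != "X" and count:
                raise ValueError(
                    f"infeasible cell ({tier},{vclass},{inh},{score}): "
                    "OTHERS variants are cannot-assess by definition")
            if inh == "AR" and score == "NO" and count:
                raise ValueError(
                    f"infeasible cell ({tier},{vclass},{inh},{score}): "
                    "heterozygous recessive carriers score YES or X, never NO")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its intended truth labels.

    ``truth`` maps (sample_id, chrom, pos, ref, alt) of every non-decoy
    variant to its intended (tier, vclass, inheritance class, score);
    ``decoys`` maps allele keys of spiked decoys to the filter rule each one
    violates.
    """

    participants: list[Participant]
    variants: list[VariantCall]
    annotations: dict[str, GeneAnnotation]
    truth: dict[tuple, tuple[int, str, str, str]] = field(default_factory=dict)
    decoys: dict[tuple, str] = field(default_factory=dict)
    panels: dict[str, PanelDefinition] = field(default_factory=dict)
    pathogenicity: dict[tuple, int] = field(default_factory=dict)

    def by_cell(self) -> dict[tuple, list[tuple]]:
        out: dict[tuple, list[tuple]] = {}
        for key, label in self.truth.items():
            out.setdefault(label, []).append(key)
        return out


class _Genome:
    """Deterministic position allocator over a 24-chromosome map."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.next_pos = {c: 100_000 for c in AUTOSOMES + ["X", "Y"]}

    def place(self, chrom: str | None = None) -> tuple[str, int]:
        if chrom is None:
            chrom = AUTOSOMES[int(self.rng.integers(len(AUTOSOMES)))]
        pos = self.next_pos[chrom]
        self.next_pos[chrom] = pos + int(self.rng.integers(10, 200))
        return chrom, pos


_T1_SNV_CSQ = ("stop_gained", "splice_site", "stop_lost", "start_lost")
_T1_INDEL_CSQ = ("frameshift", "splice_site")
_T2_INDEL_CSQ = ("inframe_codon_change", "codon_insertion_deletion")
_T2_SNV_PREDICTORS = (("damaging", "benign"), ("missing", "damaging"),
                      ("damaging", "damaging"), ("tolerated", "damaging"))


class _Builder:
    def __init__(self, spec: CohortSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.genome = _Genome(self.rng)
        self.participants = self._make_participants()
        self.annotations: dict[str, GeneAnnotation] = {}
        self.variants: list[VariantCall] = []
        self.truth: dict[tuple, tuple] = {}
        self.decoys: dict[tuple, str] = {}
        self._gene_n = 0
        self._term_n = 0
        pool_n = spec.n_match_participants or spec.n_participants
        self.match_pool = self.participants[:pool_n]
        self._pool_ptr = 0
        self._any_ptr = 0
        self._match_terms: dict[str, list[str]] = {}
        self._csq_ptr: dict[tuple, int] = {}

    # -- participants -------------------------------------------------------
    def _make_participants(self) -> list[Participant]:
        spec = self.spec
        n = spec.n_participants
        n_male = round(n * spec.fraction_male)
        n_cancer = round(n * spec.fraction_cancer)
        n_group1 = round(n * 39 / 89)
        out = []
        for i in range(n):
            # interleave sexes/cancer so every prefix of the cohort is mixed
            sex = "M" if (i * n_male) // n != ((i + 1) * n_male) // n else "F"
            cancer = (i * n_cancer) // n != ((i + 1) * n_cancer) // n
            out.append(Participant(
                sample_id=f"S{i + 1:03d}", sex=sex, diagnoses=[],
                has_invasive_cancer=cancer, group=1 if i < n_group1 else 2))
        return out

    # -- vocabulary ---------------------------------------------------------
    def _new_gene(self, prefix: str = "SG") -> str:
        self._gene_n += 1
        return f"{prefix}{self._gene_n:05d}"

    def _new_term(self, kind: str) -> str:
        self._term_n += 1
        return f"{kind}{self._term_n:05d}"

    # -- carrier selection --------------------------------------------------
    def _pick(self, pool: list[Participant], ptr_name: str,
              sex: str | None, cell: tuple) -> Participant:
        ptr = getattr(self, ptr_name)
        for off in range(len(pool)):
            p = pool[(ptr + off) % len(pool)]
            if sex is None or p.sex == sex:
                # advance past skipped members only when none were skipped,
                # so a sex-constrained pick does not cost others their turn
                if off == 0:
                    setattr(self, ptr_name, (ptr + 1) % len(pool))
                return p
        raise ValueError(
            f"infeasible cell {cell}: no participant of sex {sex} available")

    # -- variant construction ----------------------------------------------
    def _alleles(self, tier: int, vclass: str) -> tuple[str, str, str]:
        """(ref, alt, consequence) cycling through the cell's consequences."""
        key = (tier, vclass)
        i = self._csq_ptr.get(key, 0)
        self._csq_ptr[key] = i + 1
        if vclass == SNV:
            ref, alt = [("A", "T"), ("C", "T"), ("G", "A"), ("T", "C")][i % 4]
            csq = "missense" if tier == 2 else _T1_SNV_CSQ[i % 4]
            return ref, alt, csq
        csqs = _T1_INDEL_CSQ if tier == 1 else _T2_INDEL_CSQ
        ref, alt = [("AT", "A"), ("C", "CAG"), ("GAC", "G"), ("T", "TGC")][i % 4]
        return ref, alt, csqs[i % len(csqs)]

    def _base_call(self, sample: Participant, tier: int, vclass: str,
                   chrom: str | None, zygosity: str, gene: str) -> VariantCall:
        ref, alt, csq = self._alleles(tier, vclass)
        chrom, pos = self.genome.place(chrom)
        sift = polyphen = "missing"
        if tier == 2 and vclass == SNV:
            sift, polyphen = _T2_SNV_PREDICTORS[
                int(self.rng.integers(len(_T2_SNV_PREDICTORS)))]
        depth = int(self.rng.integers(30, 100))
        pop_af = {}
        if self.rng.random() < 0.7:
            pop_af["1000g"] = round(float(self.rng.uniform(0.0005, 0.09)), 4)
        return VariantCall(
            sample_id=sample.sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            vclass=vclass, zygosity=zygosity,
            map_quality=float(self.rng.integers(40, 61)), depth=depth,
            alt_depth=max(5, depth // 2), consequence=csq,
            sift=sift, polyphen=polyphen, gene=gene, pop_af=pop_af)

    def _gene_ann(self, gene: str, inheritance: str, phenotypes: list[str],
                  **kw) -> GeneAnnotation:
        ann = GeneAnnotation(gene=gene, phenotypes=phenotypes,
                             has_hgmd_omim_phenotype=bool(phenotypes),
                             inheritance=inheritance, **kw)
        self.annotations[gene] = ann
        return ann

    def _plant_match(self, carrier: Participant, gene_phenos: list[str]) -> None:
        """Give the carrier a diagnosis overlapping the gene's phenotypes,
        re-using an existing planted term once the per-participant cap of
        distinct matches is reached."""
        cap = self.spec.matches_per_participant
        terms = self._match_terms.setdefault(carrier.sample_id, [])
        if cap is None or len(terms) < cap:
            term = self._new_term("Matchterm")
            terms.append(term)
            carrier.diagnoses.append(term)
        else:
            term = terms[0]
        gene_phenos.insert(0, f"{term} disorder")

    # -- one cell -----------------------------------------------------------
    def build_cell(self, tier: int, vclass: str, inh: str, score: str,
                   count: int) -> None:
        cell = (tier, vclass, inh, score)
        for _ in range(count):
            gene = self._new_gene()
            phenos = [f"{self._new_term('Genetrait')} disorder"]
            chrom = None
            zyg = "heterozygous"
            ann_kw: dict = {}
            sex: str | None = None

            if inh in ("AD", "AD_AR", "DIGENIC"):
                mode = inh
                if score == "X":
                    ann_kw["observable_in_emr"] = False
            elif inh == "AR":
                mode = "AR"
            elif inh == "XLR":
                mode, chrom = "XLR", "X"
                if score == "X":
                    sex, zyg = "F", "heterozygous"
                else:
                    sex, zyg = "M", "hemizygous"
            elif inh == "XLD":
                mode, chrom, sex = "XLD", "X", "F"
                if score == "X":
                    ann_kw["observable_in_emr"] = False
            elif inh in ("SNP_novel", "SNP_exact"):
                mode = "SNP"
                if score == "X":
                    ann_kw["sex_limited"] = "male_only"
                    sex = "F"
            else:  # OTHERS
                if vclass == SNV:
                    mode, chrom, zyg, sex = "YL", "Y", "hemizygous", "M"
                else:
                    mode = "AD"
                    ann_kw["protective_only"] = True

            if score == "YES":
                carrier = self._pick(self.match_pool, "_pool_ptr", sex, cell)
            else:
                carrier = self._pick(self.participants, "_any_ptr", sex, cell)

            v = self._base_call(carrier, tier, vclass, chrom, zyg, gene)
            if score == "YES":
                self._plant_match(carrier, phenos)
            if mode == "SNP":
                if inh == "SNP_exact":
                    ann_kw["gwas_exact_positions"] = {v.key}
                else:
                    ann_kw["gwas_exact_positions"] = {
                        (v.chrom, v.pos + 1, "A", "G")}
            self._gene_ann(gene, mode, phenos, **ann_kw)
            self.variants.append(v)
            self.truth[(v.sample_id,) + v.key] = (tier, vclass, inh, score)

    def build(self) -> SyntheticCohort:
        for (tier, vclass, inh, score) in sorted(self.spec.cell_counts):
            self.build_cell(tier, vclass, inh, score,
                            self.spec.cell_counts[(tier, vclass, inh, score)])
        cohort = SyntheticCohort(
            participants=self.participants, variants=self.variants,
            annotations=self.annotations, truth=self.truth, decoys=self.decoys)
        return spike_decoys(cohort, self.spec, builder=self)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort deterministically from ``spec`` (see class docs).

    Running the full pipeline on the result reproduces ``spec.cell_counts``
    exactly; spiked decoys are all removed by the filter cascade.
    """
    return _Builder(spec).build()


# ---------------------------------------------------------------------------
# decoys

def spike_decoys(cohort: SyntheticCohort, spec: CohortSpec,
                 builder: _Builder | None = None) -> SyntheticCohort:
    """Add negative controls, each violating exactly one filter rule.

    Decoys are fully annotated, tierable variants that would survive every
    other rule, so each one isolates the rule it names.
    """
    if builder is None:
        builder = _Builder(CohortSpec(n_participants=spec.n_participants,
                                      seed=spec.seed + 7))
        builder.participants = cohort.participants
        builder.annotations = cohort.annotations
        builder.variants = cohort.variants
        builder.truth = cohort.truth
        builder.decoys = cohort.decoys
    b = builder
    cfg = FilterConfig()

    def _decoy_call(rule: str) -> VariantCall:
        carrier = b._pick(b.participants, "_any_ptr", None, ("decoy", rule))
        gene = b._new_gene("DG")
        chrom, pos = b.genome.place()
        v = VariantCall(
            sample_id=carrier.sample_id, chrom=chrom, pos=pos, ref="A", alt="G",
            vclass=SNV, zygosity="heterozygous", map_quality=60.0, depth=60,
            alt_depth=30, consequence="missense", sift="damaging",
            polyphen="damaging", gene=gene,
            pop_af={"1000g": 0.01})
        b._gene_ann(gene, "AD", [f"{b._new_term('Genetrait')} disorder"])
        return v

    quality_kinds = ("quality_mq", "quality_dp", "quality_altdp")
    for i in range(spec.n_quality_fail_decoys):
        kind = quality_kinds[i % 3]
        v = _decoy_call(kind)
        if kind == "quality_mq":
            v.map_quality = cfg.min_map_quality - 1
        elif kind == "quality_dp":
            v.depth = cfg.min_depth - 1
            v.alt_depth = min(v.alt_depth, v.depth)
            if v.alt_depth < cfg.min_alt_depth:   # keep single-rule violation
                v.alt_depth = cfg.min_alt_depth
        else:
            v.alt_depth = cfg.min_alt_depth - 1
        b.variants.append(v)
        b.decoys[v.key] = kind

    for _ in range(spec.n_common_af_decoys):
        v = _decoy_call("population_maf")
        v.pop_af = {"1000g": 0.25}
        b.variants.append(v)
        b.decoys[v.key] = "population_maf"

    n_carriers = math.ceil(cfg.max_cohort_fraction * spec.n_participants)
    for _ in range(spec.n_cohort_recurrent_decoys):
        v0 = _decoy_call("cohort_frequency")
        b.variants.append(v0)
        b.decoys[v0.key] = "cohort_frequency"
        placed = {v0.sample_id}
        while len(placed) < n_carriers:
            carrier = b._pick(b.participants, "_any_ptr", None,
                              ("decoy", "cohort_frequency"))
            if carrier.sample_id in placed:
                continue
            placed.add(carrier.sample_id)
            b.variants.append(VariantCall(
                sample_id=carrier.sample_id, chrom=v0.chrom, pos=v0.pos,
                ref=v0.ref, alt=v0.alt, vclass=v0.vclass,
                zygosity="heterozygous", map_quality=60.0, depth=60,
                alt_depth=30, consequence=v0.consequence, sift=v0.sift,
                polyphen=v0.polyphen, gene=v0.gene, pop_af=dict(v0.pop_af)))

    for _ in range(spec.n_no_phenotype_gene_decoys):
        v = _decoy_call("no_phenotype_gene")
        ann = b.annotations[v.gene]
        ann.phenotypes = []
        ann.has_hgmd_omim_phenotype = False
        b.variants.append(v)
        b.decoys[v.key] = "no_phenotype_gene"

    for _ in range(spec.n_non_disease_trait_decoys):
        v = _decoy_call("non_disease_trait")
        b.annotations[v.gene].is_non_disease_trait_only = True
        b.variants.append(v)
        b.decoys[v.key] = "non_disease_trait"

    return cohort


# ---------------------------------------------------------------------------
# the published-table fixture

# per-person ACMG-panel variant counts: 15 zero-variant participants,
# mean 1.8, median 2, range 0-6, total 161.
_ACMG_DIST = [0] * 15 + [1] * 29 + [2] * 20 + [3] * 14 + [4] * 7 + [5] * 2 + [6] * 2
# cancer-panel counts by cancer status: 51 variants over 39 cancer subjects
# (mean 1.3, range 0-3), 64 over 50 without cancer (range 0-4); total 115.
_CANCER_DIST_CANCER = [0] * 10 + [1] * 12 + [2] * 12 + [3] * 5
_CANCER_DIST_CONTROL = [0] * 10 + [1] * 22 + [2] * 13 + [3] * 4 + [4] * 1

_FIXTURE_SEED = 20150724 % (2 ** 31)


def reference_cohort_fixture(seed: int = _FIXTURE_SEED) -> SyntheticCohort:
    """The deterministic 89-participant cohort reproducing every published
    cross-tabulation cell, panel burden and phenotype-view count.

    Properties (all verified by pushing the cohort through the real
    pipeline): 7046 filter-passing classified variants (644 Tier-1, 6402
    Tier-2); 202 match / 3710 no-match / 3134 cannot-assess; 161 variants in
    the ACMG-56 panel (13 Tier-1) over 74 carriers; 115 in the cancer-57
    panel (3 Tier-1, two of them likely-pathogenic in cancer subjects); 146
    matched diagnoses out of 636 over the 73 participants with any match.

    ``seed`` varies sampled identifiers and positions only, never counts.
    """
    cell_counts = {(t, vc, inh, score): n
                   for (t, vc, inh), (y, no, x) in REFERENCE_CELLS.items()
                   for score, n in zip(("YES", "NO", "X"), (y, no, x))}
    spec = CohortSpec(
        n_participants=89, seed=seed, cell_counts=cell_counts,
        n_quality_fail_decoys=9, n_common_af_decoys=10,
        n_cohort_recurrent_decoys=2, n_no_phenotype_gene_decoys=10,
        n_non_disease_trait_decoys=10,
        fraction_cancer=39 / 89, fraction_male=51 / 89,
        n_match_participants=73, matches_per_participant=2)
    cohort = generate_cohort(spec)
    _plant_panels(cohort)
    _pad_diagnoses(cohort, spec)
    return cohort


def _plant_panels(cohort: SyntheticCohort) -> None:
    """Relabel AD no-match variants into panel genes and redistribute their
    carriers to the published per-person distributions.

    ACMG-planted variants use ACMG-only symbols and cancer-planted variants
    use cancer-only symbols, so the two panel subsets are disjoint.
    """
    by_cell = cohort.by_cell()
    t1_snv = list(by_cell[(1, SNV, "AD", "NO")])
    t1_indel = list(by_cell[(1, INDEL, "AD", "NO")])
    t2_snv = list(by_cell[(2, SNV, "AD", "NO")])

    variants_by_key = {(v.sample_id,) + v.key: v for v in cohort.variants}
    acmg_only = sorted(set(ACMG56_GENES) - set(CANCER57_GENES))
    cancer_only = sorted(set(CANCER57_GENES) - set(ACMG56_GENES))

    # 161 ACMG variants: 8 Tier-1 SNV, 5 Tier-1 INDEL, 148 Tier-2 SNV
    acmg_vars = ([variants_by_key[k] for k in t1_snv[:8]]
                 + [variants_by_key[k] for k in t1_indel[:5]]
                 + [variants_by_key[k] for k in t2_snv[:148]])
    # 115 cancer-panel variants: 2 Tier-1 SNV, 1 Tier-1 INDEL (the
    # likely-pathogenic frameshift), 112 Tier-2 SNV (one likely-pathogenic
    # missense); the two score-4 variants go to distinct cancer subjects.
    cancer_vars = ([variants_by_key[k] for k in t1_snv[8:10]]
                   + [variants_by_key[k] for k in t1_indel[5:6]]
                   + [variants_by_key[k] for k in t2_snv[148:260]])

    def _retruth(v: VariantCall, old_key: tuple, new_sample: str) -> None:
        label = cohort.truth.pop(old_key)
        v.sample_id = new_sample
        cohort.truth[(new_sample,) + v.key] = label

    def _assign(vars_, genes, participants, dist) -> None:
        slots = []
        for p, c in zip(participants, dist):
            slots.extend([p.sample_id] * c)
        assert len(slots) == len(vars_)
        for i, v in enumerate(vars_):
            gene = genes[i % len(genes)]
            if gene not in cohort.annotations:
                cohort.annotations[gene] = GeneAnnotation(
                    gene=gene, phenotypes=[f"Genetrait {gene} neoplasia"],
                    has_hgmd_omim_phenotype=True, inheritance="AD")
            old_key = (v.sample_id,) + v.key
            v.gene = gene
            _retruth(v, old_key, slots[i])

    _assign(acmg_vars, acmg_only, cohort.participants, _ACMG_DIST)

    cancer_p = [p for p in cohort.participants if p.has_invasive_cancer]
    control_p = [p for p in cohort.participants if not p.has_invasive_cancer]
    assert (len(cancer_p), len(control_p)) == (39, 50)
    slots_groups = list(zip(cancer_p, _CANCER_DIST_CANCER)) + \
        list(zip(control_p, _CANCER_DIST_CONTROL))
    dist = [c for _, c in slots_groups]
    _assign(cancer_vars, cancer_only, [p for p, _ in slots_groups], dist)

    # The two likely-pathogenic (score-4) variants: the Tier-1 frameshift
    # (ATR) and one Tier-2 missense (BRIP1).  Assignment slots 2 and 3 land
    # on distinct cancer subjects (the first slots enumerate the cancer
    # group), so both carriers have invasive cancer; everything else 1-3.
    fs = cancer_vars[2]
    ms = cancer_vars[3]
    for v, gene in ((fs, "ATR"), (ms, "BRIP1")):
        v.gene = gene
        cohort.annotations.setdefault(gene, GeneAnnotation(
            gene=gene, phenotypes=[f"Genetrait {gene} neoplasia"],
            has_hgmd_omim_phenotype=True, inheritance="AD"))
    by_id = {p.sample_id: p for p in cohort.participants}
    assert fs.sample_id != ms.sample_id
    assert by_id[fs.sample_id].has_invasive_cancer
    assert by_id[ms.sample_id].has_invasive_cancer
    for i, v in enumerate(cancer_vars):
        cohort.pathogenicity[v.key] = 4 if v in (fs, ms) else (i % 3) + 1

    cohort.panels = {"acmg56": acmg56_panel(), "cancer57": cancer57_panel()}


def _pad_diagnoses(cohort: SyntheticCohort, spec: CohortSpec) -> None:
    """Bring chart-review diagnosis lists to the published shape: 636
    diagnoses over the 73 participants with a planted match (the rest of
    each list is non-matching filler), four filler diagnoses for each of
    the 16 participants with none."""
    pool = cohort.participants[:spec.n_match_participants]
    rest = cohort.participants[spec.n_match_participants:]
    filler = 0

    def _pad(p: Participant, quota: int) -> None:
        nonlocal filler
        while len(p.diagnoses) < quota:
            filler += 1
            p.diagnoses.append(f"Ailment{filler:04d}")

    for i, p in enumerate(pool):
        _pad(p, 9 if i < 52 else 8)
    for p in rest:
        _pad(p, 4)


# ---------------------------------------------------------------------------
# disk round trip

def write_cohort(cohort: SyntheticCohort, out_dir: str | os.PathLike) -> None:
    """Write a cohort in the pipeline's input formats (VCF + TSVs)."""
    os.makedirs(out_dir, exist_ok=True)
    eio.write_cohort_vcf(cohort.variants, cohort.participants,
                         os.path.join(out_dir, "cohort.vcf"))
    eio.write_variant_annotations(cohort.variants,
                                  os.path.join(out_dir, "variant_annotations.tsv"))
    eio.write_gene_annotation(cohort.annotations,
                              os.path.join(out_dir, "gene_annotations.tsv"))
    eio.write_participants(cohort.participants,
                           os.path.join(out_dir, "participants.tsv"))
    for name, panel in cohort.panels.items():
        eio.write_panel(panel, os.path.join(out_dir, f"{name}.txt"))
    if cohort.pathogenicity:
        eio.write_pathogenicity(cohort.pathogenicity,
                                os.path.join(out_dir, "pathogenicity.tsv"))


def read_cohort_inputs(in_dir: str | os.PathLike) -> SyntheticCohort:
    """Read back a cohort directory written by :func:`write_cohort`.

    Truth labels are not persisted; the returned cohort carries the inputs
    the pipeline needs (annotated calls, gene annotations, participants,
    panels, pathogenicity).
    """
    participants = eio.read_participants(os.path.join(in_dir, "participants.tsv"))
    calls = eio.read_cohort_vcf(os.path.join(in_dir, "cohort.vcf"))
    vann = eio.read_variant_annotations(
        os.path.join(in_dir, "variant_annotations.tsv"))
    eio.attach_annotations(calls, vann)
    anns = eio.read_gene_annotation(os.path.join(in_dir, "gene_annotations.tsv"))
    panels = {}
    for name in ("acmg56", "cancer57"):
        path = os.path.join(in_dir, f"{name}.txt")
        if os.path.exists(path):
            panels[name] = eio.read_panel(path, name)
    pathog = {}
    ppath = os.path.join(in_dir, "pathogenicity.tsv")
    if os.path.exists(ppath):
        pathog = eio.read_pathogenicity(ppath)
    return SyntheticCohort(participants=participants, variants=calls,
                           annotations=anns, panels=panels,
                           pathogenicity=pathog)
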