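"""Core domain types for the exome genotype–phenotype correlation pipeline.

The pipeline operates on per-sample variant calls annotated with gene-level
disease knowledge (an HGMD/OMIM-style table), participant chart-review
diagnoses, and gene panels.  These dataclasses are the in-memory contract
shared by every stage: filtering, tier classification, inheritance-aware
Yes/No/X scoring, and panel burden statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = [
    "VariantCall",
    "GeneAnnotation",
    "Participant",
    "PanelDefinition",
    "FilterConfig",
    "TieredVariant",
    "ScoredVariant",
    "SNV",
    "INDEL",
    "VCLASSES",
    "ZYGOSITIES",
    "CONSEQUENCES",
    "INHERITANCE_MODES",
    "INHERITANCE_CLASSES",
    "SCORES",
    "REASONS",
    "FILTER_RULES",
    "variant_key",
]

SNV = "SNV"
INDEL = "INDEL"
VCLASSES = frozenset({SNV, INDEL})

ZYGOSITIES = frozenset({"heterozygous", "homozygous_alt", "hemizygous"})

CONSEQUENCES = frozenset({
    "stop_gained", "stop_lost", "start_lost", "splice_site", "missense",
    "frameshift", "inframe_codon_change", "codon_insertion_deletion",
    "synonymous", "other",
})

# Annotation-table inheritance modes: the seven curated groups.  SNP marks a
# gene whose only disease link is a GWAS association.
INHERITANCE_MODES = frozenset({"AD", "AD_AR", "AR", "XLR", "XLD", "YL", "SNP", "DIGENIC"})

# Scoring-time inheritance classes: SNP splits by whether the observed variant
# is the exact GWAS-associated allele; YL / protective / unobservable
# non-Mendelian genes collapse into OTHERS.
INHERITANCE_CLASSES = ("AD", "AD_AR", "AR", "XLR", "XLD", "DIGENIC",
                       "SNP_novel", "SNP_exact", "OTHERS")

SCORES = ("YES", "NO", "X")

REASONS = frozenset({
    "phenotype_overlap", "no_overlap", "monoallelic_recessive",
    "sex_incompatible", "unobservable_phenotype", "protective_variant",
    "others_category",
})

FILTER_RULES = ("quality_mq", "quality_dp", "quality_altdp", "population_maf",
                "cohort_frequency", "no_phenotype_gene", "non_disease_trait")

_SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


def _is_sex_chrom(chrom: str) -> bool:
    return chrom in _SEX_CHROMS


@dataclass
class VariantCall:
    """One called variant in one sample, with quality and annotations.

    Annotation fields (``consequence``, ``sift``, ``polyphen``, ``gene``,
    ``pop_af``) may be unset on calls read straight from a VCF; they are
    joined from the sidecar variant-annotation table before filtering.
    ``pop_af`` maps reference-panel name to the reported allele frequency.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    zygosity: str
    map_quality: float | None = None
    depth: int | None = None
    alt_depth: int | None = None
    consequence: str = "other"
    sift: str = "missing"
    polyphen: str = "missing"
    gene: str = ""
    pop_af: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.vclass not in VCLASSES:
            raise ValueError(f"unknown vclass {self.vclass!r}")
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        if is_snv != (self.vclass == SNV):
            raise ValueError(
                f"vclass {self.vclass} inconsistent with alleles {self.ref}>{self.alt}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.zygosity == "hemizygous" and not _is_sex_chrom(self.chrom):
            raise ValueError(f"hemizygous call on autosome {self.chrom}")
        if self.depth is not None and self.alt_depth is not None:
            if self.alt_depth > self.depth:
                raise ValueError("alt_depth exceeds depth")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele identity shared across samples: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


def variant_key(v: VariantCall) -> tuple[str, int, str, str]:
    return v.key


@dataclass
class GeneAnnotation:
    """Gene-level disease knowledge in the style of an HGMD/OMIM digest.

    ``phenotypes`` keeps the curated free-text phenotype descriptions in file
    order (pipe-delimited on disk).  ``gwas_exact_positions`` lists the exact
    GWAS-associated alleles for SNP-mode genes.
    """

    gene: str
    phenotypes: list[str] = field(default_factory=list)
    has_hgmd_omim_phenotype: bool = False
    is_non_disease_trait_only: bool = False
    inheritance: str = "AD"
    protective_only: bool = False
    sex_limited: str = "none"
    observable_in_emr: bool = True
    gwas_exact_positions: set[tuple[str, int, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(
                f"unknown inheritance {self.inheritance!r}; allowed: "
                + ", ".join(sorted(INHERITANCE_MODES)))
        if self.sex_limited not in ("none", "male_only", "female_only"):
            raise ValueError(f"unknown sex_limited {self.sex_limited!r}")
        if not self.has_hgmd_omim_phenotype and self.phenotypes:
            raise ValueError(
                f"gene {self.gene}: phenotypes listed but has_hgmd_omim_phenotype is false")
        if self.gwas_exact_positions and self.inheritance != "SNP":
            raise ValueError(
                f"gene {self.gene}: gwas_exact_positions only valid for SNP genes")


@dataclass
class Participant:
    """One cohort member: sex, chart-review diagnoses, cancer status."""

    sample_id: str
    sex: str
    diagnoses: list[str] = field(default_factory=list)
    has_invasive_cancer: bool = False
    group: int = 1

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.group not in (1, 2):
            raise ValueError(f"group must be 1 or 2, got {self.group!r}")


@dataclass
class PanelDefinition:
    """A named gene panel (e.g. the ACMG secondary-findings list)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} has no genes")


@dataclass
class FilterConfig:
    """Thresholds of the custom filtering cascade.

    Quality minima are inclusive (a mapping quality of exactly
    ``min_map_quality`` passes); the frequency maxima are exclusive (a folded
    minor-allele frequency equal to ``max_maf`` is excluded, matching
    "MAF >= 10% were excluded").  ``reference_panels`` limits which population
    panels are consulted; ``None`` means every panel present on the call.
    """

    min_map_quality: float = 20.0
    min_depth: int = 20
    min_alt_depth: int = 5
    max_maf: float = 0.10
    max_cohort_fraction: float = 0.10
    reference_panels: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("min_map_quality", "min_depth", "min_alt_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("max_maf", "max_cohort_fraction"):
            val = getattr(self, name)
            if not (0 < val <= 1):
                raise ValueError(f"{name} must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        return cls(**d)


@dataclass
class TieredVariant:
    """A filter-passing variant assigned to Tier-1 or Tier-2.

    ``tier_basis`` records the consequence that triggered the assignment.
    """

    variant: VariantCall
    tier: int
    tier_basis: str

    def __post_init__(self) -> None:
        if self.tier not in (1, 2):
            raise ValueError(f"tier must be 1 or 2, got {self.tier}")


@dataclass
class ScoredVariant:
    """A tiered variant with inheritance class and Yes/No/X verdict."""

    tiered: TieredVariant
    inh_class: str
    score: str
    reason: str

    def __post_init__(self) -> None:
        if self.inh_class not in INHERITANCE_CLASSES:
            raise ValueError(f"unknown inheritance class {self.inh_class!r}")
        if self.score not in SCORES:
            raise ValueError(f"unknown score {self.score!r}")
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if (self.score == "YES") != (self.reason == "phenotype_overlap"):
            raise ValueError("YES iff reason is phenotype_overlap")

    @property
    def variant(self) -> VariantCall:
        return self.tiered.variant
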