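"""Filter-cascade rules, boundaries, monotonicity and decoy elimination."""
import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from exophen import (
    CohortSpec,
    FilterConfig,
    GeneAnnotation,
    VariantCall,
    apply_filters,
    generate_cohort,
)
from exophen.filters import (
    cohort_frequency_filter,
    passes_gene_phenotype,
    passes_population_maf,
    passes_quality,
)


def _snv(**kw):
    base = dict(sample_id="S1", chrom="1", pos=100, ref="A", alt="G",
                vclass="SNV", zygosity="heterozygous", map_quality=60.0,
                depth=50, alt_depth=25, gene="G1")
    base.update(kw)
    return VariantCall(**base)


CFG = FilterConfig()


@pytest.mark.parametrize("mq,dp,alt_dp,expected", [
    (20, 20, 5, True),     # all minima inclusive
    (19, 200, 80, False),  # mapping quality below threshold
    (60, 20, 4, False),    # alternate depth below threshold
    (60, 19, 10, False),   # total depth below threshold
    (None, 50, 25, False),  # missing field fails closed
])
def test_quality_thresholds_are_inclusive_minima(mq, dp, alt_dp, expected):
    v = _snv(map_quality=mq, depth=dp, alt_depth=alt_dp)
    assert passes_quality(v, CFG) is expected


def test_indel_quality_uses_only_alt_depth():
    """INDEL calls are filtered on supporting reads alone, so low MQ/DP do
    not remove them."""
    indel = _snv(ref="AT", alt="A", vclass="INDEL", map_quality=5.0, depth=10,
                 alt_depth=5)
    assert passes_quality(indel, CFG)
    assert not passes_quality(dataclasses.replace(indel, alt_depth=4), CFG)


@pytest.mark.parametrize("pop_af,expected", [
    ({"1000g": 0.10}, False),   # at the 10% boundary: excluded
    ({"1000g": 0.0999}, True),
    ({}, True),                 # no frequency evidence passes
    ({"1000g": 0.95}, True),    # folded minor allele frequency 0.05
    ({"1000g": 0.90}, False),   # folded 0.10: excluded
    ({"1000g": 0.01, "esp": 0.5}, False),  # any panel suffices
])
def test_population_maf_is_folded_and_any_panel(pop_af, expected):
    assert passes_population_maf(_snv(pop_af=pop_af), CFG) is expected


def test_population_maf_rejects_invalid_frequency():
    with pytest.raises(ValueError, match="outside"):
        passes_population_maf(_snv(pop_af={"1000g": 1.5}), CFG)


def test_gene_phenotype_rule():
    ann = {
        "DIS": GeneAnnotation(gene="DIS", phenotypes=["Eczema"],
                              has_hgmd_omim_phenotype=True),
        "TRAIT": GeneAnnotation(gene="TRAIT", phenotypes=["Hair color"],
                                has_hgmd_omim_phenotype=True,
                                is_non_disease_trait_only=True),
    }
    assert passes_gene_phenotype(_snv(gene="DIS"), ann) == (True, None)
    assert passes_gene_phenotype(_snv(gene="ABSENT"), ann) == \
        (False, "no_phenotype_gene")
    assert passes_gene_phenotype(_snv(gene="TRAIT"), ann) == \
        (False, "non_disease_trait")


def test_cohort_frequency_boundary_on_89_samples():
    """9/89 carriers (10.1%) is removed; 8/89 (9.0%) is retained."""
    def key_in(n, pos):
        return [_snv(sample_id=f"S{i}", pos=pos) for i in range(n)]

    variants = key_in(9, 100) + key_in(8, 200)
    retained, removed = cohort_frequency_filter(variants, 89, CFG)
    assert {v.pos for v in removed} == {100} and len(removed) == 9
    assert {v.pos for v in retained} == {200} and len(retained) == 8

    assert cohort_frequency_filter([], 89, CFG) == ([], [])


def test_cohort_counts_distinct_carriers_not_alleles():
    # same sample carrying a key twice counts once
    variants = [_snv(sample_id="S1", pos=100)] * 12
    retained, removed = cohort_frequency_filter(variants, 89, CFG)
    assert removed == [] and len(retained) == 12


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 19)),
                min_size=1, max_size=60))
def test_cohort_filter_agrees_with_brute_force(pairs):
    """Carrier counting matches an independent per-key scan over samples."""
    variants = [_snv(sample_id=f"S{s}", pos=100 + k) for s, k in pairs]
    n_samples = 10
    retained, removed = cohort_frequency_filter(variants, n_samples, CFG)
    for v in variants:
        carriers = {w.sample_id for w in variants if w.key == v.key}
        should_remove = len(carriers) / n_samples >= CFG.max_cohort_fraction
        assert (v in removed) is should_remove
        assert (v in retained) is (not should_remove)


def _ann_for(variants):
    return {v.gene: GeneAnnotation(gene=v.gene, phenotypes=["Genetrait disorder"],
                                   has_hgmd_omim_phenotype=True)
            for v in variants}


def test_apply_filters_partition_and_all_pass():
    variants = [_snv(sample_id=f"S{i}", pos=100 + i) for i in range(20)]
    retained, outcomes = apply_filters(variants, _ann_for(variants), CFG, 89)
    assert len(retained) == 20
    assert all(o.passed and not o.failed_rules for o in outcomes)
    assert len(outcomes) == len(variants)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(mq=st.floats(0, 80), dp=st.integers(0, 60), alt=st.integers(0, 30),
       maf=st.floats(0.01, 1.0), cf=st.floats(0.01, 1.0))
def test_filter_monotonicity_in_thresholds(mq, dp, alt, maf, cf):
    """Tightening any threshold never grows the retained set."""
    variants = [_snv(sample_id=f"S{i % 7}", pos=100 + i % 13,
                     map_quality=20.0 + (i % 5) * 10, depth=20 + i % 30,
                     alt_depth=min(5 + i % 10, 20 + i % 30),
                     pop_af={"1000g": (i % 10) / 40})
                for i in range(40)]
    ann = _ann_for(variants)
    base, _ = apply_filters(variants, ann, CFG, 20)
    tight = FilterConfig(min_map_quality=max(CFG.min_map_quality, mq),
                         min_depth=max(CFG.min_depth, dp),
                         min_alt_depth=max(CFG.min_alt_depth, alt),
                         max_maf=min(CFG.max_maf, maf),
                         max_cohort_fraction=min(CFG.max_cohort_fraction, cf))
    tightened, _ = apply_filters(variants, ann, tight, 20)
    ids = lambda vs: {id(v) for v in vs}
    assert ids(tightened) <= ids(base)


def test_decoys_removed_and_readmitted_by_relaxing_rule(tmp_path):
    """Every decoy fails exactly its named rule, and removing that rule's
    threshold re-admits it."""
    spec = CohortSpec(n_participants=20, seed=11, cell_counts={
        (2, "SNV", "AD", "NO"): 15},
        n_quality_fail_decoys=6, n_common_af_decoys=3,
        n_cohort_recurrent_decoys=1, n_no_phenotype_gene_decoys=2,
        n_non_disease_trait_decoys=2)
    cohort = generate_cohort(spec)
    retained, outcomes = apply_filters(cohort.variants, cohort.annotations,
                                       CFG, 20)
    assert len(retained) == 15  # decoys eliminated
    by_key = {}
    for o in outcomes:
        by_key.setdefault(o.key, []).extend(o.failed_rules)
    for key, rule in cohort.decoys.items():
        assert set(by_key[key]) == {rule}, (key, rule, by_key[key])

    # relaxing the violated thresholds re-admits the rule's decoys
    relaxed = FilterConfig(min_map_quality=0, min_depth=0, min_alt_depth=0)
    retained2, _ = apply_filters(cohort.variants, cohort.annotations,
                                 relaxed, 20)
    quality_keys = {k for k, r in cohort.decoys.items()
                    if r.startswith("quality")}
    assert quality_keys <= {v.key for v in retained2}


def test_filter_outcomes_conserve_variants(pipeline_result, fixture_cohort):
    outcomes = pipeline_result["outcomes"]
    assert len(outcomes) == len(fixture_cohort.variants)
    n_removed = sum(1 for o in outcomes if not o.passed)
    retained = len(fixture_cohort.variants) - n_removed
    assert retained == len(fixture_cohort.truth)
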