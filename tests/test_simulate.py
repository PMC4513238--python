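"""Generator contracts: determinism, label recovery, decoy semantics."""
import json

import pytest
from hypothesis import given, settings, strategies as st

from exophen import (
    CohortSpec,
    FilterConfig,
    apply_filters,
    build_crosstab,
    classify_all,
    generate_cohort,
    score_cohort,
    reference_cohort_fixture,
)


def _cohort_signature(cohort):
    """Serializable digest of everything the generator controls."""
    return json.dumps({
        "participants": [(p.sample_id, p.sex, p.diagnoses,
                          p.has_invasive_cancer, p.group)
                         for p in cohort.participants],
        "variants": [(v.sample_id, v.chrom, v.pos, v.ref, v.alt, v.vclass,
                      v.zygosity, v.map_quality, v.depth, v.alt_depth,
                      v.consequence, v.sift, v.polyphen, v.gene,
                      sorted(v.pop_af.items()))
                     for v in cohort.variants],
        "truth": sorted((list(k), list(t)) for k, t in cohort.truth.items()),
        "decoys": sorted((list(k), r) for k, r in cohort.decoys.items()),
    }, sort_keys=True)


def _recovered_cells(cohort, n_samples):
    retained, _ = apply_filters(cohort.variants, cohort.annotations,
                                FilterConfig(), n_samples)
    scored = score_cohort(classify_all(retained), cohort.annotations,
                          cohort.participants)
    ct = build_crosstab(scored)
    out = {}
    for (tier, vclass, inh), c in ct.cells.items():
        for score, n in (("YES", c.n_yes), ("NO", c.n_no), ("X", c.n_x)):
            if n:
                out[(tier, vclass, inh, score)] = n
    return out


def test_all_zero_spec_gives_empty_variants():
    cohort = generate_cohort(CohortSpec(n_participants=5, seed=1))
    assert cohort.variants == [] and cohort.truth == {}
    assert len(cohort.participants) == 5


def test_same_seed_is_byte_identical():
    spec = dict(n_participants=20, seed=42, cell_counts={
        (1, "SNV", "AD", "YES"): 3, (2, "SNV", "AR", "X"): 5},
        n_quality_fail_decoys=3)
    a = generate_cohort(CohortSpec(**spec))
    b = generate_cohort(CohortSpec(**spec))
    assert _cohort_signature(a) == _cohort_signature(b)


def test_different_seed_changes_positions_not_counts():
    spec = dict(n_participants=20, cell_counts={
        (1, "SNV", "AD", "YES"): 3, (2, "SNV", "SNP_novel", "NO"): 7})
    a = generate_cohort(CohortSpec(seed=1, **spec))
    b = generate_cohort(CohortSpec(seed=2, **spec))
    assert _cohort_signature(a) != _cohort_signature(b)
    assert _recovered_cells(a, 20) == _recovered_cells(b, 20)


def test_requested_cell_is_recovered_exactly():
    """A spec asking for 3 Tier-1 AD SNV YES variants yields a cohort on
    which the pipeline scores exactly 3 such variants."""
    spec = CohortSpec(n_participants=15, seed=9, cell_counts={
        (1, "SNV", "AD", "YES"): 3})
    cells = _recovered_cells(generate_cohort(spec), 15)
    assert cells == {(1, "SNV", "AD", "YES"): 3}


_CELL_KEYS = st.sampled_from([
    (1, "SNV", "AD", "YES"), (1, "SNV", "AD", "NO"), (1, "SNV", "AD", "X"),
    (1, "SNV", "AR", "YES"), (1, "SNV", "AR", "X"),
    (1, "SNV", "XLR", "YES"), (1, "SNV", "XLR", "NO"), (1, "SNV", "XLR", "X"),
    (2, "SNV", "AD_AR", "NO"), (2, "SNV", "XLD", "NO"), (2, "SNV", "XLD", "X"),
    (1, "INDEL", "DIGENIC", "NO"), (2, "INDEL", "AR", "X"),
    (2, "SNV", "SNP_novel", "YES"), (2, "SNV", "SNP_novel", "NO"),
    (2, "SNV", "SNP_exact", "NO"), (2, "SNV", "SNP_exact", "X"),
    (1, "SNV", "OTHERS", "X"), (2, "INDEL", "OTHERS", "X"),
])


@settings(deadline=None, derandomize=True, max_examples=25)
@given(cells=st.dictionaries(_CELL_KEYS, st.integers(0, 6), max_size=8),
       seed=st.integers(0, 1000))
def test_label_recovery_for_feasible_specs(cells, seed):
    """Generator and pipeline are mutual oracles: the pipeline reproduces
    any feasible requested cell structure exactly."""
    spec = CohortSpec(n_participants=16, seed=seed, cell_counts=cells)
    cohort = generate_cohort(spec)
    expected = {k: n for k, n in cells.items() if n}
    assert _recovered_cells(cohort, 16) == expected


def test_infeasible_cell_is_named():
    with pytest.raises(ValueError, match="XLR"):
        generate_cohort(CohortSpec(
            n_participants=4, seed=0, fraction_male=0.0,
            cell_counts={(1, "SNV", "XLR", "NO"): 1}))
    with pytest.raises(ValueError, match="OTHERS"):
        CohortSpec(n_participants=5,
                   cell_counts={(1, "SNV", "OTHERS", "YES"): 1})
    with pytest.raises(ValueError, match="never NO"):
        CohortSpec(n_participants=5,
                   cell_counts={(1, "SNV", "AR", "NO"): 1})


def test_decoys_do_not_change_filtered_count():
    base = dict(n_participants=20, seed=4,
                cell_counts={(2, "SNV", "AD", "NO"): 12})
    plain = generate_cohort(CohortSpec(**base))
    spiked = generate_cohort(CohortSpec(
        **base, n_quality_fail_decoys=6, n_common_af_decoys=4,
        n_cohort_recurrent_decoys=1, n_no_phenotype_gene_decoys=3,
        n_non_disease_trait_decoys=3))
    assert len(spiked.variants) > len(plain.variants)
    for cohort in (plain, spiked):
        retained, _ = apply_filters(cohort.variants, cohort.annotations,
                                    FilterConfig(), 20)
        assert len(retained) == 12


def test_cohort_recurrent_decoy_occupies_threshold_fraction():
    spec = CohortSpec(n_participants=30, seed=2,
                      n_cohort_recurrent_decoys=1)
    cohort = generate_cohort(spec)
    (key, rule), = cohort.decoys.items()
    assert rule == "cohort_frequency"
    carriers = {v.sample_id for v in cohort.variants if v.key == key}
    assert len(carriers) == 3  # ceil(0.1 * 30)
    retained, _ = apply_filters(cohort.variants, cohort.annotations,
                                FilterConfig(), 30)
    assert retained == []


class TestReferenceCohortFixture:
    def test_cohort_shape(self, fixture_cohort):
        assert len(fixture_cohort.participants) == 89
        sexes = [p.sex for p in fixture_cohort.participants]
        assert (sexes.count("M"), sexes.count("F")) == (51, 38)
        cancer = sum(p.has_invasive_cancer for p in fixture_cohort.participants)
        assert cancer == 39

    def test_truth_covers_exactly_non_decoys(self, fixture_cohort):
        assert len(fixture_cohort.truth) == 7046
        decoy_keys = set(fixture_cohort.decoys)
        for (sample, chrom, pos, ref, alt) in fixture_cohort.truth:
            assert (chrom, pos, ref, alt) not in decoy_keys

    def test_every_gene_is_annotated(self, fixture_cohort):
        for v in fixture_cohort.variants:
            assert v.gene in fixture_cohort.annotations

    def test_fixture_is_deterministic(self):
        assert _cohort_signature(reference_cohort_fixture()) == \
            _cohort_signature(reference_cohort_fixture())

    def test_fixture_truth_matches_pipeline_output(self, fixture_cohort,
                                                   pipeline_result):
        """Every retained variant lands in exactly the cell its truth label
        promises."""
        scored = pipeline_result["scored"]
        assert len(scored) == len(fixture_cohort.truth)
        for s in scored:
            v = s.variant
            label = fixture_cohort.truth[(v.sample_id,) + v.key]
            assert label == (s.tiered.tier, v.vclass, s.inh_class, s.score)
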