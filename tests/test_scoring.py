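"""Inheritance assignment, phenotype overlap, and Yes/No/X scoring rules."""
import pytest
from hypothesis import given, settings, strategies as st

from exophen import (
    GeneAnnotation,
    Participant,
    TieredVariant,
    VariantCall,
    assign_inheritance,
    default_lexicon,
    phenotype_centric_view,
    phenotype_overlap,
    score_cohort,
    score_variant,
)
from exophen.scoring import normalize


def _tiered(chrom="1", pos=100, zygosity="heterozygous", gene="G1",
            sample="S1", consequence="stop_gained", vclass="SNV"):
    ref, alt = ("A", "G") if vclass == "SNV" else ("AT", "A")
    v = VariantCall(sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    vclass=vclass, zygosity=zygosity, map_quality=60,
                    depth=50, alt_depth=25, consequence=consequence, gene=gene)
    return TieredVariant(variant=v, tier=1, tier_basis=consequence)


def _ann(**kw):
    base = dict(gene="G1", phenotypes=["Genetrait disorder"],
                has_hgmd_omim_phenotype=True, inheritance="AD")
    base.update(kw)
    return GeneAnnotation(**base)


LEX = default_lexicon()


class TestPhenotypeOverlap:
    def test_exact_keyword_match(self):
        assert phenotype_overlap(["Eczema", "Ichthyosis vulgaris"], ["Eczema"])

    def test_lexicon_synonym_bridges_deafness_to_hearing_loss(self):
        assert phenotype_overlap(["Deafness"], ["Hearing loss"], LEX)
        assert not phenotype_overlap(["Deafness"], ["Hearing loss"])

    def test_lexicon_bridges_cardiomyopathy_to_tachycardia(self):
        assert phenotype_overlap(
            ["Arrhythmogenic right ventricular cardiomyopathy"],
            ["Ventricular tachycardia"], LEX)

    def test_empty_diagnoses_never_match(self):
        assert not phenotype_overlap(["Eczema"], [])
        assert not phenotype_overlap([], ["Eczema"])

    def test_stopwords_do_not_create_overlap(self):
        assert not phenotype_overlap(["Atherosclerosis, increased risk, association with"],
                                     ["Glaucoma, increased risk"])

    def test_normalization_strips_punctuation_and_case(self):
        assert normalize("Non-syndromic Hearing Loss,") == "non syndromic hearing loss"

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(a=st.sampled_from(["Deafness", "Hearing loss", "Eczema",
                              "Glaucoma suspect", "Nephropathy",
                              "Chronic renal failure", "Osteoarthritis"]),
           b=st.sampled_from(["Deafness", "Hearing loss", "Eczema",
                              "Glaucoma", "Nephropathy",
                              "Degenerative joint disease", "Aneurysm"]))
    def test_single_phrase_overlap_is_symmetric(self, a, b):
        assert phenotype_overlap([a], [b], LEX) == phenotype_overlap([b], [a], LEX)


class TestAssignInheritance:
    def test_mendelian_modes_pass_through(self):
        for mode in ("AD", "AD_AR", "AR", "XLR", "XLD", "DIGENIC"):
            assert assign_inheritance(_tiered(), _ann(inheritance=mode)) == mode

    def test_snp_splits_on_exact_gwas_position(self):
        t = _tiered(chrom="1", pos=100)
        exact = _ann(inheritance="SNP",
                     gwas_exact_positions={("1", 100, "A", "G")})
        novel = _ann(inheritance="SNP",
                     gwas_exact_positions={("1", 999, "A", "G")})
        assert assign_inheritance(t, exact) == "SNP_exact"
        assert assign_inheritance(t, novel) == "SNP_novel"

    def test_yl_and_protective_fold_into_others(self):
        assert assign_inheritance(_tiered(chrom="Y", zygosity="hemizygous"),
                                  _ann(inheritance="YL")) == "OTHERS"
        assert assign_inheritance(_tiered(), _ann(protective_only=True)) == "OTHERS"


class TestScoreVariant:
    M = Participant(sample_id="S1", sex="M", diagnoses=["Eczema"])
    F = Participant(sample_id="S1", sex="F", diagnoses=[])

    def test_overlap_scores_yes(self):
        s = score_variant(_tiered(), "AD", _ann(phenotypes=["Eczema"]), self.M)
        assert (s.score, s.reason) == ("YES", "phenotype_overlap")

    def test_no_overlap_in_dominant_gene_scores_no(self):
        s = score_variant(_tiered(), "AD", _ann(), self.M)
        assert (s.score, s.reason) == ("NO", "no_overlap")

    def test_monoallelic_recessive_scores_x(self):
        s = score_variant(_tiered(), "AR", _ann(inheritance="AR"), self.M)
        assert (s.score, s.reason) == ("X", "monoallelic_recessive")

    def test_matching_recessive_carrier_scores_yes_not_x(self):
        """Overlap precedes the carrier rule: a matching AR heterozygote is a
        YES, which is why recessive rows carry matches but no NO entries."""
        ann = _ann(inheritance="AR", phenotypes=["Eczema"])
        s = score_variant(_tiered(), "AR", ann, self.M)
        assert s.score == "YES"

    def test_biallelic_recessive_genotype_is_assessable(self):
        s = score_variant(_tiered(), "AR", _ann(inheritance="AR"), self.M,
                          biallelic=True)
        assert (s.score, s.reason) == ("NO", "no_overlap")
        hom = _tiered(zygosity="homozygous_alt")
        s2 = score_variant(hom, "AR", _ann(inheritance="AR"), self.M)
        assert (s2.score, s2.reason) == ("NO", "no_overlap")

    def test_female_xlr_heterozygote_is_carrier_x(self):
        t = _tiered(chrom="X")
        s = score_variant(t, "XLR", _ann(inheritance="XLR"), self.F)
        assert (s.score, s.reason) == ("X", "monoallelic_recessive")

    def test_male_xlr_hemizygote_is_assessable(self):
        t = _tiered(chrom="X", zygosity="hemizygous")
        s = score_variant(t, "XLR", _ann(inheritance="XLR"), self.M)
        assert (s.score, s.reason) == ("NO", "no_overlap")

    def test_sex_limited_gene_in_wrong_sex_scores_x(self):
        """A prostate-cancer-gene variant in a woman cannot be assessed."""
        ann = _ann(sex_limited="male_only")
        s = score_variant(_tiered(), "AD", ann, self.F)
        assert (s.score, s.reason) == ("X", "sex_incompatible")

    def test_unobservable_phenotype_scores_x(self):
        s = score_variant(_tiered(), "AD", _ann(observable_in_emr=False), self.M)
        assert (s.score, s.reason) == ("X", "unobservable_phenotype")

    def test_others_category_scores_x(self):
        s = score_variant(_tiered(chrom="Y", zygosity="hemizygous"), "OTHERS",
                          _ann(inheritance="YL"), self.M)
        assert (s.score, s.reason) == ("X", "others_category")

    def test_lexicon_match_via_dominant_gene(self):
        ann = _ann(phenotypes=["Arrhythmogenic right ventricular cardiomyopathy"])
        p = Participant(sample_id="S1", sex="F",
                        diagnoses=["Ventricular tachycardia"])
        s = score_variant(_tiered(), "AD", ann, p, lex=LEX)
        assert s.score == "YES"


class TestScoreCohort:
    def _setup(self):
        anns = {"G1": _ann(inheritance="AR")}
        t1 = _tiered(pos=100)
        t2 = _tiered(pos=200, consequence="splice_site")
        p = [Participant(sample_id="S1", sex="M", diagnoses=[])]
        return anns, t1, t2, p

    def test_two_heterozygotes_in_same_ar_gene_become_assessable(self):
        anns, t1, t2, p = self._setup()
        scored = score_cohort([t1, t2], anns, p)
        assert [s.score for s in scored] == ["NO", "NO"]
        scored_single = score_cohort([t1], anns, p)
        assert scored_single[0].score == "X"

    def test_unknown_sample_raises(self):
        anns, t1, _, _ = self._setup()
        with pytest.raises(KeyError, match="participant"):
            score_cohort([t1], anns, [Participant(sample_id="S9", sex="M")])

    def test_cohort_with_no_diagnoses_has_zero_yes(self):
        anns = {"G1": _ann()}
        tiered = [_tiered(pos=100 + i, sample="S1") for i in range(5)]
        p = [Participant(sample_id="S1", sex="M", diagnoses=[])]
        assert all(s.score != "YES" for s in score_cohort(tiered, anns, p))


def test_ar_heterozygotes_never_score_no_on_fixture(pipeline_result):
    for s in pipeline_result["scored"]:
        if s.inh_class == "AR" and s.variant.zygosity == "heterozygous":
            assert s.score in ("YES", "X")


def test_scoring_is_permutation_invariant(fixture_cohort):
    from exophen import FilterConfig, apply_filters, classify_all
    retained, _ = apply_filters(fixture_cohort.variants,
                                fixture_cohort.annotations, FilterConfig(), 89)
    tiered = classify_all(retained)
    fwd = score_cohort(tiered, fixture_cohort.annotations,
                       fixture_cohort.participants)
    rev = score_cohort(tiered[::-1], fixture_cohort.annotations,
                       fixture_cohort.participants)
    assert fwd == rev[::-1]


def test_phenotype_view_counts_each_diagnosis_once():
    """Two YES variants hitting the same diagnosis yield one match."""
    anns = {"G1": _ann(phenotypes=["Eczema"]),
            "G2": _ann(gene="G2", phenotypes=["Eczema variant"])}
    p = Participant(sample_id="S1", sex="M", diagnoses=["Eczema", "Gout"])
    t1 = _tiered(pos=100, gene="G1")
    t2 = _tiered(pos=200, gene="G2")
    scored = score_cohort([t1, t2], anns, [p])
    assert [s.score for s in scored] == ["YES", "YES"]
    view = phenotype_centric_view(scored, [p], anns)
    assert view.n_matched == 1
    assert view.per_participant[0]["matched"] == ["Eczema"]
    assert view.n_phenotypes == 2


def test_phenotype_view_participant_without_yes_has_no_matches():
    anns = {"G1": _ann()}
    p = Participant(sample_id="S1", sex="M", diagnoses=["Gout"])
    scored = score_cohort([_tiered()], anns, [p])
    view = phenotype_centric_view(scored, [p], anns)
    assert view.n_matched == 0
    assert view.n_participants_no_match == 1
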