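"""Site/genotype QC, frequency, recurrence and inheritance filters."""
from __future__ import annotations

import itertools
import random

import pytest

from castriage.filtering import (
    FilterConfig,
    apply_filters,
    build_cohort_index,
    filter_cohort_recurrence,
    filter_frequency,
    filter_genotype_qc,
    filter_site_qc,
    filter_sv,
    infer_inheritance,
    pair_compound_hets,
)
from castriage.types import GenotypeCall, Individual, Pedigree, SiteQCMetrics, StructuralVariantCall

from conftest import gt, make_trio_ped, make_variant

CFG = FilterConfig()


class TestSiteQC:
    def test_low_quality_by_depth_drops_snv(self):
        v = make_variant(site_qc=SiteQCMetrics(qd=1.5))
        d = filter_site_qc(v, CFG)
        assert not d.keep and d.reason == "QD"

    def test_indel_uses_laxer_strand_thresholds(self):
        # fails the SNV cutoffs (60/3) but passes the indel ones (200/10)
        v = make_variant(ref="A", alt="AT",
                         site_qc=SiteQCMetrics(fs=150, sor=5, variant_class="indel"))
        assert filter_site_qc(v, CFG).keep
        snv = make_variant(site_qc=SiteQCMetrics(fs=150, sor=5))
        assert filter_site_qc(snv, CFG).reason == "FS"

    def test_all_metrics_missing_with_pass_flag_keeps(self):
        v = make_variant(site_qc=SiteQCMetrics())
        assert filter_site_qc(v, CFG).keep

    def test_vqsr_flag_drops_even_with_clean_metrics(self):
        v = make_variant(site_qc=SiteQCMetrics(
            filter_flags=frozenset({"VQSRTrancheSNP99.70to100.00"}), qd=30))
        assert filter_site_qc(v, CFG).reason == "VQSR"

    def test_excess_heterozygosity_boundary_is_strict(self):
        keep = make_variant(site_qc=SiteQCMetrics(excess_het_z=4.5))
        drop = make_variant(site_qc=SiteQCMetrics(excess_het_z=4.51))
        assert filter_site_qc(keep, CFG).keep
        assert filter_site_qc(drop, CFG).reason == "ExcessHet"

    def test_mq_rank_sum_applies_to_snvs_only(self):
        snv = make_variant(site_qc=SiteQCMetrics(mq_rank_sum=-13))
        indel = make_variant(ref="A", alt="AT",
                             site_qc=SiteQCMetrics(mq_rank_sum=-13, variant_class="indel"))
        assert filter_site_qc(snv, CFG).reason == "MQRankSum"
        assert filter_site_qc(indel, CFG).keep


class TestGenotypeQC:
    def test_boundary_plus_one_passes(self, trio_ped):
        v = make_variant(genotypes={"P1": gt("P1", "het", dp=11, gq=21),
                                    "F1": gt("F1", "hom_ref", 30, 99),
                                    "M1": gt("M1", "hom_ref", 30, 99)})
        assert filter_genotype_qc(v, trio_ped, CFG).keep

    def test_depth_threshold_is_strict_in_any_member(self, trio_ped):
        v = make_variant(genotypes={"P1": gt("P1", "het", 40, 90),
                                    "F1": gt("F1", "hom_ref", dp=10, gq=90),
                                    "M1": gt("M1", "hom_ref", 30, 99)})
        d = filter_genotype_qc(v, trio_ped, CFG)
        assert not d.keep and d.reason == "DP(F1)"

    def test_duo_checks_only_available_members(self):
        ped = make_trio_ped(duo_missing="mother")
        v = make_variant(genotypes={"P1": gt("P1", "het", 40, 90),
                                    "F1": gt("F1", "hom_ref", 40, 90)})
        assert filter_genotype_qc(v, ped, CFG).keep

    def test_missing_proband_genotype_drops(self, trio_ped):
        v = make_variant(genotypes={"F1": gt("F1", "hom_ref"), "M1": gt("M1", "hom_ref")})
        assert filter_genotype_qc(v, trio_ped, CFG).reason == "proband_genotype_missing"


class TestFrequency:
    @pytest.mark.parametrize("ac,keep", [(None, True), (0, True), (2, True), (3, False)])
    def test_dominant_allele_count_rule(self, ac, keep):
        v = make_variant(gnomad_ac=ac)
        assert filter_frequency(v, CFG, "dominant_denovo").keep is keep

    @pytest.mark.parametrize("af,keep", [(None, True), (0.0004, True),
                                         (0.0005, False), (0.01, False)])
    def test_compound_het_frequency_rule(self, af, keep):
        v = make_variant(gnomad_af=af)
        assert filter_frequency(v, CFG, "compound_het").keep is keep


class TestCohortRecurrence:
    def _two_family_ped(self):
        return Pedigree([
            Individual("P1", "FAM1", "F1", "M1", "male", "affected"),
            Individual("F1", "FAM1", sex="male", affected="unaffected"),
            Individual("M1", "FAM1", sex="female", affected="unaffected"),
            Individual("P2", "FAM2", "F2", "M2", "male", "affected"),
            Individual("F2", "FAM2", sex="male", affected="unaffected"),
            Individual("M2", "FAM2", sex="female", affected="unaffected"),
        ])

    def test_allele_in_unaffected_parent_of_other_family_drops(self):
        ped = self._two_family_ped()
        v1 = make_variant(genotypes={"P1": gt("P1", "het")})
        v2 = make_variant(family_id="FAM2",
                          genotypes={"P2": gt("P2", "hom_ref"), "F2": gt("F2", "het")})
        index = build_cohort_index([v1, v2], ped)
        assert not filter_cohort_recurrence(v1, index).keep

    def test_allele_shared_by_two_affected_probands_keeps(self):
        ped = self._two_family_ped()
        v1 = make_variant(genotypes={"P1": gt("P1", "het")})
        v2 = make_variant(family_id="FAM2", genotypes={"P2": gt("P2", "het")})
        index = build_cohort_index([v1, v2], ped)
        assert filter_cohort_recurrence(v1, index).keep
        assert filter_cohort_recurrence(v2, index).keep

    def test_empty_cohort_index_keeps(self):
        v = make_variant()
        assert filter_cohort_recurrence(v, {}).keep


def _brute_force_inheritance(proband_gt, father_gt, mother_gt):
    """Independent rule table over trio/duo genotype configurations.

    Returns the expected model string (None = parent genotype unavailable).
    """
    carrier = {"het", "hom_alt", "hemi_alt"}
    if proband_gt not in carrier:
        return "unknown"
    f = father_gt in carrier if father_gt is not None else None
    m = mother_gt in carrier if mother_gt is not None else None
    if f is False and m is False:
        return "de_novo"
    if proband_gt == "hom_alt" and father_gt == "het" and mother_gt == "het":
        return "homozygous_recessive"
    if f and m:
        return "unknown"
    if m:
        return "inherited_maternal"
    if f:
        return "inherited_paternal"
    return "unknown"


class TestInheritance:
    GTS = ["hom_ref", "het", "hom_alt"]

    def test_enumeration_matches_rule_table_for_trios(self, trio_ped):
        for p, f, m in itertools.product(self.GTS, repeat=3):
            v = make_variant(genotypes={"P1": gt("P1", p), "F1": gt("F1", f),
                                        "M1": gt("M1", m)})
            call = infer_inheritance(v, trio_ped)
            assert call.model == _brute_force_inheritance(p, f, m), (p, f, m)

    def test_enumeration_matches_rule_table_for_duos(self):
        ped = make_trio_ped(duo_missing="father")
        for p, m in itertools.product(self.GTS, repeat=2):
            v = make_variant(genotypes={"P1": gt("P1", p), "M1": gt("M1", m)})
            call = infer_inheritance(v, ped)
            assert call.model == _brute_force_inheritance(p, None, m), (p, m)

    def test_x_de_novo_in_female_is_flagged_x_linked(self):
        ped = make_trio_ped(proband_sex="female")
        v = make_variant(chrom="X", genotypes={"P1": gt("P1", "het"),
                                               "F1": gt("F1", "hom_ref"),
                                               "M1": gt("M1", "hom_ref")})
        call = infer_inheritance(v, ped)
        assert call.model == "de_novo" and call.x_linked
        assert call.consistent_with_phenotype

    def test_inherited_from_affected_mother_is_consistent(self):
        ped = make_trio_ped(mother_affected=True)
        v = make_variant(genotypes={"P1": gt("P1", "het"), "F1": gt("F1", "hom_ref"),
                                    "M1": gt("M1", "het")})
        call = infer_inheritance(v, ped)
        assert call.model == "inherited_maternal" and call.consistent_with_phenotype

    def test_inherited_from_unaffected_parent_is_inconsistent(self, trio_ped):
        v = make_variant(genotypes={"P1": gt("P1", "het"), "F1": gt("F1", "het"),
                                    "M1": gt("M1", "hom_ref")})
        call = infer_inheritance(v, trio_ped)
        assert call.model == "inherited_paternal" and not call.consistent_with_phenotype

    def test_x_maternal_carrier_to_male_is_consistent_despite_unaffected_mother(self):
        ped = make_trio_ped(proband_sex="male")
        v = make_variant(chrom="X", genotypes={"P1": gt("P1", "hemi_alt"),
                                               "F1": gt("F1", "hom_ref"),
                                               "M1": gt("M1", "het")})
        call = infer_inheritance(v, ped)
        assert call.model == "inherited_maternal" and call.x_linked
        assert call.consistent_with_phenotype

    def test_missing_proband_genotype_is_an_error(self, trio_ped):
        v = make_variant(genotypes={"F1": gt("F1", "hom_ref"), "M1": gt("M1", "hom_ref")})
        with pytest.raises(ValueError, match="proband genotype missing"):
            infer_inheritance(v, trio_ped)


class TestCompoundHets:
    def _het(self, pos, parent):
        genotypes = {"P1": gt("P1", "het"),
                     "F1": gt("F1", "het" if parent == "father" else "hom_ref"),
                     "M1": gt("M1", "het" if parent == "mother" else "hom_ref")}
        return make_variant(pos=pos, genotypes=genotypes)

    def test_one_maternal_one_paternal_gives_one_pair(self, trio_ped):
        pairs = pair_compound_hets([self._het(100, "mother"), self._het(200, "father")],
                                   trio_ped)
        assert len(pairs) == 1

    def test_two_maternal_hets_give_no_pair(self, trio_ped):
        pairs = pair_compound_hets([self._het(100, "mother"), self._het(200, "mother")],
                                   trio_ped)
        assert pairs == []

    def test_three_hets_give_all_maternal_paternal_combinations(self, trio_ped):
        variants = [self._het(100, "mother"), self._het(200, "mother"),
                    self._het(300, "father")]
        pairs = pair_compound_hets(variants, trio_ped)
        # brute force: every (maternal, paternal) combination
        maternal = [v for v in variants if v.genotypes["M1"].genotype == "het"]
        paternal = [v for v in variants if v.genotypes["F1"].genotype == "het"]
        assert len(pairs) == len(maternal) * len(paternal) == 2


class TestStructuralVariants:
    def _call(self, **kw):
        base = dict(family_id="FAM1", chrom="2", start=100, end=5000, sv_type="DEL",
                    sv_af=None, families_observed=1)
        base.update(kw)
        return StructuralVariantCall(**base)

    def test_recurrent_in_three_families_drops(self):
        assert filter_sv([self._call(families_observed=3)], CFG) == []

    def test_rare_single_family_call_keeps(self):
        calls = [self._call(sv_af=0.0004)]
        assert filter_sv(calls, CFG) == calls

    def test_common_sv_drops_strictly_above_threshold(self):
        assert filter_sv([self._call(sv_af=0.0006)], CFG) == []
        assert filter_sv([self._call(sv_af=0.0005)], CFG) != []

    def test_de_novo_duplication_with_missing_frequency_keeps(self):
        dup = self._call(chrom="2", start=230641603, end=230701402, sv_type="DUP")
        assert dup.length == 59_800
        assert filter_sv([dup], CFG) == [dup]

    def test_cnv_span_cap(self):
        with pytest.raises(ValueError, match="exceeds"):
            self._call(end=100 + 6_000_000)


class TestApplyFilters:
    def test_order_independence_of_survivor_set(self):
        from castriage.simulate import CohortSimSpec, simulate_cohort

        variants, ped, _ = simulate_cohort(CohortSimSpec(n_families=6, seed=21,
                                                         background_rate=15.0))
        pool_a, _ = apply_filters(variants, ped)
        shuffled = variants.copy()
        random.Random(7).shuffle(shuffled)
        pool_b, _ = apply_filters(shuffled, ped)
        key = lambda pv: (pv.variant.family_id,) + pv.variant.allele_key
        assert [key(p) for p in pool_a] == [key(p) for p in pool_b]
        assert [p.inheritance.model for p in pool_a] == [p.inheritance.model for p in pool_b]

    def test_attrition_conserves_every_input_variant(self):
        from castriage.simulate import CohortSimSpec, simulate_cohort

        variants, ped, _ = simulate_cohort(CohortSimSpec(n_families=6, seed=22,
                                                         background_rate=15.0))
        pool, attrition = apply_filters(variants, ped)
        assert len(attrition) == len(variants)
        n_dropped = (attrition["stage"] != "").sum()
        assert len(pool) + n_dropped == len(variants)

    def test_unknown_genotype_sample_is_an_error(self, trio_ped):
        v = make_variant(genotypes={"P1": gt("P1", "het"), "ZZ": gt("ZZ", "het")})
        with pytest.raises(ValueError, match="absent from pedigree"):
            apply_filters([v], trio_ped)
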