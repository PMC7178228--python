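"""Per-sample profiling: star alleles, phenotypes, dosing, reports, MSC payloads."""

import json

import pytest

from pgxkit.profiles import (
    anticoagulant_dose_lookup,
    assign_diplotype,
    build_profile,
    call_star_alleles,
    co_occurrence_screen,
    generate_report,
    hla_tag_report,
    msc_payload,
)
from pgxkit.variant_io import SiteRecord

BUILD = "GRCh37"


def _panel_record(panel, gene, star, genotypes):
    pv = panel.by_star(gene, star)
    chrom, pos = pv.coords(BUILD)
    ac = sum(a for gt in genotypes.values() for a in gt if a)
    an = sum(1 for gt in genotypes.values() for a in gt if a is not None)
    return SiteRecord(chrom, pos, pv.ref, pv.alt, ac=ac, an=an, genotypes=genotypes,
                      gene=gene, annotations={"gene": gene, "consequence": "missense_variant"})


def _homref_everywhere(panel, sample, but=()):
    """gVCF-like records: hom-ref at every panel site except the overrides."""
    overrides = {(g, s): gt for g, s, gt in but}
    records = []
    for pv in panel.sites(BUILD):
        gt = overrides.get((pv.gene, pv.star_label), (0, 0))
        records.append(_panel_record(panel, pv.gene, pv.star_label, {sample: gt}))
    return records


class TestStarAlleleCalling:
    def test_het_variant_gives_star_over_wildtype(self, panel):
        records = _homref_everywhere(panel, "S", but=[("CYP2C9", "*2", (0, 1))])
        call = assign_diplotype("CYP2C9", *call_star_alleles("S", records, panel, BUILD)["CYP2C9"],
                                panel)
        assert call.diplotype == "*1/*2"

    def test_hom_variant(self, panel):
        records = _homref_everywhere(panel, "S", but=[("VKORC1", "*2", (1, 1))])
        call = assign_diplotype("VKORC1", *call_star_alleles("S", records, panel, BUILD)["VKORC1"],
                                panel)
        assert call.diplotype == "*2/*2"

    def test_missing_genotype_never_imputed_as_wildtype(self, panel):
        records = _homref_everywhere(panel, "S")
        # mask the CYP2C19*2 site entirely
        pv = panel.by_star("CYP2C19", "*2")
        records = [r for r in records if r.key != pv.key(BUILD)]
        alleles, flags = call_star_alleles("S", records, panel, BUILD)["CYP2C19"]
        assert "allele_unknown:*2" in flags
        call = assign_diplotype("CYP2C19", alleles, flags, panel)
        assert "*?" in call.diplotype

    def test_two_het_alleles_flag_phase(self, panel):
        records = _homref_everywhere(panel, "S", but=[("CYP2C19", "*2", (0, 1)),
                                                      ("CYP2C19", "*17", (0, 1))])
        alleles, flags = call_star_alleles("S", records, panel, BUILD)["CYP2C19"]
        call = assign_diplotype("CYP2C19", alleles, flags, panel)
        assert call.diplotype == "*17/*2"
        assert "ambiguous_phase" in call.flags

    def test_more_than_two_alleles_keeps_highest_impact(self, panel):
        records = _homref_everywhere(panel, "S", but=[("CYP2D6", "*4", (0, 1)),
                                                      ("CYP2D6", "*41", (0, 1)),
                                                      ("CYP2D6", "*10", (1, 1))])
        alleles, flags = call_star_alleles("S", records, panel, BUILD)["CYP2D6"]
        assert sorted(alleles) == ["*10", "*10", "*4", "*41"]
        call = assign_diplotype("CYP2D6", alleles, flags, panel)
        # no-function *4 outranks the decreased-function alleles
        assert "*4" in call.alleles and len(call.alleles) == 2
        assert {"ambiguous_phase", "possible_misclassification"} <= call.flags


class TestCoOccurrence:
    def test_planted_individual_yields_single_three_variant_note(self, cohort547, panel):
        _, cohort = cohort547
        notes = co_occurrence_screen("S0000", cohort.records, panel, BUILD)
        cyp2c19 = [n for n in notes if n["gene"] == "CYP2C19"]
        assert len(cyp2c19) == 1
        assert len(cyp2c19[0]["variants"]) == 3
        assert cyp2c19[0]["possible_misclassification"]

    def test_single_variant_gene_not_flagged(self, panel):
        records = _homref_everywhere(panel, "S", but=[("TPMT", "*3C", (0, 1))])
        assert co_occurrence_screen("S", records, panel, BUILD) == []


class TestAnticoagulantLookup:
    def test_reference_combination(self):
        g = anticoagulant_dose_lookup("*1/*1", "*1/*1")
        assert g.dose_fraction == 100.0 and not g.withheld

    def test_double_homozygote_dose_reduction(self):
        g = anticoagulant_dose_lookup("*2/*2", "*2/*2")
        assert g.dose_fraction == 35.0

    def test_unresolved_genotype_withholds_guidance(self):
        g = anticoagulant_dose_lookup("*2/*2", "*2/*?")
        assert g.withheld and g.dose_fraction is None

    def test_combination_without_fraction_gets_action_text_only(self):
        g = anticoagulant_dose_lookup("*1/*2", "*1/*1")
        assert g.dose_fraction is None and not g.withheld
        assert "INR" in g.action_text


class TestHlaTag:
    def test_het_carrier_with_caveat(self):
        note = hla_tag_report(1)
        assert note["status"] == "carrier"
        assert "European ancestry" in note["caveat"]

    def test_homref_non_carrier(self):
        assert hla_tag_report(0)["status"] == "non_carrier"

    def test_missing_site_is_unknown_never_non_carrier(self):
        assert hla_tag_report(None)["status"] == "unknown"


class TestProfileAndReport:
    @pytest.fixture()
    def wildtype_profile(self, panel, rules, recommendations):
        records = _homref_everywhere(panel, "S")
        tag = panel.tag_variants[0]
        records.append(SiteRecord(*tag.coords(BUILD), tag.ref, tag.alt, ac=0, an=2,
                                  genotypes={"S": (0, 0)}, gene=tag.gene))
        return build_profile("S", records, panel, rules, recommendations, build=BUILD)

    def test_all_wildtype_profile_has_no_dose_adjustments(self, wildtype_profile, panel):
        assert set(wildtype_profile.calls) == set(panel.genes)
        assert all(c.phenotype in ("NM", "non_carrier", "normal_sensitivity")
                   for c in wildtype_profile.calls.values())
        assert wildtype_profile.recommendations == []
        report, _ = generate_report(wildtype_profile)
        assert "no dose adjustments" in report

    def test_poor_metabolizer_gets_gene_linked_recommendations(self, panel, rules, recommendations):
        records = _homref_everywhere(panel, "S", but=[("CYP2C19", "*2", (1, 1))])
        profile = build_profile("S", records, panel, rules, recommendations, build=BUILD)
        assert profile.calls["CYP2C19"].phenotype == "PM"
        report, _ = generate_report(profile)
        assert "clopidogrel" in report

    def test_msc_payload_roundtrip_and_determinism(self, panel, rules, recommendations):
        records = _homref_everywhere(panel, "S", but=[("CYP2C9", "*3", (0, 1)),
                                                      ("VKORC1", "*2", (1, 1))])
        p1 = build_profile("S", records, panel, rules, recommendations, build=BUILD)
        p2 = build_profile("S", records, panel, rules, recommendations, build=BUILD)
        m1, m2 = msc_payload(p1), msc_payload(p2)
        assert m1 == m2  # identical inputs give identical payloads
        decoded = json.loads(json.dumps(m1))
        assert decoded["phenotypes"] == {g: c.phenotype for g, c in p1.calls.items()}
        assert decoded["profile_id"] == m1["profile_id"]

    def test_sv_table_sets_cyp2d6_diplotype(self, panel, rules, recommendations):
        records = _homref_everywhere(panel, "S")
        profile = build_profile("S", records, panel, rules, recommendations,
                                sv_table={"S": "*5/*1"}, build=BUILD)
        call = profile.calls["CYP2D6"]
        assert call.diplotype == "*5/*1"
        assert call.phenotype == "IM"
        assert "sv_unknown" not in call.flags

    def test_without_sv_table_cyp2d6_flagged(self, wildtype_profile):
        assert "sv_unknown" in wildtype_profile.calls["CYP2D6"].flags
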