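import pytest

from pidtriage import (
    AffectedStatus,
    AnnotatedVariant,
    CallSet,
    CandidateGroup,
    FilterConfig,
    GenotypeCall,
    GroupHypothesis,
    InheritanceMode,
    PanelEntry,
    Sample,
    Tier,
    Zygosity,
    build_pedigree,
    classify,
    phenotype_match,
    run_pipeline,
    summarize_cohort,
    validate_panel,
)
from pidtriage.fixture import fixture_panel

AD = InheritanceMode.AD
AR = InheritanceMode.AR


class TestPhenotypeMatch:
    lrba = PanelEntry("LRBA", frozenset({AR}),
                      phenotype_tags=frozenset(
                          {"granulomatous_disease", "autoimmune_cytopenia"}))

    def test_overlapping_tags_match(self):
        assert phenotype_match(
            frozenset({"autoimmune_cytopenia", "granulomatous_disease"}),
            self.lrba)

    def test_disjoint_tags_do_not_match(self):
        assert not phenotype_match(
            frozenset({"recurrent_sinopulmonary_infections"}), self.lrba)

    def test_empty_patient_tags_never_match(self):
        assert not phenotype_match(frozenset(), self.lrba)


def one_variant_callset(gene="NFKB1", hgmd=False, zyg=Zygosity.HET):
    cs = CallSet()
    v = AnnotatedVariant(gene, 100, "A", "T", gene=gene, cadd_scaled=30.0,
                         hgmd_known=hgmd)
    cs.add_variant(v)
    cs.add_call(GenotypeCall("P", v.key, zyg, 50, 99))
    return cs, v.key


class TestClassify:
    panel = validate_panel([
        PanelEntry("NFKB1", frozenset({AD}),
                   phenotype_tags=frozenset({"hypogammaglobulinemia"})),
        PanelEntry("FASLG", frozenset({AR}),
                   phenotype_tags=frozenset({"lymphoproliferation"})),
        PanelEntry("TNFRSF13B", frozenset({AD, AR}),
                   phenotype_tags=frozenset({"hypogammaglobulinemia"}),
                   association_tier_override="disease_associated"),
    ])

    def test_mode_and_phenotype_match_is_likely(self):
        cs, key = one_variant_callset("NFKB1")
        g = CandidateGroup("P", "NFKB1", GroupHypothesis.MONOALLELIC, (key,))
        f = classify(g, self.panel,
                     frozenset({"hypogammaglobulinemia"}), cs)
        assert f.tier is Tier.LIKELY_DISEASE_CAUSING and f.reasons == ()

    def test_zygosity_mismatch_is_other_damaging(self):
        # heterozygous variant in a recessive-only gene
        cs, key = one_variant_callset("FASLG")
        g = CandidateGroup("P", "FASLG", GroupHypothesis.MONOALLELIC, (key,))
        f = classify(g, self.panel, frozenset({"lymphoproliferation"}), cs)
        assert f.tier is Tier.OTHER_DAMAGING
        assert "zygosity_mismatch" in f.reasons

    def test_phenotype_mismatch_is_other_damaging(self):
        cs, key = one_variant_callset("NFKB1")
        g = CandidateGroup("P", "NFKB1", GroupHypothesis.MONOALLELIC, (key,))
        f = classify(g, self.panel, frozenset({"eczema"}), cs)
        assert f.tier is Tier.OTHER_DAMAGING
        assert f.reasons == ("phenotype_mismatch",)

    def test_association_override_wins_regardless(self):
        cs, key = one_variant_callset("TNFRSF13B")
        g = CandidateGroup("P", "TNFRSF13B", GroupHypothesis.MONOALLELIC,
                           (key,))
        f = classify(g, self.panel, frozenset({"hypogammaglobulinemia"}), cs)
        assert f.tier is Tier.DISEASE_ASSOCIATED

    def test_unphased_biallelic_in_ar_gene_reports_phase_unknown(self):
        cs = CallSet()
        keys = []
        for i in range(2):
            v = AnnotatedVariant("FASLG", 100 + i, "A", "T", gene="FASLG")
            cs.add_variant(v)
            keys.append(v.key)
            cs.add_call(GenotypeCall("P", v.key, Zygosity.HET, 50, 99))
        g = CandidateGroup("P", "FASLG", GroupHypothesis.BIALLELIC_UNPHASED,
                           tuple(keys))
        f = classify(g, self.panel, frozenset({"lymphoproliferation"}), cs)
        assert f.tier is Tier.OTHER_DAMAGING
        assert "phase_unknown" in f.reasons

    def test_hgmd_reported_but_never_raises_tier(self):
        cs, key = one_variant_callset("FASLG", hgmd=True)
        g = CandidateGroup("P", "FASLG", GroupHypothesis.MONOALLELIC, (key,))
        f = classify(g, self.panel, frozenset(), cs)
        assert f.hgmd_support
        assert f.tier is Tier.OTHER_DAMAGING

    def test_hemizygous_hom_alt_compatible_with_xl_gene(self):
        panel = validate_panel([
            PanelEntry("BTK", frozenset({InheritanceMode.XL}),
                       phenotype_tags=frozenset({"low_B_cells"}))])
        cs, key = one_variant_callset("BTK", zyg=Zygosity.HOM_ALT)
        g = CandidateGroup("P", "BTK", GroupHypothesis.BIALLELIC_HOM, (key,))
        f = classify(g, panel, frozenset({"low_B_cells"}), cs)
        assert f.tier is Tier.LIKELY_DISEASE_CAUSING


class TestCohortSummary:
    def test_paper_cohort_headline_numbers(self, paper_result):
        s = paper_result.summary
        assert s.n_patients == 50
        assert s.n_unique_likely == 17
        assert s.n_patients_likely == 15
        assert s.diagnostic_yield == pytest.approx(0.30)

    def test_yield_bounds(self, paper_result):
        s = paper_result.summary
        assert 0 <= s.diagnostic_yield <= \
            s.n_patients_with_panel_variant / s.n_patients

    def test_shared_variant_deduplicated(self, paper_result):
        # the splice variant shared by the two related patients counts once
        likely = [f for f in paper_result.findings
                  if f.tier is Tier.LIKELY_DISEASE_CAUSING]
        assert len(likely) == 15
        total_keys = sum(len(f.group.variant_keys) for f in likely)
        assert total_keys == 18
        assert paper_result.summary.n_unique_likely == 17

    def test_multi_gene_patient_counted_once_top_tier_first(self, paper):
        # add an association-tier variant to a patient who already holds a
        # likely finding: the breakdown keeps them in the causal gene
        cs = CallSet()
        for v in paper.callset.variants.values():
            cs.add_variant(v)
        taci = AnnotatedVariant("TNFRSF13B", 500, "C", "T",
                                gene="TNFRSF13B", cadd_scaled=25.0)
        cs.add_variant(taci)
        for c in paper.callset.calls.values():
            cs.add_call(c)
        cs.add_call(GenotypeCall("P11", taci.key, Zygosity.HET, 50, 99))
        res = run_pipeline(cs, paper.pedigree, paper.panel)
        tiers = {f.tier for f in res.findings if f.patient_id == "P11"}
        assert tiers == {Tier.LIKELY_DISEASE_CAUSING,
                         Tier.DISEASE_ASSOCIATED}
        breakdown = res.summary.tier_breakdown
        assert breakdown["likely_disease_causing"]["PIK3CD"] == 1
        assert "TNFRSF13B" not in breakdown.get("disease_associated", {})
        assert res.summary.n_patients_likely == 15

    def test_empty_cohort_all_zero(self):
        ped = build_pedigree(
            [Sample("P", affected=AffectedStatus.AFFECTED)])
        s = summarize_cohort([], CallSet(), ped, fixture_panel(),
                             FilterConfig())
        assert s.n_unique_likely == 0 and s.diagnostic_yield == 0.0
        assert s.tier_breakdown == {}

    def test_override_removal_is_local(self, paper):
        # turning off the TNFRSF13B override must not change other genes
        from dataclasses import replace as dc_replace

        cs = CallSet()
        for v in paper.callset.variants.values():
            cs.add_variant(v)
        taci = AnnotatedVariant("TNFRSF13B", 500, "C", "T",
                                gene="TNFRSF13B", cadd_scaled=25.0)
        cs.add_variant(taci)
        for c in paper.callset.calls.values():
            cs.add_call(c)
        cs.add_call(GenotypeCall("P20", taci.key, Zygosity.HET, 50, 99))

        base = run_pipeline(cs, paper.pedigree, paper.panel)
        entries = [
            dc_replace(e, association_tier_override=None)
            if e.gene == "TNFRSF13B" else e
            for e in paper.panel
        ]
        res = run_pipeline(cs, paper.pedigree, validate_panel(entries))

        def tiers_without_taci(result):
            return sorted(
                (f.patient_id, f.gene, f.tier.value)
                for f in result.findings if f.gene != "TNFRSF13B"
            )

        assert tiers_without_taci(base) == tiers_without_taci(res)
        taci_base = [f.tier for f in base.findings if f.gene == "TNFRSF13B"]
        taci_new = [f.tier for f in res.findings if f.gene == "TNFRSF13B"]
        assert taci_base == [Tier.DISEASE_ASSOCIATED]
        assert taci_new == [Tier.LIKELY_DISEASE_CAUSING]
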