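"""Inheritance engine: grouping, trio phasing vs a brute-force oracle,
de novo detection and segregation flags."""

import itertools

import pytest

from pidtriage import (
    AffectedStatus,
    AnnotatedVariant,
    CallSet,
    CandidateGroup,
    GenotypeCall,
    GroupHypothesis,
    InheritanceMode,
    PanelEntry,
    Sample,
    SegregationFlag,
    Tier,
    VariantKey,
    Zygosity,
    build_pedigree,
    detect_de_novo,
    group_candidates,
    load_paper_fixture,
    phase_compound_het,
    run_pipeline,
    validate_panel,
)

AD = InheritanceMode.AD
AR = InheritanceMode.AR
HOM_REF, HET, HOM_ALT = Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT

PANEL = validate_panel([
    PanelEntry("ARGENE", frozenset({AR}),
               phenotype_tags=frozenset({"tag"})),
    PanelEntry("ADGENE", frozenset({AD}),
               phenotype_tags=frozenset({"tag"})),
])


def make_trio_callset(n_variants, proband_zygs, mother_zygs, father_zygs,
                      gene="ARGENE"):
    cs = CallSet()
    keys = []
    for i in range(n_variants):
        v = AnnotatedVariant(gene, 100 + i, "A", "T", gene=gene,
                             cadd_scaled=30.0)
        cs.add_variant(v)
        keys.append(v.key)
    for sid, zygs in (("P", proband_zygs), ("M", mother_zygs),
                      ("F", father_zygs)):
        for k, z in zip(keys, zygs):
            cs.add_call(GenotypeCall(sid, k, z, 50, 99))
    ped = build_pedigree([
        Sample("M", affected=AffectedStatus.UNAFFECTED),
        Sample("F", affected=AffectedStatus.UNAFFECTED),
        Sample("P", affected=AffectedStatus.AFFECTED, mother_id="M",
               father_id="F", phenotype_tags=frozenset({"tag"})),
    ])
    return cs, ped, keys


class TestGrouping:
    def test_two_hets_in_ar_gene_form_biallelic_candidate(self):
        cs, ped, keys = make_trio_callset(2, [HET, HET], [HET, HOM_REF],
                                          [HOM_REF, HET])
        groups = group_candidates({"P": cs.calls_for_sample("P")[:2]},
                                  PANEL, cs.variants)
        groups = [g for g in groups if g.patient_id == "P"]
        assert len(groups) == 1
        assert groups[0].hypothesis is GroupHypothesis.BIALLELIC_UNPHASED
        assert len(groups[0].variant_keys) == 2

    def test_single_het_is_monoallelic_even_in_ar_gene(self):
        cs, _, _ = make_trio_callset(1, [HET], [HOM_REF], [HOM_REF])
        (g,) = group_candidates(
            {"P": [c for c in cs.calls_for_sample("P")]}, PANEL, cs.variants)
        assert g.hypothesis is GroupHypothesis.MONOALLELIC

    def test_hom_alt_is_biallelic_hom(self):
        cs, _, _ = make_trio_callset(1, [HOM_ALT], [HET], [HET])
        (g,) = group_candidates(
            {"P": [c for c in cs.calls_for_sample("P")]}, PANEL, cs.variants)
        assert g.hypothesis is GroupHypothesis.BIALLELIC_HOM

    def test_two_hets_in_ad_only_gene_stay_monoallelic(self):
        cs, _, _ = make_trio_callset(2, [HET, HET], [HOM_REF, HOM_REF],
                                     [HOM_REF, HOM_REF], gene="ADGENE")
        groups = group_candidates(
            {"P": cs.calls_for_sample("P")}, PANEL, cs.variants)
        assert all(g.hypothesis is GroupHypothesis.MONOALLELIC
                   for g in groups)
        assert len(groups) == 2

    def test_every_surviving_call_in_exactly_one_group(self, paper,
                                                       paper_result):
        calls = {
            (p, c.variant_key)
            for p, cc in paper_result.cascade.survivors.items() for c in cc
        }
        grouped = [
            (g.patient_id, k)
            for g in paper_result.groups for k in g.variant_keys
        ]
        assert sorted(grouped) == sorted(calls)


def phasing_oracle(origins):
    """Brute-force enumeration of parental-origin assignments.

    ``origins`` is one set per variant holding the parents that carry it.
    Returns 'comphet' when every assignment uses both parents, 'cis' when
    every assignment uses one, else 'unphased'.
    """
    if any(not o for o in origins):
        return "unphased"  # Mendelian inconsistency
    outcomes = set()
    for combo in itertools.product(*origins):
        outcomes.add("trans" if len(set(combo)) >= 2 else "cis")
    if outcomes == {"trans"}:
        return "comphet"
    if outcomes == {"cis"}:
        return "cis"
    return "unphased"


def observed_phase(result):
    if len(result) == 2:
        return "cis"
    (g,) = result
    if g.hypothesis is GroupHypothesis.BIALLELIC_COMPHET:
        return "comphet"
    assert SegregationFlag.PHASE_UNKNOWN in g.segregation
    return "unphased"


class TestPhasing:
    def test_one_variant_from_each_parent_is_trans(self):
        cs, ped, keys = make_trio_callset(2, [HET, HET], [HET, HOM_REF],
                                          [HOM_REF, HET])
        group = CandidateGroup("P", "ARGENE",
                               GroupHypothesis.BIALLELIC_UNPHASED,
                               tuple(keys))
        (out,) = phase_compound_het(group, ped, cs)
        assert out.hypothesis is GroupHypothesis.BIALLELIC_COMPHET

    def test_both_variants_from_one_parent_is_cis(self):
        # both variants on the paternal haplotype: not a biallelic candidate
        cs, ped, keys = make_trio_callset(2, [HET, HET], [HOM_REF, HOM_REF],
                                          [HET, HET])
        group = CandidateGroup("P", "ARGENE",
                               GroupHypothesis.BIALLELIC_UNPHASED,
                               tuple(keys))
        out = phase_compound_het(group, ped, cs)
        assert len(out) == 2
        assert all(g.hypothesis is GroupHypothesis.MONOALLELIC for g in out)

    def test_missing_parent_leaves_phase_unknown(self):
        cs = CallSet()
        keys = []
        for i in range(2):
            v = AnnotatedVariant("ARGENE", 100 + i, "A", "T", gene="ARGENE")
            cs.add_variant(v)
            keys.append(v.key)
            cs.add_call(GenotypeCall("P", v.key, HET, 50, 99))
        ped = build_pedigree([Sample("P", affected=AffectedStatus.AFFECTED)])
        group = CandidateGroup("P", "ARGENE",
                               GroupHypothesis.BIALLELIC_UNPHASED,
                               tuple(keys))
        (out,) = phase_compound_het(group, ped, cs)
        assert out.hypothesis is GroupHypothesis.BIALLELIC_UNPHASED
        assert SegregationFlag.PHASE_UNKNOWN in out.segregation

    def test_mendelian_inconsistency_logged_and_unphased(self, caplog):
        cs, ped, keys = make_trio_callset(2, [HET, HET], [HOM_REF, HOM_REF],
                                          [HOM_REF, HET])
        group = CandidateGroup("P", "ARGENE",
                               GroupHypothesis.BIALLELIC_UNPHASED,
                               tuple(keys))
        with caplog.at_level("WARNING"):
            (out,) = phase_compound_het(group, ped, cs)
        assert SegregationFlag.PHASE_UNKNOWN in out.segregation
        assert "inconsistency" in caplog.text

    @pytest.mark.parametrize("n_variants", [2, 3])
    def test_agrees_with_brute_force_oracle_exhaustively(self, n_variants):
        zygs = (HOM_REF, HET, HOM_ALT)
        for m_zygs in itertools.product(zygs, repeat=n_variants):
            for f_zygs in itertools.product(zygs, repeat=n_variants):
                cs, ped, keys = make_trio_callset(
                    n_variants, [HET] * n_variants, list(m_zygs),
                    list(f_zygs))
                group = CandidateGroup(
                    "P", "ARGENE", GroupHypothesis.BIALLELIC_UNPHASED,
                    tuple(keys))
                result = phase_compound_het(group, ped, cs)
                origins = [
                    {p for p, z in (("M", mz), ("F", fz))
                     if z in (HET, HOM_ALT)}
                    for mz, fz in zip(m_zygs, f_zygs)
                ]
                expected = phasing_oracle(origins)
                if expected == "cis" and n_variants > 2:
                    assert len(result) == n_variants
                    continue
                got = (
                    "cis" if len(result) > 1 else observed_phase(result)
                )
                assert got == expected, (m_zygs, f_zygs)


class TestDeNovo:
    def build(self, proband, mother, father, mother_status, father_status):
        cs = CallSet()
        v = AnnotatedVariant("ADGENE", 100, "A", "T", gene="ADGENE")
        cs.add_variant(v)
        for sid, z in (("P", proband), ("M", mother), ("F", father)):
            if z is not None:
                cs.add_call(GenotypeCall(sid, v.key, z, 50, 99))
        ped = build_pedigree([
            Sample("M", affected=mother_status),
            Sample("F", affected=father_status),
            Sample("P", affected=AffectedStatus.AFFECTED, mother_id="M",
                   father_id="F"),
        ])
        group = CandidateGroup("P", "ADGENE", GroupHypothesis.MONOALLELIC,
                               (v.key,))
        return detect_de_novo(group, ped, cs)

    def test_both_parents_reference_flags_de_novo(self):
        g = self.build(HET, HOM_REF, HOM_REF, AffectedStatus.UNAFFECTED,
                       AffectedStatus.UNAFFECTED)
        assert SegregationFlag.DE_NOVO in g.segregation

    def test_unaffected_carrier_father_flags_transmission(self):
        g = self.build(HET, HOM_REF, HET, AffectedStatus.UNAFFECTED,
                       AffectedStatus.UNAFFECTED)
        assert SegregationFlag.INHERITED_UNAFFECTED_PARENT in g.segregation
        assert SegregationFlag.DE_NOVO not in g.segregation

    def test_ungenotyped_parent_gives_no_de_novo_call(self):
        g = self.build(HET, HOM_REF, None, AffectedStatus.UNAFFECTED,
                       AffectedStatus.UNAFFECTED)
        assert SegregationFlag.DE_NOVO not in g.segregation

    def test_flags_mutually_exclusive_on_paper_cohort(self, paper_result):
        for g in paper_result.groups:
            assert not (
                SegregationFlag.DE_NOVO in g.segregation
                and SegregationFlag.INHERITED_UNAFFECTED_PARENT
                in g.segregation
            )


class TestSegregationOnPaperCohort:
    def flags_for(self, result, pid):
        (g,) = [g for g in result.groups if g.patient_id == pid]
        return g.segregation

    def test_unaffected_mother_and_siblings_incomplete_penetrance(
            self, paper_result):
        flags = self.flags_for(paper_result, "P08")
        assert SegregationFlag.INCOMPLETE_PENETRANCE in flags

    def test_mildly_affected_carrier_mother_variable_expressivity(
            self, paper_result):
        flags = self.flags_for(paper_result, "P12")
        assert SegregationFlag.VARIABLE_EXPRESSIVITY in flags
        assert SegregationFlag.INHERITED_UNAFFECTED_PARENT not in flags

    def test_affected_second_cousin_carrier_segregates_with_disease(
            self, paper_result):
        for pid in ("P01", "P02"):
            assert SegregationFlag.SEGREGATES_WITH_DISEASE in \
                self.flags_for(paper_result, pid)

    def test_de_novo_trio_not_flagged_as_segregating(self, paper_result):
        flags = self.flags_for(paper_result, "P06")
        assert SegregationFlag.DE_NOVO in flags
        assert SegregationFlag.SEGREGATES_WITH_DISEASE not in flags

    def test_carrier_relatives_recorded(self, paper_result):
        (g,) = [g for g in paper_result.groups if g.patient_id == "P08"]
        assert {r for r, _ in g.carrier_relatives} == \
            {"P08_M", "P08_S1", "P08_S2"}


class TestRelabelingEquivariance:
    def test_flags_stable_under_sample_renaming(self):
        fx = load_paper_fixture()
        base = run_pipeline(fx.callset, fx.pedigree, fx.panel)

        mapping = {s.sample_id: f"Z{i:03d}"
                   for i, s in enumerate(fx.samples)}
        cs = CallSet()
        for v in fx.callset.variants.values():
            cs.add_variant(v)
        for c in fx.callset.calls.values():
            cs.add_call(GenotypeCall(mapping[c.sample_id], c.variant_key,
                                     c.zygosity, c.depth, c.gq))
        from dataclasses import replace

        samples = [
            replace(s, sample_id=mapping[s.sample_id],
                    mother_id=mapping.get(s.mother_id),
                    father_id=mapping.get(s.father_id))
            for s in fx.samples
        ]
        renamed = run_pipeline(cs, build_pedigree(samples), fx.panel)

        def signature(result, names):
            return sorted(
                (names.get(g.patient_id, g.patient_id), g.gene,
                 g.hypothesis.value,
                 tuple(sorted(f.value for f in g.segregation)))
                for g in result.groups
            )

        assert signature(base, mapping) == signature(renamed, {})
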