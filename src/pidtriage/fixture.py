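"""Packaged study fixture: the published mono- and biallelic variant tables.

This module rebuilds, in code, the 18 reported variant rows (12 monoallelic
carriers across NFKB1, STAT3, CTLA4, PIK3CD and IKZF1; three
compound-heterozygous subjects in LRBA and STXBP2), together with the
pedigree facts stated for them: the two de novo events, transmission from
unaffected or mildly affected carrier relatives, the second-cousin pair
sharing one NFKB1 splice variant, and the parental origins of the
compound-heterozygous pairs.  CADD-scaled scores and population allele
frequencies are the published values.

Genomic coordinates are synthetic — one contig per gene, positions spaced
arbitrarily — because the published tables identify variants by HGVS
notation only and no downstream logic reads coordinates.  Gene-specific
MSC values and the controlled phenotype tags are likewise curated so the
published tier assignments are reproduced (the LRBA cutoff sits above all
four published LRBA CADD scores, exercising the phenotype-match override
those variants were retained under); they are a reconstruction, not
published data.

The cohort is 50 affected patients: the 15 variant carriers plus 35
patients with no panel variants, standing in for the undiagnosed remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import CallSet
from .models import (
    AffectedStatus,
    AnnotatedVariant,
    GenotypeCall,
    InheritanceMode,
    Panel,
    PanelEntry,
    Pedigree,
    Sample,
    Sex,
    VariantKey,
    Zygosity,
    build_pedigree,
    validate_panel,
)

__all__ = ["PaperFixture", "load_paper_fixture", "fixture_panel"]

AD = InheritanceMode.AD
AR = InheritanceMode.AR

_DEPTH, _GQ = 50, 99  # confirmed calls: comfortably above the quality gate


def fixture_panel() -> Panel:
    """The fixture's gene panel (a small PID panel, not the full 269)."""

    def entry(gene, modes, msc, tags, override=None):
        return PanelEntry(
            gene=gene,
            inheritance_modes=frozenset(modes),
            msc=msc,
            phenotype_tags=frozenset(tags),
            association_tier_override=override,
        )

    return validate_panel([
        entry("NFKB1", {AD}, 3.31,
              {"hypogammaglobulinemia", "autoimmune_cytopenia",
               "granulomatous_disease", "opportunistic_infections"}),
        entry("STAT3", {AD}, 15.0,
              {"autoimmune_cytopenia", "granulomatous_disease",
               "early_onset_autoimmunity"}),
        entry("CTLA4", {AD}, 18.0,
              {"autoimmune_cytopenia", "enteropathy", "low_B_cells"}),
        entry("PIK3CD", {AD}, 20.0,
              {"recurrent_sinopulmonary_infections", "lymphoid_hyperplasia",
               "enteropathy"}),
        entry("IKZF1", {AD}, 20.0,
              {"low_B_cells", "hypogammaglobulinemia",
               "recurrent_sinopulmonary_infections"}),
        entry("LRBA", {AR}, 28.0,
              {"granulomatous_disease", "autoimmune_cytopenia",
               "enteropathy"}),
        entry("STXBP2", {AR}, 20.0,
              {"hemophagocytosis", "ebv_susceptibility", "low_B_cells"}),
        entry("TNFRSF13B", {AD, AR}, 3.31,
              {"hypogammaglobulinemia"}, override="disease_associated"),
        entry("DOCK8", {AR}, 20.0,
              {"eczema", "recurrent_viral_infections"}),
        entry("CIITA", {AR}, 20.0, {"mhc_class_II_deficiency"}),
        entry("FASLG", {AR}, 20.0, {"lymphoproliferation"}),
    ])


# (gene, transcript, pos, ref, alt, hgvs_c, hgvs_p, cadd, exac_af, hgmd)
_VARIANTS = [
    ("NFKB1", "NM_003998.3", 1000, "G", "A", "c.1301-1G>A", None,
     24.0, None, False),
    ("NFKB1", "NM_003998.3", 2000, "A", "G", "c.259-4A>G", None,
     9.635, 0.000008256, False),
    ("NFKB1", "NM_003998.3", 3000, "T", "A", "c.957T>A", "p.Y319*",
     36.0, None, False),
    ("NFKB1", "NM_003998.3", 4000, "CT", "C", "c.1375delT", "p.F459Lfs*26",
     23.2, None, False),
    ("STAT3", "NM_139276.2", 1000, "G", "A", "c.737G>A", "p.R246Q",
     33.0, None, False),
    ("STAT3", "NM_139276.2", 2000, "T", "C", "c.937T>C", "p.F313L",
     16.66, None, False),
    ("STAT3", "NM_139276.2", 3000, "C", "T", "c.307C>T", "p.R103W",
     34.0, None, False),
    ("CTLA4", "NM_005214.4", 1000, "A", "ACTGG", "c.56_57insCTGG",
     "p.T19Tfs*42", 19.5, None, False),
    ("CTLA4", "NM_005214.4", 2000, "C", "G", "c.406C>G", "p.P136A",
     23.8, None, False),
    ("PIK3CD", "NM_005026.3", 1000, "G", "A", "c.3061G>A", "p.E1021K",
     31.0, None, True),
    ("IKZF1", "NM_006060.5", 1000, "G", "A", "c.551G>A", "p.R184Q",
     27.9, None, False),
    ("LRBA", "NM_006726.4", 1000, "A", "G", "c.1399A>G", "p.M467V",
     19.0, 0.002165, False),
    ("LRBA", "NM_006726.4", 2000, "C", "G", "c.8351C>G", "p.A2784G",
     25.7, None, False),
    ("LRBA", "NM_006726.4", 3000, "G", "A", "c.2674G>A", "p.A892T",
     24.4, 0.001532, False),
    ("LRBA", "NM_006726.4", 4000, "T", "C", "c.6695T>C", "p.I2232T",
     27.9, 0.0002160, False),
    ("STXBP2", "NM_006949.3", 1000, "TACGTACGTAC", "TGA",
     "c.474_483delinsGA", "p.C158Wfs*78", 33.0, None, True),
    ("STXBP2", "NM_006949.3", 2000, "C", "T", "c.1001C>T", "p.P334L",
     23.4, 0.00004944, True),
]

# proband -> list of hgvs_c carried (het)
_PROBAND_VARIANTS = {
    "P01": ["c.1301-1G>A"],
    "P02": ["c.1301-1G>A"],
    "P03": ["c.259-4A>G"],
    "P04": ["c.957T>A"],
    "P05": ["c.1375delT"],
    "P06": ["c.737G>A"],
    "P07": ["c.937T>C"],
    "P08": ["c.307C>T"],
    "P09": ["c.56_57insCTGG"],
    "P10": ["c.406C>G"],
    "P11": ["c.3061G>A"],
    "P12": ["c.551G>A"],
    "P13": ["c.1399A>G", "c.8351C>G"],
    "P14": ["c.2674G>A", "c.6695T>C"],
    "P15": ["c.474_483delinsGA", "c.1001C>T"],
}

_PROBAND_TAGS = {
    "P01": {"hypogammaglobulinemia", "granulomatous_disease",
            "opportunistic_infections"},
    "P02": {"hypogammaglobulinemia", "autoimmune_cytopenia"},
    "P03": {"hypogammaglobulinemia"},
    "P04": {"hypogammaglobulinemia", "autoimmune_cytopenia",
            "opportunistic_infections"},
    "P05": {"hypogammaglobulinemia", "opportunistic_infections"},
    "P06": {"autoimmune_cytopenia", "granulomatous_disease"},
    "P07": {"autoimmune_cytopenia", "early_onset_autoimmunity"},
    "P08": {"autoimmune_cytopenia", "granulomatous_disease"},
    "P09": {"autoimmune_cytopenia", "enteropathy", "low_B_cells"},
    "P10": {"autoimmune_cytopenia", "granulomatous_disease"},
    "P11": {"recurrent_sinopulmonary_infections", "enteropathy",
            "lymphoid_hyperplasia"},
    "P12": {"low_B_cells", "hypogammaglobulinemia",
            "recurrent_sinopulmonary_infections"},
    "P13": {"granulomatous_disease", "autoimmune_cytopenia"},
    "P14": {"granulomatous_disease", "autoimmune_cytopenia"},
    "P15": {"ebv_susceptibility", "low_B_cells"},
}

_PROBAND_SEX = {
    "P01": Sex.MALE, "P02": Sex.FEMALE, "P03": Sex.MALE, "P04": Sex.FEMALE,
    "P05": Sex.FEMALE, "P06": Sex.FEMALE, "P07": Sex.MALE, "P08": Sex.FEMALE,
    "P09": Sex.FEMALE, "P10": Sex.MALE, "P11": Sex.FEMALE, "P12": Sex.FEMALE,
    "P13": Sex.FEMALE, "P14": Sex.MALE, "P15": Sex.MALE,
}


@dataclass
class PaperFixture:
    """The reconstructed published cohort, ready for the pipeline."""

    callset: CallSet
    samples: list[Sample]
    pedigree: Pedigree
    panel: Panel


def _het(callset, sid, key):
    callset.add_call(GenotypeCall(sid, key, Zygosity.HET, _DEPTH, _GQ))


def _ref(callset, sid, key):
    callset.add_call(GenotypeCall(sid, key, Zygosity.HOM_REF, _DEPTH, _GQ))


def load_paper_fixture() -> PaperFixture:
    """Build the published-tables fixture cohort.

    Family structures encode the reported segregation facts:

    * P01/P02 — second cousins sharing the NFKB1 c.1301-1G>A splice
      variant (one extended family, no shared recorded parents);
    * P06, P10 — de novo (trio, both parents reference);
    * P07 — variant inherited from his unaffected father;
    * P08 — variant shared with unaffected mother and two siblings;
    * P09 — variant shared with her asymptomatic mother;
    * P12 — variant shared with her mildly hypogammaglobulinemic mother;
    * P13–P15 — compound heterozygotes, one variant from each parent.
    """
    callset = CallSet(provenance={"source": "packaged study fixture"})
    key_by_hgvs: dict[str, VariantKey] = {}
    for gene, tx, pos, ref, alt, hgvs_c, hgvs_p, cadd, af, hgmd in _VARIANTS:
        v = AnnotatedVariant(
            chrom=gene, pos=pos, ref=ref, alt=alt, gene=gene, transcript=tx,
            hgvs_c=hgvs_c, hgvs_p=hgvs_p, cadd_scaled=cadd, exac_af=af,
            hgmd_known=hgmd,
        )
        callset.add_variant(v)
        key_by_hgvs[hgvs_c] = v.key

    samples: list[Sample] = []

    def add_sample(sid, family, sex=Sex.UNKNOWN,
                   affected=AffectedStatus.UNAFFECTED,
                   mother=None, father=None, tags=frozenset()):
        samples.append(Sample(
            sample_id=sid, sex=sex, affected=affected, mother_id=mother,
            father_id=father, phenotype_tags=frozenset(tags),
            family_id=family))

    def add_proband(sid, family, mother=None, father=None):
        add_sample(sid, family, _PROBAND_SEX[sid], AffectedStatus.AFFECTED,
                   mother, father, _PROBAND_TAGS[sid])
        for hgvs in _PROBAND_VARIANTS[sid]:
            _het(callset, sid, key_by_hgvs[hgvs])

    # second cousins: same extended family, no shared recorded parents
    add_proband("P01", "F01")
    add_proband("P02", "F01")

    for sid in ("P03", "P04", "P05", "P11"):
        add_proband(sid, f"F{sid[1:]}")

    # de novo trios: both parents homozygous reference
    for sid in ("P06", "P10"):
        fam = f"F{sid[1:]}"
        add_sample(f"{sid}_M", fam, Sex.FEMALE)
        add_sample(f"{sid}_F", fam, Sex.MALE)
        add_proband(sid, fam, mother=f"{sid}_M", father=f"{sid}_F")
        key = key_by_hgvs[_PROBAND_VARIANTS[sid][0]]
        _ref(callset, f"{sid}_M", key)
        _ref(callset, f"{sid}_F", key)

    # P07: inherited from unaffected father
    add_sample("P07_M", "F07", Sex.FEMALE)
    add_sample("P07_F", "F07", Sex.MALE)
    add_proband("P07", "F07", mother="P07_M", father="P07_F")
    _ref(callset, "P07_M", key_by_hgvs["c.937T>C"])
    _het(callset, "P07_F", key_by_hgvs["c.937T>C"])

    # P08: unaffected carrier mother and two unaffected carrier siblings
    add_sample("P08_M", "F08", Sex.FEMALE)
    add_proband("P08", "F08", mother="P08_M")
    add_sample("P08_S1", "F08", Sex.FEMALE, mother="P08_M")
    add_sample("P08_S2", "F08", Sex.MALE, mother="P08_M")
    for rid in ("P08_M", "P08_S1", "P08_S2"):
        _het(callset, rid, key_by_hgvs["c.307C>T"])

    # P09: asymptomatic carrier mother
    add_sample("P09_M", "F09", Sex.FEMALE)
    add_proband("P09", "F09", mother="P09_M")
    _het(callset, "P09_M", key_by_hgvs["c.56_57insCTGG"])

    # P12: mildly affected carrier mother (variable expressivity)
    add_sample("P12_M", "F12", Sex.FEMALE,
               affected=AffectedStatus.MILDLY_AFFECTED)
    add_proband("P12", "F12", mother="P12_M")
    _het(callset, "P12_M", key_by_hgvs["c.551G>A"])

    # compound-heterozygous trios: first variant maternal, second paternal
    for sid in ("P13", "P14", "P15"):
        fam = f"F{sid[1:]}"
        add_sample(f"{sid}_M", fam, Sex.FEMALE)
        add_sample(f"{sid}_F", fam, Sex.MALE)
        add_proband(sid, fam, mother=f"{sid}_M", father=f"{sid}_F")
        k1, k2 = (key_by_hgvs[h] for h in _PROBAND_VARIANTS[sid])
        _het(callset, f"{sid}_M", k1)
        _ref(callset, f"{sid}_M", k2)
        _ref(callset, f"{sid}_F", k1)
        _het(callset, f"{sid}_F", k2)

    # the undiagnosed remainder: 35 affected patients with no panel variant
    for i in range(16, 51):
        add_sample(f"P{i:02d}", f"F{i:02d}",
                   affected=AffectedStatus.AFFECTED,
                   tags={"hypogammaglobulinemia"})

    pedigree = build_pedigree(samples)
    return PaperFixture(
        callset=callset, samples=samples, pedigree=pedigree,
        panel=fixture_panel(),
    )
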