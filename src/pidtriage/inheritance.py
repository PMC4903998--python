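"""Inheritance analysis: candidate grouping, trio phasing, segregation.

Surviving calls are grouped per (patient, gene) under a monoallelic or
biallelic hypothesis.  For biallelic candidates with two or more
heterozygous variants, phase is resolved through parental genotypes: if
one variant is traceable to each parent the pair is in trans (a true
compound heterozygote); if all variants come from one parent they are in
cis and the candidate dissolves into monoallelic groups; with an
ungenotyped parent the phase stays unknown.  Monoallelic candidates are
checked for de novo origin, and every candidate is annotated with
segregation evidence from genotyped relatives (incomplete penetrance,
variable expressivity, co-segregation with disease).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum

from .io import CallSet
from .models import (
    AffectedStatus,
    GenotypeCall,
    InheritanceMode,
    Panel,
    Pedigree,
    VariantKey,
    Zygosity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GroupHypothesis",
    "SegregationFlag",
    "CandidateGroup",
    "group_candidates",
    "phase_compound_het",
    "detect_de_novo",
    "assess_segregation",
    "analyze_candidates",
]


class GroupHypothesis(str, Enum):
    MONOALLELIC = "monoallelic"
    BIALLELIC_HOM = "biallelic_hom"
    BIALLELIC_COMPHET = "biallelic_comphet"
    BIALLELIC_UNPHASED = "biallelic_unphased"

    @property
    def biallelic(self) -> bool:
        return self is not GroupHypothesis.MONOALLELIC


class SegregationFlag(str, Enum):
    DE_NOVO = "de_novo"
    INHERITED_UNAFFECTED_PARENT = "inherited_unaffected_parent"
    INCOMPLETE_PENETRANCE = "incomplete_penetrance"
    VARIABLE_EXPRESSIVITY = "variable_expressivity"
    SEGREGATES_WITH_DISEASE = "segregates_with_disease"
    PHASE_UNKNOWN = "phase_unknown"


@dataclass(frozen=True)
class CandidateGroup:
    """One patient's candidate genotype in one gene."""

    patient_id: str
    gene: str
    hypothesis: GroupHypothesis
    variant_keys: tuple[VariantKey, ...]
    segregation: frozenset[SegregationFlag] = field(default_factory=frozenset)
    carrier_relatives: tuple[tuple[str, AffectedStatus], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.variant_keys)
        if self.hypothesis in (GroupHypothesis.MONOALLELIC,
                               GroupHypothesis.BIALLELIC_HOM):
            assert n == 1, f"{self.hypothesis} requires exactly 1 variant"
        else:
            assert n >= 2, f"{self.hypothesis} requires >=2 variants"

    def with_flags(self, *flags: SegregationFlag) -> "CandidateGroup":
        return replace(self, segregation=self.segregation | set(flags))


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def group_candidates(
    survivors: dict[str, list[GenotypeCall]],
    panel: Panel,
    variants: dict[VariantKey, "object"],
) -> list[CandidateGroup]:
    """Group surviving calls per (patient, gene) into candidate hypotheses.

    hom_alt → biallelic_hom (one group per hom_alt call); two or more het
    calls in a gene that can act recessively → one unphased biallelic
    candidate (phase resolved later); every other het call → its own
    monoallelic group.  Every surviving call lands in exactly one group.
    """
    groups: list[CandidateGroup] = []
    for pid in survivors:
        by_gene: dict[str, list[GenotypeCall]] = {}
        for c in survivors[pid]:
            gene = variants[c.variant_key].gene
            by_gene.setdefault(gene, []).append(c)
        for gene in sorted(by_gene):
            calls = sorted(by_gene[gene], key=lambda c: c.variant_key)
            homs = [c for c in calls if c.zygosity is Zygosity.HOM_ALT]
            hets = [c for c in calls if c.zygosity is Zygosity.HET]
            for c in homs:
                groups.append(CandidateGroup(
                    pid, gene, GroupHypothesis.BIALLELIC_HOM,
                    (c.variant_key,)))
            entry = panel.get(gene)
            if len(hets) >= 2 and entry is not None and entry.ar_capable:
                groups.append(CandidateGroup(
                    pid, gene, GroupHypothesis.BIALLELIC_UNPHASED,
                    tuple(c.variant_key for c in hets)))
            else:
                for c in hets:
                    groups.append(CandidateGroup(
                        pid, gene, GroupHypothesis.MONOALLELIC,
                        (c.variant_key,)))
    return groups


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

def _genotyped(call: GenotypeCall | None) -> bool:
    return call is not None and call.zygosity is not Zygosity.MISSING


def _carries(call: GenotypeCall | None) -> bool:
    return call is not None and call.zygosity.carries_alt()


def phase_compound_het(
    group: CandidateGroup,
    pedigree: Pedigree,
    calls: CallSet,
) -> list[CandidateGroup]:
    """Resolve phase of a multi-het candidate through parental genotypes.

    Enumerates parental-origin assignments (each variant to a carrier
    parent).  If every consistent assignment draws on both parents the
    variants are in trans → ``biallelic_comphet``.  If every consistent
    assignment uses a single parent they are in cis → the group dissolves
    into monoallelic groups.  Ambiguous configurations (both parents carry
    the same variants), an ungenotyped parent, or a Mendelian
    inconsistency (a variant absent from both genotyped parents) leave the
    candidate ``biallelic_unphased`` with the ``phase_unknown`` flag.
    """
    assert len(group.variant_keys) >= 2
    sample = pedigree.get(group.patient_id)
    mother, father = sample.mother_id, sample.father_id
    if mother is None or father is None:
        return [group.with_flags(SegregationFlag.PHASE_UNKNOWN)]

    origins: list[set[str]] = []
    for key in group.variant_keys:
        m_call = calls.call(mother, key)
        f_call = calls.call(father, key)
        if not (_genotyped(m_call) and _genotyped(f_call)):
            return [group.with_flags(SegregationFlag.PHASE_UNKNOWN)]
        possible = set()
        if _carries(m_call):
            possible.add(mother)
        if _carries(f_call):
            possible.add(father)
        if not possible:
            logger.warning(
                "Mendelian inconsistency: %s %s absent from both genotyped "
                "parents; leaving phase unknown",
                group.patient_id, key)
            return [group.with_flags(SegregationFlag.PHASE_UNKNOWN)]
        origins.append(possible)

    # all consistent assignments: choose one origin parent per variant
    def assignments(i: int, used: tuple[str, ...]):
        if i == len(origins):
            yield used
            return
        for p in sorted(origins[i]):
            yield from assignments(i + 1, used + (p,))

    both, single = False, False
    for a in assignments(0, ()):
        if len(set(a)) >= 2:
            both = True
        else:
            single = True
    if both and not single:
        return [replace(group, hypothesis=GroupHypothesis.BIALLELIC_COMPHET)]
    if single and not both:
        # cis: both variants on one haplotype — not a biallelic mechanism
        return [
            CandidateGroup(group.patient_id, group.gene,
                           GroupHypothesis.MONOALLELIC, (key,),
                           segregation=group.segregation)
            for key in group.variant_keys
        ]
    return [group.with_flags(SegregationFlag.PHASE_UNKNOWN)]


# ---------------------------------------------------------------------------
# De novo detection and segregation
# ---------------------------------------------------------------------------

def detect_de_novo(
    group: CandidateGroup,
    pedigree: Pedigree,
    calls: CallSet,
) -> CandidateGroup:
    """Flag de novo origin or transmission from an unaffected parent.

    ``de_novo`` requires the proband heterozygous and both parents
    genotyped homozygous-reference; with only one genotyped parent
    transmission cannot be excluded and no flag is set.  When a genotyped
    parent carries the variant and is unaffected, the group is flagged
    ``inherited_unaffected_parent`` instead (the two flags are mutually
    exclusive by construction).
    """
    assert group.hypothesis is GroupHypothesis.MONOALLELIC
    sample = pedigree.get(group.patient_id)
    key = group.variant_keys[0]
    proband = calls.call(group.patient_id, key)
    if proband is None or proband.zygosity is not Zygosity.HET:
        return group
    parent_calls = {
        pid: calls.call(pid, key)
        for pid in (sample.mother_id, sample.father_id)
        if pid is not None
    }
    carriers = [pid for pid, c in parent_calls.items() if _carries(c)]
    for pid in carriers:
        if pedigree.get(pid).affected is AffectedStatus.UNAFFECTED:
            return group.with_flags(
                SegregationFlag.INHERITED_UNAFFECTED_PARENT)
    if (
        len(parent_calls) == 2
        and all(
            _genotyped(c) and c.zygosity is Zygosity.HOM_REF
            for c in parent_calls.values()
        )
    ):
        return group.with_flags(SegregationFlag.DE_NOVO)
    return group


def _carries_pattern(
    sample_id: str, group: CandidateGroup, calls: CallSet
) -> bool:
    """Does this sample carry the group's full genotype pattern?

    Monoallelic: carries the variant.  Homozygous biallelic: homozygous for
    it.  Compound-het/unphased: carries every variant of the group.
    """
    if group.hypothesis is GroupHypothesis.BIALLELIC_HOM:
        c = calls.call(sample_id, group.variant_keys[0])
        return c is not None and c.zygosity is Zygosity.HOM_ALT
    return all(
        _carries(calls.call(sample_id, key)) for key in group.variant_keys
    )


def assess_segregation(
    group: CandidateGroup,
    pedigree: Pedigree,
    calls: CallSet,
) -> CandidateGroup:
    """Annotate the group with carrier relatives and segregation flags.

    * ``incomplete_penetrance`` — an unaffected relative carries the full
      genotype pattern;
    * ``variable_expressivity`` — a mildly affected relative carries it;
    * ``segregates_with_disease`` — at least one genotyped affected
      relative exists, every genotyped affected relative carries the
      pattern, and no genotyped unaffected relative does.
    """
    carrier_relatives: list[tuple[str, AffectedStatus]] = []
    flags: set[SegregationFlag] = set()
    affected_rel, affected_carrier, unaffected_carrier = 0, 0, False
    for rid in sorted(pedigree.relatives(group.patient_id)):
        genotyped = all(
            _genotyped(calls.call(rid, key)) for key in group.variant_keys
        )
        if not genotyped:
            continue
        status = pedigree.get(rid).affected
        carries = _carries_pattern(rid, group, calls)
        if carries:
            carrier_relatives.append((rid, status))
        if status is AffectedStatus.AFFECTED:
            affected_rel += 1
            if carries:
                affected_carrier += 1
        elif status is AffectedStatus.UNAFFECTED and carries:
            unaffected_carrier = True
            flags.add(SegregationFlag.INCOMPLETE_PENETRANCE)
        if status is AffectedStatus.MILDLY_AFFECTED and carries:
            flags.add(SegregationFlag.VARIABLE_EXPRESSIVITY)
    if affected_rel > 0 and affected_carrier == affected_rel \
            and not unaffected_carrier:
        flags.add(SegregationFlag.SEGREGATES_WITH_DISEASE)
    out = replace(group, carrier_relatives=tuple(carrier_relatives))
    return out.with_flags(*flags) if flags else out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def analyze_candidates(
    survivors: dict[str, list[GenotypeCall]],
    panel: Panel,
    pedigree: Pedigree,
    callset: CallSet,
) -> list[CandidateGroup]:
    """Group, phase, de-novo-check and segregation-annotate survivors."""
    resolved: list[CandidateGroup] = []
    for group in group_candidates(survivors, panel, callset.variants):
        if group.hypothesis is GroupHypothesis.BIALLELIC_UNPHASED:
            resolved.extend(phase_compound_het(group, pedigree, callset))
        else:
            resolved.append(group)
    out = []
    for group in resolved:
        if group.hypothesis is GroupHypothesis.MONOALLELIC:
            group = detect_de_novo(group, pedigree, callset)
        group = assess_segregation(group, pedigree, callset)
        out.append(group)
    return out
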