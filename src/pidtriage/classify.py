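"""Tier assignment and cohort-level summary statistics.

A candidate group is *likely disease-causing* only when its zygosity
hypothesis is compatible with the gene's published inheritance modes
(monoallelic ↔ AD, biallelic ↔ AR, hemizygous/homozygous ↔ XL) **and** the
patient's phenotype matches the gene's.  Genes carrying an association-tier
override (e.g. TNFRSF13B, only weakly associated with CVID) are forced
into the *disease-associated* tier regardless.  Everything else that
survived the cascade is *other damaging*, with machine-readable reasons.
Known-published (HGMD) status is reported as evidence but never raises a
tier by itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .filters import CascadeResult, Hypothesis, Rarity, phenotype_match
from .io import CallSet
from .models import (
    AnnotatedVariant,
    FilterConfig,
    InheritanceMode,
    Panel,
    Pedigree,
    VariantKey,
    Zygosity,
)
from .inheritance import CandidateGroup, GroupHypothesis

__all__ = [
    "Tier",
    "ClassifiedFinding",
    "CohortSummary",
    "phenotype_match",
    "classify",
    "classify_all",
    "summarize_cohort",
]


class Tier(str, Enum):
    LIKELY_DISEASE_CAUSING = "likely_disease_causing"
    DISEASE_ASSOCIATED = "disease_associated"
    OTHER_DAMAGING = "other_damaging"
    EXCLUDED = "excluded"


_TIER_PRECEDENCE = {
    Tier.LIKELY_DISEASE_CAUSING: 0,
    Tier.DISEASE_ASSOCIATED: 1,
    Tier.OTHER_DAMAGING: 2,
    Tier.EXCLUDED: 3,
}


@dataclass(frozen=True)
class ClassifiedFinding:
    """A candidate group with its assigned tier and the reasons for it."""

    group: CandidateGroup
    tier: Tier
    reasons: tuple[str, ...]
    hgmd_support: bool
    variants: dict[VariantKey, AnnotatedVariant] = field(default_factory=dict)

    @property
    def patient_id(self) -> str:
        return self.group.patient_id

    @property
    def gene(self) -> str:
        return self.group.gene


def _mode_compatible(
    hypothesis: GroupHypothesis, modes: frozenset[InheritanceMode]
) -> bool:
    if hypothesis is GroupHypothesis.MONOALLELIC:
        return InheritanceMode.AD in modes
    if hypothesis is GroupHypothesis.BIALLELIC_HOM:
        # homozygous covers autosomal-recessive and hemizygous X-linked
        return bool(modes & {InheritanceMode.AR, InheritanceMode.XL})
    if hypothesis is GroupHypothesis.BIALLELIC_COMPHET:
        return InheritanceMode.AR in modes
    return False  # biallelic_unphased: phase unresolved, never top tier


def classify(
    group: CandidateGroup,
    panel: Panel,
    patient_tags: frozenset[str],
    callset: CallSet,
) -> ClassifiedFinding:
    """Assign one candidate group to a tier with auditable reasons."""
    entry = panel.get(group.gene)
    variants = {k: callset.variants[k] for k in group.variant_keys}
    hgmd = any(v.hgmd_known for v in variants.values())
    if entry is None:
        return ClassifiedFinding(group, Tier.EXCLUDED, ("off_panel",),
                                 hgmd, variants)
    if entry.association_tier_override is not None:
        return ClassifiedFinding(
            group, Tier(entry.association_tier_override),
            ("association_tier_override",), hgmd, variants)
    reasons: list[str] = []
    if group.hypothesis is GroupHypothesis.BIALLELIC_UNPHASED:
        reasons.append("phase_unknown")
    elif not _mode_compatible(group.hypothesis, entry.inheritance_modes):
        reasons.append("zygosity_mismatch")
    if not phenotype_match(patient_tags, entry):
        reasons.append("phenotype_mismatch")
    if not reasons:
        return ClassifiedFinding(group, Tier.LIKELY_DISEASE_CAUSING, (),
                                 hgmd, variants)
    return ClassifiedFinding(group, Tier.OTHER_DAMAGING, tuple(reasons),
                             hgmd, variants)


def classify_all(
    groups: list[CandidateGroup],
    panel: Panel,
    pedigree: Pedigree,
    callset: CallSet,
) -> list[ClassifiedFinding]:
    out = []
    for g in groups:
        tags = (
            pedigree.get(g.patient_id).phenotype_tags
            if g.patient_id in pedigree else frozenset()
        )
        out.append(classify(g, panel, tags, callset))
    return out


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level funnel and yield statistics.

    ``n_variants_total`` counts distinct panel-gene variants carried by
    patients after the quality gate (the top of the panel funnel);
    ``n_variants_private_or_rare`` those additionally passing the
    zygosity-dependent frequency exclusion.  ``diagnostic_yield`` is the
    fraction of patients with at least one likely-disease-causing finding.
    ``cadd_ge20_frac`` / ``cadd_ge30_frac`` are the fractions of scored
    private-or-rare variants in the top 1% / top 0.1% deleteriousness
    bands.  ``tier_breakdown`` assigns each patient to exactly one gene
    category, the highest tier taking precedence.
    """

    n_patients: int
    n_patients_with_panel_variant: int
    n_variants_total: int
    n_variants_private_or_rare: int
    n_unique_likely: int
    n_patients_likely: int
    diagnostic_yield: float
    tier_breakdown: dict[str, dict[str, int]]
    cadd_ge20_frac: Optional[float]
    cadd_ge30_frac: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_patients_with_panel_variant": self.n_patients_with_panel_variant,
            "n_variants_total": self.n_variants_total,
            "n_variants_private_or_rare": self.n_variants_private_or_rare,
            "n_unique_likely": self.n_unique_likely,
            "n_patients_likely": self.n_patients_likely,
            "diagnostic_yield": self.diagnostic_yield,
            "tier_breakdown": self.tier_breakdown,
            "cadd_ge20_frac": self.cadd_ge20_frac,
            "cadd_ge30_frac": self.cadd_ge30_frac,
        }


def summarize_cohort(
    findings: list[ClassifiedFinding],
    callset: CallSet,
    pedigree: Pedigree,
    panel: Panel,
    cfg: FilterConfig,
    cascade: Optional[CascadeResult] = None,
) -> CohortSummary:
    """Compute cohort funnel counts, per-gene breakdown and yield.

    A variant shared by related patients counts once in
    ``n_unique_likely`` (distinct identity keys).  Each patient appears in
    exactly one ``tier_breakdown`` category — their best tier, and within
    it the alphabetically first gene (multi-gene ties are rare).
    """
    patients = pedigree.affected_patients()
    n_patients = len(patients)

    # funnel: panel-gene variants carried by patients, post-quality
    from .filters import quality_filter  # local to avoid cycle at import

    panel_variant_keys: set[VariantKey] = set()
    rare_keys: set[VariantKey] = set()
    patients_with_panel: set[str] = set()
    for pid in patients:
        for c in callset.calls_for_sample(pid):
            if not c.zygosity.carries_alt():
                continue
            v = callset.variants[c.variant_key]
            if not (v.gene and v.gene in panel):
                continue
            if not quality_filter(c, cfg).passed:
                continue
            patients_with_panel.add(pid)
            panel_variant_keys.add(c.variant_key)
            threshold = (
                cfg.biallelic_af_max
                if c.zygosity is Zygosity.HOM_ALT
                else cfg.het_af_max
            )
            if v.exac_af is None or v.exac_af <= threshold:
                rare_keys.add(c.variant_key)
    # survivors of the full cascade are rare under their routed hypothesis
    if cascade is not None:
        for c in cascade.survivor_calls():
            rare_keys.add(c.variant_key)

    likely = [f for f in findings if f.tier is Tier.LIKELY_DISEASE_CAUSING]
    unique_likely = {k for f in likely for k in f.group.variant_keys}
    patients_likely = {f.patient_id for f in likely}

    # one category per patient: best tier wins, then gene name
    best: dict[str, tuple[int, str]] = {}
    for f in findings:
        rank = (_TIER_PRECEDENCE[f.tier], f.gene)
        if f.patient_id not in best or rank < best[f.patient_id]:
            best[f.patient_id] = rank
    _tier_by_rank = {r: t for t, r in _TIER_PRECEDENCE.items()}
    breakdown: dict[str, dict[str, int]] = {}
    for rank, gene in best.values():
        tier = _tier_by_rank[rank]
        breakdown.setdefault(tier.value, {})
        breakdown[tier.value][gene] = breakdown[tier.value].get(gene, 0) + 1

    scored = [
        callset.variants[k].cadd_scaled
        for k in rare_keys
        if callset.variants[k].cadd_scaled is not None
    ]
    ge20 = (
        sum(1 for s in scored if s >= cfg.cadd_benign_scaled) / len(scored)
        if scored else None
    )
    ge30 = (
        sum(1 for s in scored if s >= cfg.cadd_strong_scaled) / len(scored)
        if scored else None
    )

    return CohortSummary(
        n_patients=n_patients,
        n_patients_with_panel_variant=len(patients_with_panel),
        n_variants_total=len(panel_variant_keys),
        n_variants_private_or_rare=len(rare_keys),
        n_unique_likely=len(unique_likely),
        n_patients_likely=len(patients_likely),
        diagnostic_yield=(
            len(patients_likely) / n_patients if n_patients else 0.0
        ),
        tier_breakdown=breakdown,
        cadd_ge20_frac=ge20,
        cadd_ge30_frac=ge30,
    )
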