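"""The exclusion cascade: quality, panel, frequency, CADD/MSC gates.

Stages run in a fixed order — per-call quality, gene-panel membership,
zygosity-dependent population-frequency exclusion, then the gene-specific
CADD deleteriousness gate — and every removal is recorded as an auditable
:class:`FilterDecision`, so that ``|input| == |survivors| + |failures|``
holds per stage and overall.

The frequency stage is hypothesis-dependent: a variant examined under a
monoallelic (dominant) hypothesis is held to a much stricter allele-
frequency ceiling (default 0.01%) than under a biallelic (recessive)
hypothesis (default 1%).  The hypothesis is routed from the patient's
observed zygosity pattern in the gene: a homozygous-alt call, or two or
more heterozygous calls in a gene that can act recessively, selects the
biallelic threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .io import CallSet
from .models import (
    AnnotatedVariant,
    DataError,
    FilterConfig,
    GenotypeCall,
    Panel,
    PanelEntry,
    Pedigree,
    Zygosity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "Hypothesis",
    "Rarity",
    "FilterDecision",
    "CascadeResult",
    "quality_filter",
    "panel_filter",
    "frequency_filter",
    "cadd_msc_gate",
    "phenotype_match",
    "route_hypotheses",
    "run_cascade",
]


class Stage(str, Enum):
    QUALITY = "quality"
    PANEL = "panel"
    FREQUENCY = "frequency"
    CADD_MSC = "cadd_msc"


class Hypothesis(str, Enum):
    MONOALLELIC = "monoallelic"
    BIALLELIC = "biallelic"


class Rarity(str, Enum):
    NOVEL = "novel"      # never observed in the reference population
    RARE = "rare"        # observed, at or below the governing threshold
    COMMON = "common"    # above the governing threshold


@dataclass(frozen=True)
class FilterDecision:
    """One auditable pass/fail decision for a call or variant."""

    subject: str
    stage: Stage
    passed: bool
    reason: str
    hypothesis: Optional[Hypothesis] = None

    def __post_init__(self) -> None:
        if not self.passed and not self.reason:
            raise DataError("failed decision requires a reason")


def _subject(call: GenotypeCall) -> str:
    return f"{call.sample_id}:{call.variant_key}"


# ---------------------------------------------------------------------------
# Individual gates
# ---------------------------------------------------------------------------

def quality_filter(call: GenotypeCall, cfg: FilterConfig) -> FilterDecision:
    """Remove poorly supported calls.

    A call fails when its read depth is at or below
    ``cfg.min_depth_exclusive`` or its Phred-scaled quality at or below
    ``cfg.min_gq_exclusive`` (either condition suffices under the default
    ``or`` connective; ``and`` requires both).  Calls with absent DP/GQ
    pass — absence of quality metadata is not evidence of a bad call.
    """
    low_depth = call.depth is not None and call.depth <= cfg.min_depth_exclusive
    low_gq = call.gq is not None and call.gq <= cfg.min_gq_exclusive
    if cfg.quality_connective == "and":
        failed = low_depth and low_gq
    else:
        failed = low_depth or low_gq
    if failed:
        reasons = []
        if low_depth:
            reasons.append(f"depth<={cfg.min_depth_exclusive:g}")
        if low_gq:
            reasons.append(f"gq<={cfg.min_gq_exclusive:g}")
        return FilterDecision(_subject(call), Stage.QUALITY, False,
                              ",".join(reasons))
    return FilterDecision(_subject(call), Stage.QUALITY, True, "ok")


def panel_filter(variant: AnnotatedVariant, panel: Panel) -> FilterDecision:
    """Keep only variants in panel genes (case-insensitive symbol match)."""
    if variant.gene and variant.gene in panel:
        return FilterDecision(str(variant.key), Stage.PANEL, True, "ok")
    return FilterDecision(str(variant.key), Stage.PANEL, False, "off_panel")


def frequency_filter(
    variant: AnnotatedVariant,
    hypothesis: Hypothesis,
    cfg: FilterConfig,
) -> tuple[FilterDecision, Rarity]:
    """Exclude variants too common for the inheritance hypothesis.

    Absent population frequency means the variant is novel and passes under
    either hypothesis.  A present frequency passes (label ``rare``) when it
    is at or below the governing threshold — ``het_af_max`` for the
    monoallelic hypothesis, ``biallelic_af_max`` for the biallelic one —
    and fails (label ``common``) above it.
    """
    if variant.exac_af is None:
        return (
            FilterDecision(str(variant.key), Stage.FREQUENCY, True, "novel",
                           hypothesis),
            Rarity.NOVEL,
        )
    threshold = (
        cfg.het_af_max if hypothesis is Hypothesis.MONOALLELIC
        else cfg.biallelic_af_max
    )
    if variant.exac_af <= threshold:
        return (
            FilterDecision(str(variant.key), Stage.FREQUENCY, True, "rare",
                           hypothesis),
            Rarity.RARE,
        )
    return (
        FilterDecision(
            str(variant.key), Stage.FREQUENCY, False,
            f"af={variant.exac_af:g}>{threshold:g}", hypothesis),
        Rarity.COMMON,
    )


def cadd_msc_gate(
    variant: AnnotatedVariant,
    entry: PanelEntry,
    phenotype_match: bool,
    cfg: FilterConfig,
) -> FilterDecision:
    """Gate on predicted deleteriousness versus the gene-specific MSC.

    Variants scoring at or above the gene's mutation significance cutoff
    pass.  A sub-MSC variant may still pass when the patient phenotype
    matches the gene's published presentation and the override is enabled
    (this reproduces the retention of sub-cutoff variants in genes whose
    clinical picture fits the patient).  Variants with no score, or genes
    with no cutoff, are not gated.
    """
    subject = str(variant.key)
    if variant.cadd_scaled is None or entry.msc is None:
        logger.debug("ungated (no CADD or no MSC) for %s", subject)
        return FilterDecision(subject, Stage.CADD_MSC, True, "ungated")
    if variant.cadd_scaled >= entry.msc:
        return FilterDecision(subject, Stage.CADD_MSC, True, "ok")
    if cfg.msc_override_enabled and phenotype_match:
        return FilterDecision(subject, Stage.CADD_MSC, True,
                              "msc_override_phenotype")
    return FilterDecision(
        subject, Stage.CADD_MSC, False,
        f"cadd={variant.cadd_scaled:g}<msc={entry.msc:g}")


def phenotype_match(patient_tags: frozenset[str], entry: PanelEntry) -> bool:
    """True iff the patient shares any controlled tag with the gene entry."""
    return bool(patient_tags & entry.phenotype_tags)


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    """Survivors and full decision log of one cascade run."""

    survivors: dict[str, list[GenotypeCall]]
    decisions: list[FilterDecision]
    hypotheses: dict[tuple[str, str], Hypothesis] = field(default_factory=dict)
    rarity: dict[tuple[str, ...], Rarity] = field(default_factory=dict)

    def survivor_calls(self) -> list[GenotypeCall]:
        return [c for calls in self.survivors.values() for c in calls]

    def failures(self) -> list[FilterDecision]:
        return [d for d in self.decisions if not d.passed]


def route_hypotheses(
    calls: list[GenotypeCall],
    variants: dict,
    panel: Panel,
) -> dict[str, Hypothesis]:
    """Choose the frequency hypothesis per gene from one patient's calls.

    hom_alt anywhere in the gene, or >=2 het calls in a gene that can act
    recessively, selects the biallelic threshold; anything else the
    monoallelic one.
    """
    by_gene: dict[str, list[GenotypeCall]] = {}
    for c in calls:
        gene = variants[c.variant_key].gene
        by_gene.setdefault(gene, []).append(c)
    out: dict[str, Hypothesis] = {}
    for gene, gcalls in by_gene.items():
        entry = panel.get(gene)
        has_hom = any(c.zygosity is Zygosity.HOM_ALT for c in gcalls)
        n_het = sum(1 for c in gcalls if c.zygosity is Zygosity.HET)
        if has_hom or (n_het >= 2 and entry is not None and entry.ar_capable):
            out[gene] = Hypothesis.BIALLELIC
        else:
            out[gene] = Hypothesis.MONOALLELIC
    return out


def run_cascade(
    callset: CallSet,
    pedigree: Pedigree,
    panel: Panel,
    cfg: FilterConfig,
    patient_ids: Optional[list[str]] = None,
) -> CascadeResult:
    """Run quality → panel → frequency → CADD/MSC over patients' calls.

    ``patient_ids`` defaults to the pedigree's affected samples.  Only
    alt-carrying calls enter the cascade (hom_ref / missing genotypes carry
    no candidate allele).  Relatives' genotypes are untouched here; the
    inheritance engine reads them from the original call set.
    """
    if patient_ids is None:
        patient_ids = pedigree.affected_patients()
    decisions: list[FilterDecision] = []
    survivors: dict[str, list[GenotypeCall]] = {}
    hypotheses: dict[tuple[str, str], Hypothesis] = {}
    rarity: dict[tuple[str, ...], Rarity] = {}

    for pid in patient_ids:
        calls = [
            c for c in callset.calls_for_sample(pid)
            if c.zygosity.carries_alt()
        ]
        calls.sort(key=lambda c: c.variant_key)

        # stage 1: per-call quality
        stage1 = []
        for c in calls:
            d = quality_filter(c, cfg)
            decisions.append(d)
            if d.passed:
                stage1.append(c)

        # stage 2: panel membership
        stage2 = []
        for c in stage1:
            v = callset.variants[c.variant_key]
            d = panel_filter(v, panel)
            decisions.append(FilterDecision(
                f"{pid}:{v.key}", d.stage, d.passed, d.reason))
            if d.passed:
                stage2.append(c)

        # stages 3+4: frequency (hypothesis-routed) and CADD/MSC.
        # The hypothesis is re-routed from the calls still under
        # consideration until a fixed point is reached, so the surviving
        # set is stable under re-running the cascade and independent of
        # the order of the two gates.
        patient_tags = (
            pedigree.get(pid).phenotype_tags if pid in pedigree
            else frozenset()
        )
        current = list(stage2)
        freq_decisions: dict[tuple, FilterDecision] = {}
        cadd_decisions: dict[tuple, FilterDecision] = {}
        while True:
            gene_hyp = route_hypotheses(current, callset.variants, panel)
            removed = []
            for c in current:
                v = callset.variants[c.variant_key]
                hyp = gene_hyp[v.gene]
                hypotheses[(pid, v.gene)] = hyp
                fd, label = frequency_filter(v, hyp, cfg)
                freq_decisions[tuple(v.key)] = FilterDecision(
                    f"{pid}:{v.key}", fd.stage, fd.passed, fd.reason,
                    fd.hypothesis)
                rarity[(pid,) + tuple(v.key)] = label
                entry = panel.get(v.gene)
                assert entry is not None  # guaranteed by the panel stage
                cd = cadd_msc_gate(
                    v, entry, phenotype_match(patient_tags, entry), cfg)
                cadd_decisions[tuple(v.key)] = FilterDecision(
                    f"{pid}:{v.key}", cd.stage, cd.passed, cd.reason)
                if not (fd.passed and cd.passed):
                    removed.append(c)
            if not removed:
                break
            gone = {c.variant_key for c in removed}
            current = [c for c in current if c.variant_key not in gone]

        # log one decision trail per call: the frequency decision, then the
        # CADD decision only for calls that passed frequency (stage order)
        for c in stage2:
            fd = freq_decisions[tuple(c.variant_key)]
            decisions.append(fd)
            if fd.passed:
                decisions.append(cadd_decisions[tuple(c.variant_key)])

        survivors[pid] = current

    return CascadeResult(survivors=survivors, decisions=decisions,
                         hypotheses=hypotheses, rarity=rarity)
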