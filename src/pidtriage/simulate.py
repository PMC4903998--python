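"""Seeded synthetic-cohort generator with planted scenarios and decoys.

Generates a fully annotated cohort — call set, pedigree, phenotype tags and
a truth table — in which each planted scenario realises one inheritance
configuration the pipeline must recover (de novo dominant, recessive
homozygous, true compound heterozygote, a cis pair masquerading as one,
an association-only gene) or one failure mode a specific cascade stage
must remove (too common, sub-MSC, off panel, low quality).  Background
variants emulate exome noise in non-panel genes, with allele frequencies
drawn log-uniformly and CADD scores uniformly.

Everything is driven by one integer seed; identical configurations produce
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .classify import ClassifiedFinding, Tier
from .io import (
    CallSet,
    write_ped,
    write_phenotypes,
    write_panel,
    write_sidecar,
    write_vcf,
)
from .models import (
    AffectedStatus,
    AnnotatedVariant,
    DataError,
    FilterConfig,
    GenotypeCall,
    InheritanceMode,
    Panel,
    Pedigree,
    Sample,
    Sex,
    VariantKey,
    Zygosity,
    build_pedigree,
)
from .inheritance import GroupHypothesis

__all__ = [
    "ScenarioKind",
    "ScenarioSpec",
    "CohortConfig",
    "TruthRecord",
    "SimulatedCohort",
    "RecoveryReport",
    "default_cohort_config",
    "generate_cohort",
    "recovery_report",
]

_BASES = ("A", "C", "G", "T")


class ScenarioKind(str, Enum):
    AD_DE_NOVO = "AD_de_novo"
    AD_INHERITED_PENETRANT = "AD_inherited_penetrant"
    AD_INCOMPLETE_PENETRANCE = "AD_incomplete_penetrance"
    AR_HOMOZYGOUS = "AR_homozygous"
    AR_COMPOUND_HET = "AR_compound_het"
    CIS_FALSE_COMPHET = "cis_false_comphet"
    TACI_ASSOCIATED = "TACI_associated"
    DECOY_COMMON = "decoy_common"
    DECOY_LOW_CADD = "decoy_low_cadd"
    DECOY_OFF_PANEL = "decoy_off_panel"
    DECOY_LOW_QUALITY = "decoy_low_quality"


_CAUSAL_KINDS = {
    ScenarioKind.AD_DE_NOVO,
    ScenarioKind.AD_INHERITED_PENETRANT,
    ScenarioKind.AD_INCOMPLETE_PENETRANCE,
    ScenarioKind.AR_HOMOZYGOUS,
    ScenarioKind.AR_COMPOUND_HET,
}
_AR_KINDS = {
    ScenarioKind.AR_HOMOZYGOUS,
    ScenarioKind.AR_COMPOUND_HET,
    ScenarioKind.CIS_FALSE_COMPHET,
}
_TRIO_KINDS = _CAUSAL_KINDS | {ScenarioKind.CIS_FALSE_COMPHET}

_INTENDED_TIER = {
    **{k: Tier.LIKELY_DISEASE_CAUSING for k in _CAUSAL_KINDS},
    ScenarioKind.TACI_ASSOCIATED: Tier.DISEASE_ASSOCIATED,
    ScenarioKind.CIS_FALSE_COMPHET: Tier.OTHER_DAMAGING,
    ScenarioKind.DECOY_COMMON: Tier.EXCLUDED,
    ScenarioKind.DECOY_LOW_CADD: Tier.EXCLUDED,
    ScenarioKind.DECOY_OFF_PANEL: Tier.EXCLUDED,
    ScenarioKind.DECOY_LOW_QUALITY: Tier.EXCLUDED,
}

_INTENDED_HYPOTHESIS = {
    ScenarioKind.AD_DE_NOVO: GroupHypothesis.MONOALLELIC,
    ScenarioKind.AD_INHERITED_PENETRANT: GroupHypothesis.MONOALLELIC,
    ScenarioKind.AD_INCOMPLETE_PENETRANCE: GroupHypothesis.MONOALLELIC,
    ScenarioKind.AR_HOMOZYGOUS: GroupHypothesis.BIALLELIC_HOM,
    ScenarioKind.AR_COMPOUND_HET: GroupHypothesis.BIALLELIC_COMPHET,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """How many patients receive one scenario kind, and its parameters.

    ``af_range`` is the sampling interval for the planted variant's
    population allele frequency (``None`` → novel, never observed);
    ``cadd_range`` for its CADD-scaled score.
    """

    kind: ScenarioKind
    count: int
    af_range: Optional[tuple[float, float]] = None
    cadd_range: tuple[float, float] = (30.0, 40.0)

    def __post_init__(self) -> None:
        if self.count < 0:
            raise DataError(f"{self.kind}: count must be >= 0")
        if self.af_range is not None:
            lo, hi = self.af_range
            if not (0.0 < lo <= hi <= 1.0):
                raise DataError(f"{self.kind}: af_range outside (0,1]")
        lo, hi = self.cadd_range
        if not (0.0 <= lo <= hi):
            raise DataError(f"{self.kind}: invalid cadd_range")


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort."""

    panel: Panel
    n_patients: int = 50
    n_familial: int = 8
    seed: int = 0
    scenarios: tuple[ScenarioSpec, ...] = ()
    background_variants_per_patient: int = 5
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise DataError("n_patients must be >= 1")
        if not (0 <= self.n_familial <= self.n_patients):
            raise DataError("require 0 <= n_familial <= n_patients")
        total = sum(s.count for s in self.scenarios)
        if total > self.n_patients:
            raise DataError(
                f"{total} scenario instances exceed {self.n_patients} patients")
        cfg = self.filter_config
        for s in self.scenarios:
            if s.kind is ScenarioKind.DECOY_COMMON and s.af_range is not None \
                    and s.af_range[0] <= cfg.biallelic_af_max:
                raise DataError(
                    "decoy_common af_range must lie strictly above the "
                    "biallelic frequency threshold")


@dataclass(frozen=True)
class TruthRecord:
    """What was planted for one patient in one gene, and the expected call."""

    patient_id: str
    gene: str
    kind: ScenarioKind
    intended_tier: Tier
    intended_hypothesis: Optional[GroupHypothesis]
    variant_keys: tuple[VariantKey, ...]


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth."""

    callset: CallSet
    samples: list[Sample]
    pedigree: Pedigree
    panel: Panel
    truth: list[TruthRecord]
    config: CohortConfig

    @property
    def patient_ids(self) -> list[str]:
        return [
            s.sample_id for s in self.samples
            if s.affected is AffectedStatus.AFFECTED
        ]

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        """Write VCF + PED + sidecar + phenotype TSV + truth TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sample_ids = [s.sample_id for s in self.samples]
        paths = {
            "vcf": out / "cohort.vcf",
            "ped": out / "cohort.ped",
            "sidecar": out / "annotations.tsv",
            "phenotypes": out / "phenotypes.tsv",
            "panel": out / "panel.tsv",
            "truth": out / "truth.tsv",
        }
        write_vcf(self.callset, sample_ids, paths["vcf"])
        write_ped(self.samples, paths["ped"])
        write_sidecar(list(self.callset.variants.values()), paths["sidecar"])
        write_phenotypes(
            {s.sample_id: s.phenotype_tags for s in self.samples},
            paths["phenotypes"])
        write_panel(self.panel, paths["panel"])
        with open(paths["truth"], "w") as fh:
            fh.write("patient\tgene\tkind\tintended_tier\t"
                     "intended_hypothesis\tvariants\n")
            for t in self.truth:
                fh.write("\t".join([
                    t.patient_id, t.gene, t.kind.value, t.intended_tier.value,
                    t.intended_hypothesis.value if t.intended_hypothesis
                    else "",
                    ";".join(str(k) for k in t.variant_keys),
                ]) + "\n")
        return paths


def default_cohort_config(panel: Panel, seed: int = 0,
                          n_patients: int = 50) -> CohortConfig:
    """The default cohort template: 50 patients, 15 of them carrying a
    likely-disease-causing genotype (yield 0.30), 8 with family data,
    plus association-only and per-stage decoy scenarios."""
    causal_counts = {
        ScenarioKind.AD_DE_NOVO: 3,
        ScenarioKind.AD_INHERITED_PENETRANT: 2,
        ScenarioKind.AD_INCOMPLETE_PENETRANCE: 4,
        ScenarioKind.AR_HOMOZYGOUS: 2,
        ScenarioKind.AR_COMPOUND_HET: 4,
    }
    if n_patients != 50:
        # scale the template down/up, keeping a ~30% causal fraction
        factor = n_patients / 50
        causal_counts = {
            k: max(1, round(v * factor)) for k, v in causal_counts.items()
        }
    other = {
        ScenarioKind.TACI_ASSOCIATED: 3,
        ScenarioKind.CIS_FALSE_COMPHET: 1,
        ScenarioKind.DECOY_COMMON: 6,
        ScenarioKind.DECOY_LOW_CADD: 6,
        ScenarioKind.DECOY_OFF_PANEL: 8,
        ScenarioKind.DECOY_LOW_QUALITY: 6,
    }
    if n_patients != 50:
        factor = n_patients / 50
        other = {k: max(1, round(v * factor)) for k, v in other.items()}
    scenarios = []
    for kind, count in {**causal_counts, **other}.items():
        af_range = None
        if kind in _AR_KINDS:
            af_range = (1e-6, 5e-3)   # exercises the biallelic-only band
        elif kind is ScenarioKind.TACI_ASSOCIATED:
            af_range = (1e-6, 5e-5)
        elif kind is ScenarioKind.DECOY_COMMON:
            af_range = (0.02, 0.4)
        cadd_range = (30.0, 40.0)
        if kind is ScenarioKind.DECOY_LOW_CADD:
            cadd_range = (1.0, 15.0)
        elif kind is ScenarioKind.TACI_ASSOCIATED:
            cadd_range = (10.0, 30.0)
        elif kind is ScenarioKind.DECOY_OFF_PANEL:
            cadd_range = (0.0, 40.0)
        scenarios.append(ScenarioSpec(kind, count, af_range, cadd_range))
    return CohortConfig(
        panel=panel, n_patients=n_patients,
        n_familial=max(1, round(8 * n_patients / 50)), seed=seed,
        scenarios=tuple(scenarios), background_variants_per_patient=5,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

class _Generator:
    def __init__(self, config: CohortConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.callset = CallSet(provenance={"source": "synthetic cohort",
                                           "seed": config.seed})
        self.samples: list[Sample] = []
        self.truth: list[TruthRecord] = []
        self._pos: dict[str, int] = {}
        self._bg_counter = 0

    # -- randomness helpers ----------------------------------------------
    def _log_uniform(self, lo: float, hi: float) -> float:
        if lo == hi:
            return lo
        return float(np.exp(self.rng.uniform(np.log(lo), np.log(hi))))

    def _draw_af(self, af_range) -> Optional[float]:
        if af_range is None:
            return None
        return self._log_uniform(*af_range)

    def _draw_cadd(self, cadd_range) -> float:
        return float(np.round(self.rng.uniform(*cadd_range), 2))

    def _snv(self) -> tuple[str, str]:
        ref = _BASES[self.rng.integers(0, 4)]
        alt = _BASES[self.rng.integers(0, 4)]
        while alt == ref:
            alt = _BASES[self.rng.integers(0, 4)]
        return ref, alt

    def _new_variant(self, gene: str, af, cadd, chrom=None) -> AnnotatedVariant:
        chrom = chrom or gene
        pos = self._pos.get(chrom, 990) + 10
        self._pos[chrom] = pos
        ref, alt = self._snv()
        v = AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            cadd_scaled=cadd, exac_af=af,
        )
        self.callset.add_variant(v)
        return v

    def _call(self, sid, key, zygosity, depth=None, gq=None):
        if depth is None:
            depth = int(self.rng.integers(20, 120))
        if gq is None:
            gq = float(self.rng.integers(40, 100))
        self.callset.add_call(
            GenotypeCall(sid, key, zygosity, depth, gq))

    # -- sample plumbing ---------------------------------------------------
    def _add_parents(self, pid: str) -> tuple[str, str]:
        mid, fid = f"{pid}_M", f"{pid}_F"
        fam = f"FAM_{pid}"
        self.samples.append(Sample(mid, Sex.FEMALE, AffectedStatus.UNAFFECTED,
                                   family_id=fam))
        self.samples.append(Sample(fid, Sex.MALE, AffectedStatus.UNAFFECTED,
                                   family_id=fam))
        return mid, fid

    # -- gene cycling ------------------------------------------------------
    def _genes(self, modes: set[InheritanceMode],
               exclude_override=True) -> list[str]:
        out = []
        for e in self.config.panel:
            if exclude_override and e.association_tier_override:
                continue
            if e.inheritance_modes & modes:
                out.append(e.gene)
        if not out:
            raise DataError(f"panel has no genes with modes {modes}")
        return out

    # -- main --------------------------------------------------------------
    def generate(self) -> SimulatedCohort:
        cfg = self.config
        pids = [f"S{i:03d}" for i in range(1, cfg.n_patients + 1)]

        # expand scenarios to one instance per patient, in config order
        instances: list[ScenarioSpec] = []
        for spec in cfg.scenarios:
            instances.extend([spec] * spec.count)

        ad_genes = self._genes({InheritanceMode.AD})
        ar_genes = self._genes({InheritanceMode.AR})
        override_genes = [
            e.gene for e in cfg.panel if e.association_tier_override
        ]
        low_cadd_genes = [
            e.gene for e in cfg.panel
            if e.msc is not None and not e.association_tier_override
        ]
        counters: dict[str, int] = {}

        def next_gene(pool: list[str], label: str) -> str:
            i = counters.get(label, 0)
            counters[label] = i + 1
            return pool[i % len(pool)]

        planned: dict[str, Optional[ScenarioSpec]] = {p: None for p in pids}
        for pid, spec in zip(pids, instances):
            planned[pid] = spec

        for idx, pid in enumerate(pids):
            spec = planned[pid]
            fam = f"FAM_{pid}"
            tags = {"hypogammaglobulinemia"}
            mother = father = None
            needs_trio = spec is not None and spec.kind in _TRIO_KINDS
            if needs_trio or idx < cfg.n_familial:
                mother, father = self._add_parents(pid)
            if spec is not None:
                gene_tags = self._plant(pid, spec, mother, father,
                                        next_gene, ad_genes, ar_genes,
                                        override_genes, low_cadd_genes)
                if gene_tags:
                    tags = gene_tags
            self.samples.append(Sample(
                pid, Sex.FEMALE if idx % 2 else Sex.MALE,
                AffectedStatus.AFFECTED, mother_id=mother, father_id=father,
                phenotype_tags=frozenset(tags), family_id=fam))
            self._background(pid)

        # deterministic sample order: probands as created, then relatives
        order = {s.sample_id: i for i, s in enumerate(self.samples)}
        self.samples.sort(key=lambda s: order[s.sample_id])
        pedigree = build_pedigree(self.samples)
        return SimulatedCohort(
            callset=self.callset, samples=self.samples, pedigree=pedigree,
            panel=cfg.panel, truth=self.truth, config=cfg)

    def _plant(self, pid, spec, mother, father, next_gene,
               ad_genes, ar_genes, override_genes, low_cadd_genes):
        """Realise one scenario for one patient; returns the patient tags."""
        kind = spec.kind
        panel = self.config.panel
        tags: Optional[set[str]] = None
        keys: tuple[VariantKey, ...]

        if kind in (ScenarioKind.AD_DE_NOVO,
                    ScenarioKind.AD_INHERITED_PENETRANT,
                    ScenarioKind.AD_INCOMPLETE_PENETRANCE):
            gene = next_gene(ad_genes, "AD")
            entry = panel.get(gene)
            v = self._new_variant(gene, self._draw_af(spec.af_range),
                                  self._draw_cadd(spec.cadd_range))
            self._call(pid, v.key, Zygosity.HET)
            assert mother is not None and father is not None
            if kind is ScenarioKind.AD_DE_NOVO:
                self._call(mother, v.key, Zygosity.HOM_REF)
                self._call(father, v.key, Zygosity.HOM_REF)
            else:
                carrier, other = (mother, father) if \
                    self.rng.integers(0, 2) else (father, mother)
                self._call(carrier, v.key, Zygosity.HET)
                self._call(other, v.key, Zygosity.HOM_REF)
                if kind is ScenarioKind.AD_INHERITED_PENETRANT:
                    self._set_status(carrier, AffectedStatus.MILDLY_AFFECTED)
            tags = set(entry.phenotype_tags)
            keys = (v.key,)

        elif kind is ScenarioKind.AR_HOMOZYGOUS:
            gene = next_gene(ar_genes, "AR")
            entry = panel.get(gene)
            v = self._new_variant(gene, self._draw_af(spec.af_range),
                                  self._draw_cadd(spec.cadd_range))
            self._call(pid, v.key, Zygosity.HOM_ALT)
            self._call(mother, v.key, Zygosity.HET)
            self._call(father, v.key, Zygosity.HET)
            tags = set(entry.phenotype_tags)
            keys = (v.key,)

        elif kind in (ScenarioKind.AR_COMPOUND_HET,
                      ScenarioKind.CIS_FALSE_COMPHET):
            gene = next_gene(ar_genes, "AR")
            entry = panel.get(gene)
            v1 = self._new_variant(gene, self._draw_af(spec.af_range),
                                   self._draw_cadd(spec.cadd_range))
            v2 = self._new_variant(gene, self._draw_af(spec.af_range),
                                   self._draw_cadd(spec.cadd_range))
            self._call(pid, v1.key, Zygosity.HET)
            self._call(pid, v2.key, Zygosity.HET)
            if kind is ScenarioKind.AR_COMPOUND_HET:
                self._call(mother, v1.key, Zygosity.HET)
                self._call(mother, v2.key, Zygosity.HOM_REF)
                self._call(father, v1.key, Zygosity.HOM_REF)
                self._call(father, v2.key, Zygosity.HET)
            else:  # both variants on the paternal haplotype
                self._call(mother, v1.key, Zygosity.HOM_REF)
                self._call(mother, v2.key, Zygosity.HOM_REF)
                self._call(father, v1.key, Zygosity.HET)
                self._call(father, v2.key, Zygosity.HET)
            tags = set(entry.phenotype_tags)
            keys = (v1.key, v2.key)

        elif kind is ScenarioKind.TACI_ASSOCIATED:
            if not override_genes:
                raise DataError("panel has no association-override gene")
            gene = next_gene(override_genes, "TACI")
            v = self._new_variant(gene, self._draw_af(spec.af_range),
                                  self._draw_cadd(spec.cadd_range))
            self._call(pid, v.key, Zygosity.HET)
            keys = (v.key,)

        elif kind is ScenarioKind.DECOY_COMMON:
            gene = next_gene(low_cadd_genes, "COMMON")
            af_range = spec.af_range or (0.02, 0.4)
            v = self._new_variant(gene, self._draw_af(af_range),
                                  self._draw_cadd(spec.cadd_range))
            self._call(pid, v.key, Zygosity.HET)
            keys = (v.key,)

        elif kind is ScenarioKind.DECOY_LOW_CADD:
            # gene whose MSC sits strictly above the decoy's score range and
            # whose tags exclude the default patient tag, so the phenotype
            # override cannot rescue the sub-MSC variant
            pool = [
                g for g in low_cadd_genes
                if panel.get(g).msc > spec.cadd_range[1]
                and "hypogammaglobulinemia" not in panel.get(g).phenotype_tags
            ]
            if not pool:
                raise DataError(
                    "decoy_low_cadd cadd_range must lie strictly below the "
                    "MSC of at least one phenotype-disjoint panel gene")
            gene = next_gene(pool, "LOWCADD")
            v = self._new_variant(gene, self._draw_af(spec.af_range),
                                  self._draw_cadd(spec.cadd_range))
            self._call(pid, v.key, Zygosity.HET)
            keys = (v.key,)

        elif kind is ScenarioKind.DECOY_OFF_PANEL:
            gene = f"NOTPID{self._bg_counter:04d}"
            self._bg_counter += 1
            v = self._new_variant(gene, self._draw_af(spec.af_range),
                                  self._draw_cadd(spec.cadd_range),
                                  chrom="OFFPANEL")
            self._call(pid, v.key, Zygosity.HET)
            keys = (v.key,)

        elif kind is ScenarioKind.DECOY_LOW_QUALITY:
            gene = next_gene(low_cadd_genes, "LOWQUAL")
            v = self._new_variant(gene, self._draw_af(spec.af_range),
                                  self._draw_cadd(spec.cadd_range))
            depth = int(self.rng.integers(0, 3))  # at or below the cutoff
            self._call(pid, v.key, Zygosity.HET, depth=depth)
            keys = (v.key,)

        else:  # pragma: no cover
            raise DataError(f"unknown scenario kind {kind}")

        self.truth.append(TruthRecord(
            patient_id=pid, gene=gene, kind=kind,
            intended_tier=_INTENDED_TIER[kind],
            intended_hypothesis=_INTENDED_HYPOTHESIS.get(kind),
            variant_keys=keys))
        return tags

    def _set_status(self, sid: str, status: AffectedStatus) -> None:
        for i, s in enumerate(self.samples):
            if s.sample_id == sid:
                self.samples[i] = s.with_affected(status)
                return

    def _background(self, pid: str) -> None:
        """Exome noise: variants in non-panel genes."""
        for _ in range(self.config.background_variants_per_patient):
            gene = f"BGENE{self._bg_counter:05d}"
            self._bg_counter += 1
            v = self._new_variant(
                gene,
                self._log_uniform(1e-6, 0.5),
                float(np.round(self.rng.uniform(0.0, 40.0), 2)),
                chrom="BACKGROUND",
            )
            self._call(pid, v.key, Zygosity.HET)


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a cohort per ``config``; deterministic under its seed."""
    return _Generator(config).generate()


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    """Planted-versus-recovered accounting for one simulated cohort."""

    per_kind: dict[str, dict[str, int]]
    true_positives: int
    false_negatives: int
    false_positives: int
    true_negatives: int

    @property
    def sensitivity(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 1.0

    @property
    def specificity(self) -> float:
        denom = self.true_negatives + self.false_positives
        return self.true_negatives / denom if denom else 1.0


def recovery_report(
    truth: list[TruthRecord],
    findings: list[ClassifiedFinding],
    patient_ids: list[str],
) -> RecoveryReport:
    """Score pipeline findings against the generator's truth table.

    A planted scenario is recovered when the pipeline's best tier for its
    (patient, gene) equals the intended tier (absent findings count as
    excluded).  Sensitivity is over scenarios intended
    likely-disease-causing; specificity over everything else, with any
    unplanted likely-tier finding counted as a false positive.
    """
    known = set(patient_ids)
    for f in findings:
        if f.patient_id not in known:
            raise DataError(
                f"finding for unknown patient {f.patient_id!r}: "
                "cohort/finding mismatch")

    precedence = [Tier.LIKELY_DISEASE_CAUSING, Tier.DISEASE_ASSOCIATED,
                  Tier.OTHER_DAMAGING, Tier.EXCLUDED]
    observed: dict[tuple[str, str], Tier] = {}
    for f in findings:
        k = (f.patient_id, f.gene)
        if k not in observed or precedence.index(f.tier) < \
                precedence.index(observed[k]):
            observed[k] = f.tier

    per_kind: dict[str, dict[str, int]] = {}
    tp = fn = tn = 0
    truth_keys = set()
    likely_truth_keys = set()
    for t in truth:
        truth_keys.add((t.patient_id, t.gene))
        got = observed.get((t.patient_id, t.gene), Tier.EXCLUDED)
        stats = per_kind.setdefault(
            t.kind.value, {"planted": 0, "recovered": 0})
        stats["planted"] += 1
        if got is t.intended_tier:
            stats["recovered"] += 1
        if t.intended_tier is Tier.LIKELY_DISEASE_CAUSING:
            likely_truth_keys.add((t.patient_id, t.gene))
            if got is Tier.LIKELY_DISEASE_CAUSING:
                tp += 1
            else:
                fn += 1
        else:
            if got is not Tier.LIKELY_DISEASE_CAUSING:
                tn += 1
    # any likely-tier finding not planted as likely (including a planted
    # non-likely scenario wrongly promoted) is a false positive
    fp = sum(
        1 for k, tier in observed.items()
        if tier is Tier.LIKELY_DISEASE_CAUSING and k not in likely_truth_keys
    )
    return RecoveryReport(per_kind=per_kind, true_positives=tp,
                          false_negatives=fn, false_positives=fp,
                          true_negatives=tn)
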