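"""Domain model for panel-based exome triage.

The pipeline reasons about four kinds of object: annotated variants (one
record per alternate allele), per-sample genotype calls, pedigree samples,
and gene-panel entries.  A single :class:`FilterConfig` houses every numeric
threshold used by the filtering cascade so that the whole procedure is
reproducible from one configuration object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, NamedTuple, Optional

__all__ = [
    "VariantKey",
    "Zygosity",
    "Sex",
    "AffectedStatus",
    "InheritanceMode",
    "AnnotatedVariant",
    "GenotypeCall",
    "Sample",
    "PanelEntry",
    "FilterConfig",
    "Pedigree",
    "Panel",
    "PedigreeError",
    "PanelError",
    "DataError",
    "build_pedigree",
    "validate_panel",
]


class DataError(ValueError):
    """Invalid domain data (out-of-range annotation, malformed record)."""


class PedigreeError(DataError):
    """Structurally invalid pedigree (cycles, dangling parent ids)."""


class PanelError(DataError):
    """Invalid gene panel (duplicate symbols, empty inheritance modes)."""


class VariantKey(NamedTuple):
    """Identity of one alternate allele: (chrom, pos, ref, alt), 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # used in decision logs and reports
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


class Zygosity(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def carries_alt(self) -> bool:
        return self in (Zygosity.HET, Zygosity.HOM_ALT)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class AffectedStatus(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    MILDLY_AFFECTED = "mildly_affected"
    UNKNOWN = "unknown"


class InheritanceMode(str, Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"


@dataclass(frozen=True)
class AnnotatedVariant:
    """One alternate allele at a site, with its functional annotations.

    ``exac_af`` is the population allele frequency; ``None`` means the allele
    has never been observed in the reference population, i.e. the variant is
    novel/private.  ``cadd_scaled`` is the CADD-scaled deleteriousness score
    (``None`` when no precomputed score is available).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    cadd_scaled: Optional[float] = None
    exac_af: Optional[float] = None
    hgmd_known: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.exac_af is not None and not (0.0 <= self.exac_af <= 1.0):
            raise DataError(
                f"exac_af outside [0,1]: {self.exac_af} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_novel(self) -> bool:
        return self.exac_af is None


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one variant, with call-level quality.

    ``depth`` and ``gq`` may be ``None`` when the source VCF carried no
    DP/GQ fields; such calls pass the quality gate (they are presumed
    confirmed by other means, e.g. Sanger resequencing).
    """

    sample_id: str
    variant_key: VariantKey
    zygosity: Zygosity
    depth: Optional[int] = None
    gq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise DataError(f"negative depth {self.depth} for {self.sample_id}")
        if self.gq is not None and self.gq < 0:
            raise DataError(f"negative GQ {self.gq} for {self.sample_id}")


@dataclass(frozen=True)
class Sample:
    """A pedigree member with phenotype information.

    ``phenotype_tags`` is a set of controlled phenotype terms (for example
    ``autoimmune_cytopenia``, ``granulomatous_disease``, ``low_B_cells``)
    used for gene/phenotype matching.  ``family_id`` groups members of one
    extended family even when no parental links are recorded (distant
    relatives such as second cousins).
    """

    sample_id: str
    sex: Sex = Sex.UNKNOWN
    affected: AffectedStatus = AffectedStatus.UNKNOWN
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    phenotype_tags: frozenset[str] = field(default_factory=frozenset)
    family_id: Optional[str] = None

    def with_tags(self, tags: Iterable[str]) -> "Sample":
        return replace(self, phenotype_tags=frozenset(tags))

    def with_affected(self, status: AffectedStatus) -> "Sample":
        return replace(self, affected=status)


@dataclass(frozen=True)
class PanelEntry:
    """A panel gene with its published inheritance modes and MSC.

    ``msc`` is the gene-specific mutation significance cutoff in CADD-scaled
    units: variants scoring below it are considered unlikely to be causal.
    ``association_tier_override`` forces every finding in the gene into a
    fixed tier (used for genes only weakly associated with disease, such as
    TNFRSF13B in CVID).
    """

    gene: str
    inheritance_modes: frozenset[InheritanceMode]
    msc: Optional[float] = None
    phenotype_tags: frozenset[str] = field(default_factory=frozenset)
    association_tier_override: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.inheritance_modes:
            raise PanelError(f"{self.gene}: inheritance_modes must be non-empty")
        if self.msc is not None and self.msc < 0:
            raise PanelError(f"{self.gene}: msc must be >= 0, got {self.msc}")

    @property
    def ar_capable(self) -> bool:
        """Can this gene plausibly act recessively (AR or X-linked)?"""
        return bool(
            self.inheritance_modes & {InheritanceMode.AR, InheritanceMode.XL}
        )


@dataclass(frozen=True)
class FilterConfig:
    """All numeric thresholds of the filtering cascade.

    Defaults follow the triage procedure this package implements:

    * calls at read depth <=2 or Phred-scaled quality <=20 are removed;
    * heterozygous (monoallelic-hypothesis) variants are excluded above a
      population allele frequency of 0.01% and homozygous/biallelic ones
      above 1%;
    * CADD-scaled 20 and 30 mark the top 1% / top 0.1% of reference SNVs
      and are used for cohort summaries only;
    * a variant below its gene's MSC may still pass when the patient
      phenotype matches the gene's published presentation
      (``msc_override_enabled``).
    """

    het_af_max: float = 1e-4
    biallelic_af_max: float = 1e-2
    min_depth_exclusive: int = 2
    min_gq_exclusive: float = 20.0
    cadd_benign_scaled: float = 20.0
    cadd_strong_scaled: float = 30.0
    msc_override_enabled: bool = True
    # connective for the quality gate: "or" removes a call failing either
    # condition, "and" only when both fail
    quality_connective: str = "or"

    def __post_init__(self) -> None:
        if not (0.0 < self.het_af_max <= self.biallelic_af_max <= 1.0):
            raise DataError(
                "require 0 < het_af_max <= biallelic_af_max <= 1, got "
                f"{self.het_af_max} and {self.biallelic_af_max}"
            )
        for name in ("min_depth_exclusive", "min_gq_exclusive",
                     "cadd_benign_scaled", "cadd_strong_scaled"):
            value = getattr(self, name)
            if value != value or value in (float("inf"), float("-inf")):
                raise DataError(f"{name} must be finite, got {value}")
        if self.quality_connective not in ("or", "and"):
            raise DataError(
                f"quality_connective must be 'or' or 'and', got "
                f"{self.quality_connective!r}"
            )


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

class Pedigree:
    """Index over samples supporting parent/child/sibling/relative lookup."""

    def __init__(self, samples: list[Sample]):
        self._samples: dict[str, Sample] = {}
        for s in samples:
            if s.sample_id in self._samples:
                raise PedigreeError(f"duplicate sample id {s.sample_id!r}")
            self._samples[s.sample_id] = s
        self._validate()

    def _validate(self) -> None:
        for s in self._samples.values():
            for pid in (s.mother_id, s.father_id):
                if pid is not None and pid not in self._samples:
                    raise PedigreeError(
                        f"{s.sample_id}: parent {pid!r} not in pedigree"
                    )
        # ancestry must be acyclic: walk parent links with a coloured DFS
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(sid: str, path: list[str]) -> None:
            if state.get(sid) == 1:
                return
            if state.get(sid) == 0:
                cycle = path[path.index(sid):] + [sid]
                raise PedigreeError(
                    "cyclic parentage: " + " -> ".join(cycle)
                )
            state[sid] = 0
            s = self._samples[sid]
            for pid in (s.mother_id, s.father_id):
                if pid is not None:
                    visit(pid, path + [sid])
            state[sid] = 1

        for sid in self._samples:
            visit(sid, [])

    # -- basic access -----------------------------------------------------
    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._samples

    def __len__(self) -> int:
        return len(self._samples)

    def __iter__(self):
        return iter(self._samples.values())

    def get(self, sample_id: str) -> Sample:
        return self._samples[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(self._samples)

    # -- relationships ----------------------------------------------------
    def parents(self, sample_id: str) -> set[str]:
        s = self._samples[sample_id]
        return {p for p in (s.mother_id, s.father_id) if p is not None}

    def children(self, sample_id: str) -> set[str]:
        return {
            s.sample_id
            for s in self._samples.values()
            if sample_id in (s.mother_id, s.father_id)
        }

    def siblings(self, sample_id: str) -> set[str]:
        """Samples sharing at least one recorded parent (excluding self)."""
        mine = self.parents(sample_id)
        if not mine:
            return set()
        return {
            s.sample_id
            for s in self._samples.values()
            if s.sample_id != sample_id and self.parents(s.sample_id) & mine
        }

    def founders(self) -> set[str]:
        return {sid for sid in self._samples if not self.parents(sid)}

    def non_founders(self) -> set[str]:
        return {sid for sid in self._samples if self.parents(sid)}

    def relatives(self, sample_id: str) -> set[str]:
        """All other members of the sample's family.

        Family membership is the explicit ``family_id`` when recorded (so
        distant relatives with no shared recorded parents, e.g. second
        cousins, are still relatives); otherwise the connected component of
        the parent/child graph.
        """
        s = self._samples[sample_id]
        if s.family_id is not None:
            return {
                o.sample_id
                for o in self._samples.values()
                if o.sample_id != sample_id and o.family_id == s.family_id
            }
        component = {sample_id}
        frontier = [sample_id]
        while frontier:
            sid = frontier.pop()
            for nxt in self.parents(sid) | self.children(sid) | self.siblings(sid):
                if nxt not in component:
                    component.add(nxt)
                    frontier.append(nxt)
        component.discard(sample_id)
        return component

    def affected_patients(self) -> list[str]:
        """Sample ids with affected status, in input order."""
        return [
            s.sample_id
            for s in self._samples.values()
            if s.affected is AffectedStatus.AFFECTED
        ]


def build_pedigree(samples: list[Sample]) -> Pedigree:
    """Validate samples and build a relationship index over them."""
    return Pedigree(list(samples))


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

class Panel:
    """A validated gene panel with case-insensitive symbol lookup."""

    def __init__(self, entries: list[PanelEntry]):
        self._entries: dict[str, PanelEntry] = {}
        for e in entries:
            k = e.gene.upper()
            if k in self._entries:
                raise PanelError(f"duplicate panel gene {e.gene!r}")
            self._entries[k] = e

    @property
    def size(self) -> int:
        return len(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, gene: str) -> Optional[PanelEntry]:
        return self._entries.get(gene.upper())

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self._entries.values()]


def validate_panel(entries: list[PanelEntry]) -> Panel:
    """Reject duplicate symbols / empty mode sets; return an indexed panel."""
    return Panel(list(entries))
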