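"""Readers and writers for the pipeline's external formats.

Supported inputs: annotated VCF 4.x (annotations inline in INFO or joined
from a sidecar TSV on the variant identity key), PLINK-style 6-column PED
(with an optional affected-status sidecar for statuses PED cannot encode,
e.g. ``mildly_affected``), gene-panel TSV, per-sample phenotype-tag TSV and
a YAML filter configuration.  Outputs: per-finding report TSV, cohort
summary JSON, and (for the simulator) VCF/PED/sidecar files.

Positions are 1-based throughout, exactly as in VCF.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from cyvcf2 import VCF

from .models import (
    AffectedStatus,
    AnnotatedVariant,
    DataError,
    FilterConfig,
    GenotypeCall,
    InheritanceMode,
    Panel,
    PanelEntry,
    Sample,
    Sex,
    VariantKey,
    Zygosity,
    validate_panel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CallSet",
    "read_annotated_vcf",
    "read_sidecar",
    "write_sidecar",
    "read_ped",
    "write_ped",
    "read_panel",
    "write_panel",
    "read_phenotypes",
    "write_phenotypes",
    "apply_phenotypes",
    "load_filter_config",
    "write_report",
    "write_vcf",
]

SIDECAR_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript",
    "hgvs_c", "hgvs_p", "cadd", "exac_af", "hgmd",
]


@dataclass
class CallSet:
    """Container for one cohort's variants and genotype calls."""

    variants: dict[VariantKey, AnnotatedVariant] = field(default_factory=dict)
    calls: dict[tuple[str, VariantKey], GenotypeCall] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add_variant(self, v: AnnotatedVariant) -> None:
        if v.key in self.variants:
            raise DataError(f"duplicate variant identity key {v.key}")
        self.variants[v.key] = v

    def add_call(self, c: GenotypeCall) -> None:
        if c.variant_key not in self.variants:
            raise DataError(f"call references unknown variant {c.variant_key}")
        k = (c.sample_id, c.variant_key)
        if k in self.calls:
            raise DataError(f"duplicate call for {k}")
        self.calls[k] = c

    def call(self, sample_id: str, key: VariantKey) -> Optional[GenotypeCall]:
        return self.calls.get((sample_id, key))

    def calls_for_sample(self, sample_id: str) -> list[GenotypeCall]:
        return [c for (sid, _), c in self.calls.items() if sid == sample_id]

    def carriers(self, key: VariantKey) -> list[GenotypeCall]:
        return [
            c for (_, k), c in self.calls.items()
            if k == key and c.zygosity.carries_alt()
        ]

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid, _ in self.calls:
            seen.setdefault(sid)
        return list(seen)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_KEYS = {
    "gene": "GENE", "transcript": "TRANSCRIPT", "hgvs_c": "HGVSC",
    "hgvs_p": "HGVSP", "cadd": "CADD_PHRED", "exac_af": "EXAC_AF",
    "hgmd": "HGMD",
}


def _info_field(variant, key: str, alt_index: int, n_alt: int):
    raw = variant.INFO.get(key)
    if raw is None:
        return None
    if isinstance(raw, (tuple, list)):
        raw = raw[alt_index] if alt_index < len(raw) else None
    elif isinstance(raw, str) and n_alt > 1 and "," in raw:
        parts = raw.split(",")
        raw = parts[alt_index] if alt_index < len(parts) else None
    if raw in (None, ".", ""):
        return None
    return raw


def _zygosity_for_alt(alleles: list[int], alt_number: int) -> Zygosity:
    """Zygosity of one sample w.r.t. alternate allele ``alt_number``.

    Haploid carriers (hemizygous males on X) are reported hom_alt.
    """
    ploid = [a for a in alleles if a is not None]
    if not ploid or any(a < 0 for a in ploid):
        return Zygosity.MISSING
    n_alt = sum(1 for a in ploid if a == alt_number)
    if n_alt == 0:
        return Zygosity.HOM_REF
    if n_alt == len(ploid):
        return Zygosity.HOM_ALT
    return Zygosity.HET


_INT32_MISSING = -2147483648


def _format_values(variant, key: str):
    """Per-sample FORMAT values with missing entries mapped to None.

    Uses ``Variant.format`` rather than the gt_depths/gt_quals shortcuts,
    which conflate a genuine value of 0 with a missing entry.
    """
    try:
        arr = variant.format(key)
    except Exception:
        return None
    if arr is None:
        return None
    out = []
    for row in arr:
        val = row[0] if getattr(row, "__len__", None) else row
        if val is None or val == _INT32_MISSING or val != val:
            out.append(None)
        elif float(val) < 0:
            out.append(None)
        else:
            out.append(float(val))
    return out


def _truthy_flag(value) -> bool:
    if value is None or value is True:
        return value is True
    s = str(value).strip().lower()
    return s not in ("", "0", ".", "false", "no", "none")


def read_annotated_vcf(
    path: Union[str, Path],
    sidecar: Optional[Union[str, Path]] = None,
) -> CallSet:
    """Read an annotated multi-sample VCF into a :class:`CallSet`.

    Multi-allelic rows are decomposed into one :class:`AnnotatedVariant` per
    alternate allele.  Annotations come from the INFO keys ``GENE``,
    ``HGVSC``, ``HGVSP``, ``CADD_PHRED``, ``EXAC_AF`` and ``HGMD``; a
    sidecar TSV (see :func:`read_sidecar`) joined on (chrom, pos, ref, alt)
    takes precedence over INFO.  Missing annotation fields stay absent,
    never zero.  Calls without DP/GQ carry ``None`` for those fields and
    are treated as passing the quality filter downstream.
    """
    path = Path(path)
    side = read_sidecar(sidecar) if sidecar is not None else {}
    callset = CallSet(provenance={"vcf": str(path)})
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    n_rows = 0
    matched_side = 0
    for variant in vcf:
        n_rows += 1
        alts = variant.ALT or []
        genotypes = variant.genotypes if samples else []
        depths = _format_values(variant, "DP") if samples else None
        quals = _format_values(variant, "GQ") if samples else None
        for ai, alt in enumerate(alts):
            key = VariantKey(variant.CHROM, variant.POS, variant.REF, alt)
            ann = side.get(key)
            if ann is not None:
                matched_side += 1
                record = AnnotatedVariant(
                    chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                    gene=ann.gene, transcript=ann.transcript,
                    hgvs_c=ann.hgvs_c, hgvs_p=ann.hgvs_p,
                    cadd_scaled=ann.cadd_scaled, exac_af=ann.exac_af,
                    hgmd_known=ann.hgmd_known,
                )
            else:
                gene = _info_field(variant, _INFO_KEYS["gene"], ai, len(alts))
                cadd = _info_field(variant, _INFO_KEYS["cadd"], ai, len(alts))
                af = _info_field(variant, _INFO_KEYS["exac_af"], ai, len(alts))
                record = AnnotatedVariant(
                    chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                    gene=str(gene) if gene is not None else "",
                    transcript=_info_field(
                        variant, _INFO_KEYS["transcript"], ai, len(alts)),
                    hgvs_c=_info_field(variant, _INFO_KEYS["hgvs_c"], ai, len(alts)),
                    hgvs_p=_info_field(variant, _INFO_KEYS["hgvs_p"], ai, len(alts)),
                    cadd_scaled=float(cadd) if cadd is not None else None,
                    exac_af=float(af) if af is not None else None,
                    hgmd_known=_truthy_flag(
                        _info_field(variant, _INFO_KEYS["hgmd"], ai, len(alts))),
                )
            callset.add_variant(record)
            for si, sid in enumerate(samples):
                zyg = _zygosity_for_alt(list(genotypes[si][:-1]), ai + 1)
                depth = (
                    int(depths[si])
                    if depths is not None and depths[si] is not None
                    else None
                )
                gq = quals[si] if quals is not None else None
                if depth is None and gq is None and zyg.carries_alt():
                    logger.debug(
                        "no DP/GQ for %s at %s; call passes quality gate",
                        sid, key)
                callset.add_call(GenotypeCall(
                    sample_id=sid, variant_key=key, zygosity=zyg,
                    depth=depth, gq=gq,
                ))
    callset.provenance.update({"vcf_rows": n_rows, "samples": samples})
    if sidecar is not None:
        unmatched = len(side) - matched_side
        callset.provenance["sidecar"] = str(sidecar)
        if unmatched > 0:
            warnings.warn(
                f"{unmatched} sidecar annotation row(s) matched no VCF variant "
                "and were ignored", stacklevel=2)
    return callset


# ---------------------------------------------------------------------------
# Annotation sidecar TSV
# ---------------------------------------------------------------------------

def read_sidecar(path: Union[str, Path]) -> dict[VariantKey, AnnotatedVariant]:
    """Read annotation records keyed by (chrom, pos, ref, alt).

    Header: ``chrom pos ref alt gene transcript hgvs_c hgvs_p cadd exac_af
    hgmd`` (tab-separated).  Empty cells mean the annotation is absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SIDECAR_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"sidecar {path} missing columns {missing}")
    out: dict[VariantKey, AnnotatedVariant] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            record = AnnotatedVariant(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene=row.gene,
                transcript=row.transcript or None,
                hgvs_c=row.hgvs_c or None,
                hgvs_p=row.hgvs_p or None,
                cadd_scaled=float(row.cadd) if row.cadd != "" else None,
                exac_af=float(row.exac_af) if row.exac_af != "" else None,
                hgmd_known=_truthy_flag(row.hgmd),
            )
        except (ValueError, DataError) as exc:
            raise DataError(f"sidecar {path} line {i}: {exc}") from exc
        if record.key in out:
            raise DataError(f"sidecar {path} line {i}: duplicate key {record.key}")
        out[record.key] = record
    return out


def _fmt(value, spec: str = "") -> str:
    if value is None:
        return ""
    if spec:
        return format(value, spec)
    return str(value)


def write_sidecar(
    variants: list[AnnotatedVariant], path: Union[str, Path]
) -> None:
    """Write annotation records in sidecar TSV form (see read_sidecar)."""
    rows = []
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "transcript": _fmt(v.transcript),
            "hgvs_c": _fmt(v.hgvs_c), "hgvs_p": _fmt(v.hgvs_p),
            "cadd": _fmt(v.cadd_scaled, ".17g"),
            "exac_af": _fmt(v.exac_af, ".17g"),
            "hgmd": "1" if v.hgmd_known else "0",
        })
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_PED_AFFECTED = {"1": AffectedStatus.UNAFFECTED, "2": AffectedStatus.AFFECTED}


def read_ped(
    path: Union[str, Path],
    status_sidecar: Optional[Union[str, Path]] = None,
) -> list[Sample]:
    """Read a PLINK-style 6-column PED file into samples.

    Columns: family, individual, father, mother, sex, phenotype; ``0``
    means missing.  Sex 1/2 maps to male/female, phenotype 1/2 to
    unaffected/affected, anything else to unknown.  A two-column sidecar
    TSV (``sample_id<TAB>status``) can override affected status with values
    PED cannot express, e.g. ``mildly_affected``.
    """
    samples: list[Sample] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise DataError(
                    f"{path} line {lineno}: expected 6 columns, "
                    f"got {len(fields)}")
            fam, sid, father, mother, sex, pheno = fields
            samples.append(Sample(
                sample_id=sid,
                sex=_PED_SEX.get(sex, Sex.UNKNOWN),
                affected=_PED_AFFECTED.get(pheno, AffectedStatus.UNKNOWN),
                mother_id=None if mother == "0" else mother,
                father_id=None if father == "0" else father,
                family_id=None if fam == "0" else fam,
            ))
    if status_sidecar is not None:
        overrides: dict[str, AffectedStatus] = {}
        with open(status_sidecar) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise DataError(
                        f"{status_sidecar} line {lineno}: expected 2 columns")
                overrides[parts[0]] = AffectedStatus(parts[1])
        samples = [
            s.with_affected(overrides[s.sample_id])
            if s.sample_id in overrides else s
            for s in samples
        ]
    return samples


_SEX_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_CODE = {
    AffectedStatus.UNAFFECTED: "1",
    AffectedStatus.AFFECTED: "2",
    AffectedStatus.MILDLY_AFFECTED: "0",
    AffectedStatus.UNKNOWN: "0",
}


def write_ped(samples: list[Sample], path: Union[str, Path]) -> None:
    """Write samples as 6-column PED plus a status sidecar when needed.

    Statuses PED cannot encode (mildly_affected) additionally go to
    ``<path>.status.tsv``.
    """
    extra: list[tuple[str, str]] = []
    with open(path, "w") as fh:
        for s in samples:
            fh.write("\t".join([
                s.family_id or s.sample_id,
                s.sample_id,
                s.father_id or "0",
                s.mother_id or "0",
                _SEX_CODE[s.sex],
                _AFF_CODE[s.affected],
            ]) + "\n")
            if s.affected is AffectedStatus.MILDLY_AFFECTED:
                extra.append((s.sample_id, s.affected.value))
    if extra:
        with open(str(path) + ".status.tsv", "w") as fh:
            for sid, status in extra:
                fh.write(f"{sid}\t{status}\n")


# ---------------------------------------------------------------------------
# Panel / phenotypes / config
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["gene", "inheritance_modes", "msc", "phenotype_tags",
                 "tier_override"]


def read_panel(path: Union[str, Path]) -> Panel:
    """Read a gene-panel TSV (see PANEL_COLUMNS) and validate it."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"panel {path} missing columns {missing}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            modes = frozenset(
                InheritanceMode(m.strip())
                for m in row.inheritance_modes.split(",") if m.strip()
            )
            entries.append(PanelEntry(
                gene=row.gene,
                inheritance_modes=modes,
                msc=float(row.msc) if row.msc != "" else None,
                phenotype_tags=frozenset(
                    t.strip() for t in row.phenotype_tags.split(",")
                    if t.strip()),
                association_tier_override=row.tier_override or None,
            ))
        except ValueError as exc:
            raise DataError(f"panel {path} line {i}: {exc}") from exc
    return validate_panel(entries)


def write_panel(panel: Panel, path: Union[str, Path]) -> None:
    rows = []
    for e in panel:
        rows.append({
            "gene": e.gene,
            "inheritance_modes": ",".join(
                sorted(m.value for m in e.inheritance_modes)),
            "msc": _fmt(e.msc, "g"),
            "phenotype_tags": ",".join(sorted(e.phenotype_tags)),
            "tier_override": e.association_tier_override or "",
        })
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: Union[str, Path]) -> dict[str, frozenset[str]]:
    """Read ``sample_id<TAB>comma-joined tags`` into a mapping."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path} line {lineno}: expected 2 columns")
            out[parts[0]] = frozenset(
                t.strip() for t in parts[1].split(",") if t.strip())
    return out


def write_phenotypes(
    tags: dict[str, frozenset[str]], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for sid in sorted(tags):
            fh.write(f"{sid}\t{','.join(sorted(tags[sid]))}\n")


def apply_phenotypes(
    samples: list[Sample], tags: dict[str, frozenset[str]]
) -> list[Sample]:
    return [
        s.with_tags(tags[s.sample_id]) if s.sample_id in tags else s
        for s in samples
    ]


def load_filter_config(path: Optional[Union[str, Path]]) -> FilterConfig:
    """Load a YAML file whose keys mirror FilterConfig field names."""
    if path is None:
        return FilterConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise DataError(f"config {path}: expected a mapping")
    try:
        return FilterConfig(**data)
    except TypeError as exc:
        raise DataError(f"config {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "patient", "gene", "hgvs_c", "hgvs_p", "hypothesis", "cadd", "exac_af",
    "tier", "reasons", "segregation",
]


def write_report(findings, summary, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write the per-finding TSV and the cohort-summary JSON.

    One TSV row per variant within each classified finding (so a
    compound-heterozygous finding contributes two rows), ordered
    deterministically by (patient, gene, pos).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in findings:
        g = f.group
        for key in g.variant_keys:
            v = f.variants[key]
            rows.append({
                "patient": g.patient_id,
                "gene": g.gene,
                "hgvs_c": _fmt(v.hgvs_c),
                "hgvs_p": _fmt(v.hgvs_p),
                "hypothesis": g.hypothesis.value,
                "cadd": _fmt(v.cadd_scaled, "g"),
                "exac_af": _fmt(v.exac_af, "g"),
                "tier": f.tier.value,
                "reasons": ";".join(f.reasons),
                "segregation": ";".join(sorted(fl.value for fl in g.segregation)),
                "_pos": (v.chrom, v.pos, v.ref, v.alt),
            })
    rows.sort(key=lambda r: (r["patient"], r["gene"], r["_pos"]))
    for r in rows:
        del r["_pos"]
    findings_path = out_dir / "findings.tsv"
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(
        findings_path, sep="\t", index=False)
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"findings": findings_path, "summary": summary_path}


# ---------------------------------------------------------------------------
# VCF output (simulator / fixture export)
# ---------------------------------------------------------------------------

_ZYG_GT = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.MISSING: "./.",
}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=TRANSCRIPT,Number=A,Type=String,Description="RefSeq transcript">
##INFO=<ID=HGVSC,Number=A,Type=String,Description="HGVS coding change">
##INFO=<ID=HGVSP,Number=A,Type=String,Description="HGVS protein change">
##INFO=<ID=CADD_PHRED,Number=A,Type=Float,Description="CADD scaled score">
##INFO=<ID=EXAC_AF,Number=A,Type=Float,Description="ExAC allele frequency">
##INFO=<ID=HGMD,Number=A,Type=String,Description="HGMD known flag">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def _info_string(v: AnnotatedVariant) -> str:
    parts = []
    if v.gene:
        parts.append(f"GENE={v.gene}")
    if v.transcript:
        parts.append(f"TRANSCRIPT={v.transcript}")
    if v.hgvs_c:
        parts.append(f"HGVSC={v.hgvs_c}")
    if v.hgvs_p:
        parts.append(f"HGVSP={v.hgvs_p}")
    if v.cadd_scaled is not None:
        parts.append(f"CADD_PHRED={v.cadd_scaled:.17g}")
    if v.exac_af is not None:
        parts.append(f"EXAC_AF={v.exac_af:.17g}")
    if v.hgmd_known:
        parts.append("HGMD=1")
    return ";".join(parts) if parts else "."


def write_vcf(
    callset: CallSet,
    sample_ids: list[str],
    path: Union[str, Path],
    inline_annotations: bool = True,
) -> None:
    """Write a CallSet as sorted, uncompressed VCF 4.2 text.

    Output is byte-deterministic for a given CallSet and sample order.
    Samples with no recorded call at a variant are emitted as hom_ref with
    absent DP/GQ (the cohort VCF is assumed jointly genotyped).
    """
    keys = sorted(callset.variants)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        contigs: dict[str, None] = {}
        for k in keys:
            contigs.setdefault(k.chrom)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for k in keys:
            v = callset.variants[k]
            info = _info_string(v) if inline_annotations else "."
            cols = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
                    info, "GT:DP:GQ"]
            for sid in sample_ids:
                call = callset.call(sid, k)
                if call is None:
                    cols.append("0/0:.:.")
                else:
                    dp = "." if call.depth is None else str(call.depth)
                    gq = "." if call.gq is None else f"{call.gq:g}"
                    cols.append(f"{_ZYG_GT[call.zygosity]}:{dp}:{gq}")
            fh.write("\t".join(cols) + "\n")
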