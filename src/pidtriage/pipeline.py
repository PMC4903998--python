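"""End-to-end driver: cascade → inheritance analysis → classification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .classify import ClassifiedFinding, CohortSummary, classify_all, summarize_cohort
from .filters import CascadeResult, run_cascade
from .inheritance import CandidateGroup, analyze_candidates
from .io import CallSet
from .models import FilterConfig, Panel, Pedigree

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything one triage run produces."""

    cascade: CascadeResult
    groups: list[CandidateGroup]
    findings: list[ClassifiedFinding]
    summary: CohortSummary


def run_pipeline(
    callset: CallSet,
    pedigree: Pedigree,
    panel: Panel,
    cfg: Optional[FilterConfig] = None,
) -> PipelineResult:
    """Run the full triage procedure over one cohort.

    Filters every affected patient's calls through the exclusion cascade,
    groups survivors under inheritance hypotheses with trio phasing and
    segregation annotation, assigns tiers, and computes the cohort summary.
    """
    cfg = cfg or FilterConfig()
    cascade = run_cascade(callset, pedigree, panel, cfg)
    groups = analyze_candidates(cascade.survivors, panel, pedigree, callset)
    findings = classify_all(groups, panel, pedigree, callset)
    summary = summarize_cohort(findings, callset, pedigree, panel, cfg,
                               cascade=cascade)
    return PipelineResult(cascade=cascade, groups=groups,
                          findings=findings, summary=summary)
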