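# Methods

## Scope and model

`pidtriage` formalises a targeted exome-triage procedure for primary
immunodeficiency (PID) cohorts. Its unit of inference is the *candidate
genotype*: one patient's surviving variant calls in one panel gene,
interpreted under a Mendelian hypothesis. The pipeline is deliberately
rule-based — every decision is a deterministic function of the input
annotations, genotypes, pedigree and a single configuration object, and
every exclusion is logged with a machine-readable reason — because its
purpose is reproducible triage, not probabilistic pathogenicity
estimation (no ACMG/AMP scoring, no posterior probabilities).

Inputs are consumed as annotations: CADD-scaled scores, gene-level
mutation significance cutoffs (MSC), ExAC allele frequencies and HGMD
flags are taken as given from the annotated VCF, sidecar TSV and panel
table. The package never recomputes them, and upstream read alignment and
variant calling are out of scope.

## Thresholds and defaults

All numeric gates live in `FilterConfig`:

| parameter | default | units | role |
| --- | --- | --- | --- |
| `min_depth_exclusive` | 2 | reads | call removed when depth ≤ value |
| `min_gq_exclusive` | 20 | Phred | call removed when quality ≤ value |
| `het_af_max` | 1e-4 | allele frequency | ceiling under the monoallelic hypothesis |
| `biallelic_af_max` | 1e-2 | allele frequency | ceiling under the biallelic hypothesis |
| `cadd_benign_scaled` | 20 | CADD-scaled | "top 1 %" summary band (reporting only) |
| `cadd_strong_scaled` | 30 | CADD-scaled | "top 0.1 %" summary band (reporting only) |
| `msc_override_enabled` | true | — | phenotype match may rescue sub-MSC variants |
| `quality_connective` | `or` | — | `or` removes on either quality failure, `and` on both |

Choices worth noting:

* **Frequency cutoffs are inclusive** (pass at exactly the threshold,
  fail strictly above). The exclusion rule is phrased as "excluded if
  frequency > cutoff", and we follow that literally.
* **The heterozygous ceiling is 0.01 % = 1e-4**, two orders of magnitude
  below the biallelic 1 % ceiling. Both are overridable; the packaged
  cohort is compatible with either a 0.01 % or 0.1 % reading of the
  heterozygous bound (its only heterozygous variant with a reported
  frequency sits at 8.3e-6), while the biallelic variants (up to 2.2e-3)
  require the 1 % bound.
* **The quality connective defaults to `or`** — a call failing either the
  depth or the quality condition is removed. This is the stricter reading
  of a conjunctive phrasing and the safer one for downstream claims; it
  is configurable to `and`.
* **Missing DP/GQ pass the quality gate.** Curated variant tables often
  lack per-call quality metadata because the calls were confirmed by
  orthogonal means (Sanger, IGV inspection); absence of metadata is not
  evidence of a bad call. The reader logs such calls.

## Hypothesis routing and the fixed point

The frequency gate is zygosity-dependent, so each gene needs a governing
hypothesis before the gate can run: homozygous-alt anywhere in the gene,
or ≥ 2 heterozygous calls in an AR- or XL-capable gene, selects the
biallelic ceiling; anything else the monoallelic one. Because removals can
change the pattern (a compound-het candidate that loses one partner is no
longer biallelic), the frequency and CADD/MSC stages iterate to a fixed
point: route, apply both gates, re-route on the survivors, repeat until
stable. The set shrinks monotonically, so the iteration terminates, and
at the fixed point three properties hold unconditionally:

* **idempotence** — re-running the cascade on its own survivors returns
  them unchanged;
* **order-independence** — the frequency and CADD/MSC gates commute
  (both are evaluated against the same routed set each iteration);
* **completeness** — every input call is either a survivor or carries
  exactly one logged failing decision, attributed to the first stage that
  rejected it.

## Inheritance analysis

* **Grouping.** Per (patient, gene): each hom-alt call forms a
  `biallelic_hom` group (hemizygous males on X are represented hom-alt
  and treated the same); ≥ 2 heterozygous calls in an AR-capable gene
  form one compound-het candidate; every other het call is its own
  monoallelic group. Every surviving call lands in exactly one group.
* **Phasing** enumerates parental-origin assignments (each variant to a
  parent that carries it). All assignments using both parents ⇒ in trans
  (`biallelic_comphet`); all using one ⇒ in cis, and the candidate
  dissolves into monoallelic groups; ambiguous configurations, an
  ungenotyped parent, or a variant absent from both genotyped parents
  (Mendelian inconsistency, logged) leave the phase unknown. Only
  parent-based phasing is implemented: sibling-only pedigrees stay
  `phase_unknown`, because no principled sibling-inference rule is
  defined here and guessing one would be worse than abstaining.
* **De novo** requires both parents genotyped homozygous-reference and
  the proband heterozygous; with one parent missing, transmission cannot
  be excluded and no flag is set. A carrying unaffected parent instead
  sets `inherited_unaffected_parent`; the two flags are mutually
  exclusive by construction.
* **Segregation.** Relatives are the patient's family — the explicit
  family id when present (so distant relatives such as second cousins
  count even with no shared recorded parents), otherwise the connected
  pedigree component. An unaffected relative carrying the full genotype
  pattern sets `incomplete_penetrance`; a mildly affected carrier sets
  `variable_expressivity`; `segregates_with_disease` requires at least
  one genotyped affected relative, all of them carriers, and no
  unaffected carrier. The non-vacuity requirement matters: without it,
  every sporadic trio would "segregate" trivially. Carriers are never
  auto-rejected on penetrance grounds — dominant PID genes are known for
  incomplete penetrance, so the pipeline flags and reports rather than
  filters.

## Classification

The only inheritance-compatibility logic is the table monoallelic ↔ AD,
biallelic (hom or in-trans comphet) ↔ AR, hemizygous/homozygous ↔ XL.
`likely_disease_causing` requires compatibility *and* a phenotype match;
an unphased multi-het candidate in a recessive-only gene is
`other_damaging` with reason `phase_unknown`; a panel entry's
`association_tier_override` short-circuits everything (used for genes
only weakly associated with the phenotype, where even a matching variant
is evidence of association, not causation). HGMD support is carried as
evidence but never changes a tier. Phenotype matching is non-empty
intersection of controlled tag sets — a deliberately coarse approximation
of expert clinical judgment. The packaged cohort's tags are curated so
that the published tier assignments are reproduced; this is curation, not
inference, and applying the pipeline to new data requires curating panel
tags with the same care.

In the per-patient summary breakdown each patient appears once, under
their best tier (and alphabetically first gene within it), so a patient
with both a causal finding and an association-tier variant is counted in
the causal gene's category. Distinct variant counting uses the
(chrom, pos, ref, alt) identity key, so a variant shared by related
patients counts once.

## The packaged cohort

`load_paper_fixture()` rebuilds a published 50-patient CVID cohort in
code: 17 distinct variants in 18 carrier rows across seven genes, with
printed CADD-scaled scores and allele frequencies, and family structures
encoding the reported segregation facts (two de novo events, unaffected
and mildly affected carrier relatives, one extended family with two
affected second-cousin carriers, three fully phased compound-het trios).
Genomic coordinates are synthetic — one contig per gene — because the
source tables identify variants by HGVS only and no pipeline logic reads
coordinates. The gene-specific MSC values are likewise curated: set below
each variant's score except for *LRBA*, whose cutoff (28) sits above all
four *LRBA* variants so that they pass only through the phenotype-match
override, reproducing how those variants were retained in the original
analysis. The 35 patients without findings carry no panel variants at
all; their real counterparts carried additional variants not printed in
the main tables, so fixture-derived funnel counts above the top tier
(e.g. `n_variants_total`) describe the fixture, not the original cohort.

## The synthetic-cohort generator

`generate_cohort` emulates the *structure* of such a study — affected
probands, optional trios, planted causal genotypes, per-stage decoys,
exome background — not its biology. Scenario kinds cover each causal
configuration (dominant de novo, dominant from a mildly affected parent,
dominant with an unaffected carrier parent, recessive homozygous, true
compound het), the association-only gene, a cis pair masquerading as a
compound het, and one decoy per cascade stage (too common, sub-MSC with
mismatched phenotype, off panel, depth at or below the cutoff). The
default template plants a 30 % causal fraction in a 50-patient cohort.

Defaults the data do not dictate, chosen once: background allele
frequencies are log-uniform on [1e-6, 0.5] and CADD scores uniform on
[0, 40]; causal variants score 30–40 (recessive ones draw frequencies
log-uniformly up to 5e-3 to exercise the biallelic-only band); background
variants live in non-panel genes so that a separable template stays
separable. Everything derives from one `numpy` generator seeded from the
config, and outputs are byte-deterministic.

What passing the recovery tests does **not** show: real exomes have far
denser panel-gene backgrounds (hundreds of pre-rarity-filter panel
variants per cohort), annotation errors, population-stratified
frequencies, linkage between nearby variants and incomplete pedigrees.
The generator caricatures exome noise; sensitivity/specificity of 1.0 on
separable synthetic cohorts validates the machinery, not clinical
performance.

## Numerical and format notes

* Positions are 1-based throughout, as in VCF; multi-allelic rows are
  decomposed to one record per alternate allele, and the identity key
  (chrom, pos, ref, alt) must be unique per call set.
* Floats are serialised with 17 significant digits, so sidecar and VCF
  round-trips are exact.
* DP/GQ are read via the FORMAT arrays directly rather than cyvcf2's
  `gt_depths`/`gt_quals` accessors, which conflate a genuine 0 with a
  missing value — a distinction the quality gate depends on.
* Report rows are ordered by (patient, gene, position); decision logs
  preserve cascade order. Both are deterministic.

## Known limitations

* Phenotype matching is tag intersection; it cannot reproduce
  case-by-case expert judgment (e.g. retaining a gene despite a
  discordant cardinal phenotype) except through tag curation.
* No sibling-based or population-based phasing; no mosaicism,
  imprinting, or X-inactivation modelling.
* The frequency gate uses a single global allele frequency per variant;
  per-population frequencies are not modelled.
* Copy-number and structural variation are out of scope; the pipeline
  sees only the small variants present in the VCF.
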