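# Methods

## Scope and model

`drugrank` implements desk-scale, fully reproducible drug prioritization from
a patient's multi-omics alteration profile against a tabular drug–gene
knowledge base. The knowledge base is six plain TSV tables (drugs,
drug–gene associations, gene annotations, genetic-dependency pairs, directed
pathway edges, pharmacogenetic rules) with referential integrity enforced at
load time; storing it as diffable text rather than a database keeps the whole
artifact self-contained and versionable. Live ingestion of external annotation
sources, VEP consequence annotation and full star-allele pharmacogenetics
calling are intentionally out of scope: variants are expected pre-annotated
(INFO keys `GENE`, `CONSEQ`, `DELETERIOUS`, `POPAF`), or are assigned genes
through a caller-supplied interval gene model.

## Gene scoring (GScore)

Each altered gene receives a GScore in [0, 1]:
`min(1, Σ wᵢ·componentᵢ + bonus)` with weights
consequence 0.25, rarity 0.10, essentiality 0.15, druggability 0.25,
clinical 0.25. The additive-with-cap form was one of several defensible
choices (a rule-based tiering was the main alternative); we chose it because
it keeps each component auditable in the output table and makes monotonicity
trivially provable. The weight vector emphasizes druggability and clinical
evidence, which is what ultimately qualifies a gene as a therapeutic handle;
all weights live in the `[gscore]` config block and are re-validated (sum to
1 ± 1e−9) after any override.

Component construction:

- **Consequence / functional impact.** Fixed impact table (frameshift,
  stop-gain, splice 1.0; deleterious missense 0.8; in-frame indel 0.6;
  plain missense 0.5; synonymous/other 0.0). Truncating events in a pure
  oncogene are halved, since loss of function rarely activates an oncogene —
  a modelling choice, exposed in config. Variants with no consequence
  annotation score 0.5 (generic non-synonymous) so unannotated VCFs remain
  usable. Variants with VAF < 0.05 are treated as subclonal and down-weighted
  ×0.8. Non-SNV alterations map onto the same scale: concordant CNV
  (amplified oncogene / deleted suppressor) 0.9, discordant CNV 0.4,
  concordant expression extreme 0.7, discordant 0.2, gene-list entries 0.8
  (the query asserts an actionable alteration without stating it). A gene
  with several alterations takes the **max** impact — a gene is as actionable
  as its strongest alteration; summing would conflate burden with
  actionability.
- **Rarity.** 1 for absent or rare alleles (AF ≤ 1e−4), 0 for common ones
  (AF ≥ 1e−2), log₁₀-linear in between; the max over the gene's variants,
  1.0 when the gene carries no small variant (CNV/expression events have no
  population-frequency concept).
- **Essentiality.** Taken directly from the gene annotation table (unit
  interval, intended as a CRISPR-screen dependency strength).
- **Druggability.** Best-evidence ladder: direct target 1.0 > biomarker
  0.75 > genetic dependency 0.5 > druggable downstream pathway member
  0.25 > none 0.
- **Clinical implication.** Approved biomarker 1.0 / late trials 0.75 /
  early trials 0.5 / preclinical 0.25 / none 0; multiplied by 0.75 when the
  gene's clinical evidence does not cover the queried tumor type (PAN_CANCER
  annotations and `ALL` queries escape the penalty).
- **Concordance bonus.** 0 / 0.1 / 0.2 for one / two / three channels
  altering the gene in the same driver direction (variant always counts; CNV
  and expression only when concordant with the oncogene/suppressor role).

## Drug scoring (DScore)

Each drug–gene(s)-evidence row receives
`DScore = sign · Σ wᵢ·componentᵢ` in [−1, 1], negative for resistance
associations; weights status 0.35, indication 0.20, association class 0.20,
curated support 0.10, collective impact 0.15. Support is `min(1, n/5)` —
linear with saturation, the simplest monotone form given that no functional
shape is prescribed by the evidence. Collective gene impact is a noisy-OR,
`1 − ∏(1 − gᵢ/2)`, over the best effective GScore of each queried gene linked
to the drug: it strictly increases with every additional positively-scored
gene (drugs covering more of the patient's druggable genes are preferred)
with diminishing returns and a hard [0, 1) bound. When a drug carries both
sensitivity and resistance evidence, both rows are emitted rather than
netted; vetoing is left to the reader.

## Prioritization

Association rows fire only when the association's `required_alteration`
pattern matches the gene's alterations (token grammar: SNV, ONCOGENIC_SNV —
any variant with impact ≥ 0.8 —, AMP, DEL, OVEREXPR, UNDEREXPR, ANY).
Genetic-dependency pairs whose context matches emit the dependent gene as a
target of its own direct-target drugs, inheriting the context gene's GScore
×0.9; pathway expansion walks directed edges breadth-first to depth 3 with a
0.75 per-hop decay, visited-set cycle termination, and duplicate emissions
keep the best score. Rows group by (drug, evidence class, response); grouped
support takes the max source count in the group. Ranking sorts by (DScore
desc, best GScore desc, normalized drug name asc) — the name tie-break makes
output files byte-reproducible. BTC flags use strict inequalities
(every per-gene GScore > 0.6 **and** DScore > 0.7); gating on the row's
minimum gene score is the conservative reading for multi-gene rows.

Clinical mode keeps approved/in-trial drugs with direct-target, biomarker or
genetic-dependency evidence, and — when a specific cancer type is queried —
only drugs indicated for that type (or pan-cancer); repurposing options
surface by re-querying with `ALL`. Discovery mode keeps everything, so the
clinical result is always a subset of the discovery result.

## Pharmacogenetics

Germline variants are matched by exact `chrom:pos:ref:alt` key against
single-variant rules with a zygosity requirement (homozygous observations
satisfy a heterozygous requirement; the severity lattice
strongly-not-recommended > moderately-recommended > standard resolves
conflicts). This replaces full diplotype calling, which needs phased
haplotype definitions; the rule schema reserves a star-allele tag for future
extension. Labels are annotations only — they never change scores or order.

## Synthetic data

The fixture generator produces (i) seeded randomized knowledge bases
(default 50 genes / 30 drugs — large enough for ranking ties, small enough
for exhaustive oracles) with random driver roles, essentiality, clinical
levels, association types/patterns, dependency pairs, pathway edges and
pharmacogenetic rules, plus randomized multi-omics patients (8 altered genes,
~80% carrying a variant, 40% a CNV, expression ranks N(0, 3) over the gene
space); and (ii) curated rows reproducing two reference clinical scenarios —
a BRAF-mutant melanoma (direct targeting by vemurafenib; trametinib supported
by biomarkers and by the MAP2K1 dependency in BRAF-mutant tumors; MTOR
repurposing outside skin) and a PIK3CA-mutant breast carcinoma (alpelisib ±
fulvestrant above approved chemotherapies; heterozygous DPYD
decreased-function allele labelling fluoropyrimidines). The generator
emulates the *structure* of real inputs, not their biology: gene symbols,
effect sizes and association patterns are random, so passing tests
demonstrate the scoring laws, ranking contracts and format handling — not
clinical validity of recommendations on real tumors.

## Numerical choices and degenerate inputs

Weights are validated to sum to 1 within 1e−9; score oracles are checked to
1e−12 (plain double-precision sums of ≤ 6 products). Expression classes use
mid-rank percentiles (OVER ≥ 0.90, UNDER ≤ 0.10, configurable); neutral
expression-only genes do not enter the profile. Duplicate CNV calls keep the
last record (warning); duplicate RNK entries keep the extreme |value| at the
first position, first-wins on ties. Empty queries, missing tables, dangling
foreign keys, malformed enums and out-of-range values raise typed errors;
unknown genes score zero essentiality/druggability/clinical rather than
erroring, so partially-annotated inputs degrade gracefully. All randomness
flows through seeded `random.Random` instances; repeated runs are
byte-identical.

## Problem sizes

The randomized verification ensembles use 10,000 scoring contexts per score
and 100 end-to-end prioritizer runs on 40-gene / 25-drug knowledge bases —
sizes at which every invariant is exercised thousands of times while the
whole suite completes in seconds.

## Known limitations

- Consequence/impact tables, score weights, ladder values, the pathway decay
  and the dependency factor are this package's documented defaults, not
  community-calibrated constants; recalibrate via the YAML config for serious
  use.
- No variant normalization beyond multiallelic splitting; no structural
  variants, fusions or phasing.
- Indication matching uses a flat organ-code vocabulary; no histology or
  biomarker-defined sub-indications.
- Resistance evidence is reported alongside sensitivity evidence but does not
  veto it.
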