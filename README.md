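# drugrank

Multi-omics *in silico* drug prioritization for cancer patients.

Tumor sequencing routinely yields long lists of molecular alterations, most of
which are clinically unactionable. `drugrank` helps researchers and molecular
tumor boards interpret such lists: it integrates a patient's somatic and
germline small variants (VCF), gene-level copy-number calls (TSV) and a gene
expression ranking (RNK), scores each altered gene and each candidate drug
against a tabular drug–gene knowledge base, and emits a ranked therapy table
plus a two-section clinical decision report.

## The scores

**GScore** (gene actionability, in [0, 1]) is a weighted sum of five unit
components per gene, plus a multi-omics concordance bonus, capped at 1:

```
GScore = min(1, w_c·consequence + w_f·rarity + w_e·essentiality
              + w_d·druggability + w_l·clinical  +  bonus)
```

with default weights (0.25, 0.10, 0.15, 0.25, 0.25). The consequence component
is the strongest alteration's impact on a fixed [0, 1] scale (e.g. truncating
variant 1.0, deleterious missense 0.8, concordant CNV 0.9); rarity maps the
population allele frequency log-linearly from 1 (AF ≤ 1e−4) to 0 (AF ≥ 1e−2);
druggability ladders over the four evidence classes (direct target 1.0 >
biomarker 0.75 > genetic dependency 0.5 > druggable downstream pathway member
0.25); the bonus (0 / 0.1 / 0.2) rewards two or three omics channels pushing
the same driver direction.

**DScore** (drug suitability, in [−1, 1]) scores each drug–gene(s) association:

```
DScore = sign(response) · ( w_s·status + w_i·indication + w_a·association
                            + w_n·support + w_g·collective )
```

with default weights (0.35, 0.20, 0.20, 0.10, 0.15). Status ladders approved
(1.0) / in trials (0.6) / experimental (0.2); indication is 1.0 for the queried
cancer type, 0.5 for repurposing from another cancer, 0.25 for non-cancer
drugs; support saturates at five curated sources; the collective gene impact
`1 − ∏(1 − gᵢ/2)` over the GScores of the queried genes linked to the drug
rewards drugs that target more druggable genes. Sensitivity associations score
positive, resistance negative.

Rows are ranked by (DScore desc, best GScore desc, drug name) and **Best
Therapeutic Candidates** (BTCs) are rows with every per-gene GScore > 0.6 and
DScore > 0.7 (strict). *Clinical* mode restricts output to approved/in-trial
drugs indicated for the queried tumor type with direct-target, biomarker or
genetic-dependency evidence; *discovery* mode also surfaces experimental drugs
and pathway-member evidence. Germline variants are additionally matched
against a simplified CPIC-style pharmacogenetics rules engine (e.g. a
heterozygous DPYD decreased-function allele labels fluoropyrimidines
"moderately recommended"); labels annotate the table and never re-rank it.

## Worked example

Generate the bundled fixtures (a randomized knowledge base plus curated
melanoma and breast scenarios) and run a clinical-mode multi-omics query for a
BRAF-mutant melanoma patient:

```
drugrank make-fixtures --out demo --seed 1
drugrank query-multiomics --kb demo/kb \
    --vcf-somatic demo/melanoma_patient/somatic.vcf \
    --cnv demo/melanoma_patient/cnv.tsv \
    --rnk demo/melanoma_patient/expr.rnk \
    --cancer-type SKIN --mode clinical --out demo/results
```

`demo/results/report.md` then contains:

```
- Altered genes: 5
- Candidate drugs: 2 (5 drug-gene association rows)
- Best Therapeutic Candidates: 5

| Drug | Status | ... | Actionable variants | Association | DScore |
| TRAMETINIB  | APPROVED | ... | MAP2K1 (EXPR/SNV, GScore 1.000) | DIRECT_TARGET | 0.986 |
| TRAMETINIB  | APPROVED | ... | BRAF (SNV, GScore 0.920); CDKN2A (CNV/EXPR, GScore 0.890); G6PD (EXPR/SNV, GScore 0.787) | BIOMARKER | 0.966 |
| VEMURAFENIB | APPROVED | ... | BRAF (SNV, GScore 0.920) | DIRECT_TARGET | 0.960 |
| TRAMETINIB  | APPROVED | ... | MAP2K1 (SNV, GScore 0.828) | GENETIC_DEPENDENCY | 0.926 |
| VEMURAFENIB | APPROVED | ... | MAP2K1 (EXPR/SNV, GScore 1.000) | BIOMARKER | 0.900 |
```

Reading: the oncogenic BRAF missense mutation is directly targetable by
vemurafenib (GScore 0.92 — deleterious, rare, essential, approved biomarker in
skin); trametinib is supported by its direct target MAP2K1 (mutated *and*
overexpressed, GScore capped at 1.0), by three sensitivity biomarkers, and by
the genetic dependency of MAP2K1 in BRAF-mutant tumors (inherited GScore
0.92 × 0.9 = 0.828). Re-running with `--cancer-type ALL` adds the MTOR
inhibitors everolimus and sirolimus as repurposing options driven by the MTOR
mutation. Machine-readable outputs (`results.tsv`, `report.json`,
`pgx_report.json`) land next to the report.

## Layout

- `src/drugrank/kb.py`, `fixtures.py` — knowledge-base schema, TSV
  persistence, synthetic/curated fixture generation
- `src/drugrank/inputs.py` — VCF / CNV-TSV / RNK / gene-list parsing and
  profile assembly
- `src/drugrank/variant_scoring.py`, `gscore.py`, `dscore.py` — scoring
  engines (all constants overridable via a YAML config, see `--config`)
- `src/drugrank/prioritize.py`, `pgx.py` — evidence classification,
  dependency/pathway expansion, ranking, BTC selection, pharmacogenetics
- `src/drugrank/report.py`, `cli.py` — reports, machine-readable outputs,
  command-line interface
- `docs/methods.md` — model assumptions, parameter rationale and limitations
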