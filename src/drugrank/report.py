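"""Genomic report rendering and machine-readable outputs.

The clinical report has exactly two sections, in order: (i) a summary and
statistical overview of the run, (ii) the complete list of Best
Therapeutic Candidates annotated with approval status, therapy type,
response, drug family, actionable variants and drug–gene association
class.  Markdown, HTML and JSON renderings are byte-stable for a fixed
run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

from .config import ScoringConfig, DEFAULT_CONFIG
from .inputs import PatientProfile
from .kb import KnowledgeBase
from .pgx import PgxRecommendation
from .prioritize import PrioritizedRow, QueryOptions, QueryResult

REPORT_FORMATS = ("markdown", "html", "json")


@dataclass(frozen=True)
class RunSummary:
    n_somatic_variants: int
    n_germline_variants: int
    n_cnv_genes: int
    n_expression_genes: int
    n_assumed_genes: int
    n_altered_genes: int
    n_candidate_drugs: int
    n_rows: int
    n_btc: int
    mode: str
    cancer_type: str
    kb_version: str
    config_digest: str


def summarize(
    result: QueryResult,
    profile: PatientProfile,
    kb: KnowledgeBase,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> RunSummary:
    """Counts derived solely from the profile and the ranked table."""
    evs = profile.genes.values()
    return RunSummary(
        n_somatic_variants=sum(len(e.somatic) for e in evs),
        n_germline_variants=sum(len(e.germline) for e in evs),
        n_cnv_genes=sum(1 for e in evs if e.cnv is not None),
        n_expression_genes=sum(
            1 for e in evs if e.expression_percentile is not None),
        n_assumed_genes=sum(1 for e in evs if e.assumed_altered),
        n_altered_genes=len(profile.altered_genes()),
        n_candidate_drugs=len({r.drug.drug_id for r in result.rows}),
        n_rows=len(result.rows),
        n_btc=len(result.btcs),
        mode=result.options.mode.name,
        cancer_type=result.options.cancer_type,
        kb_version=kb.version,
        config_digest=config.digest(),
    )


def _btc_entry(row: PrioritizedRow) -> dict:
    return {
        "drug": row.drug.name,
        "approval_status": row.drug.clinical_status.name,
        "therapy_type": row.drug.therapy_type.name,
        "response": row.response.name,
        "drug_family": row.drug.family,
        "actionable_variants": [
            {"gene": g.gene, "gscore": round(g.gscore, 6),
             "alterations": sorted(g.flags)}
            for g in row.genes
        ],
        "association_type": row.evidence_class.name,
        "dscore": round(row.dscore, 6),
        "pgx_label": row.pgx_label,
    }


def render_report(
    summary: RunSummary,
    btc_rows: list[PrioritizedRow],
    format: str = "markdown",
) -> str:
    """Render the two-section report in the requested format."""
    if format not in REPORT_FORMATS:
        raise ValueError(
            f"unknown report format {format!r}; expected one of {REPORT_FORMATS}")
    if format == "json":
        payload = {
            "summary": asdict(summary),
            "best_therapeutic_candidates": [_btc_entry(r) for r in btc_rows],
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    lines = ["# Genomic report", "", "## 1. Summary", ""]
    s = summary
    lines += [
        f"- Query mode: {s.mode}, cancer type: {s.cancer_type}",
        f"- Knowledge base version: {s.kb_version} (config {s.config_digest})",
        f"- Input records: {s.n_somatic_variants} somatic variants, "
        f"{s.n_germline_variants} germline variants, {s.n_cnv_genes} CNV genes, "
        f"{s.n_expression_genes} expression-profiled genes, "
        f"{s.n_assumed_genes} gene-list genes",
        f"- Altered genes: {s.n_altered_genes}",
        f"- Candidate drugs: {s.n_candidate_drugs} "
        f"({s.n_rows} drug-gene association rows)",
        f"- Best Therapeutic Candidates: {s.n_btc}",
        "",
        "## 2. Best Therapeutic Candidates",
        "",
    ]
    if not btc_rows:
        lines.append("No Best Therapeutic Candidates were identified.")
    else:
        lines.append(
            "| Drug | Status | Therapy | Response | Family | "
            "Actionable variants | Association | DScore | PGx |")
        lines.append("|---|---|---|---|---|---|---|---|---|")
        for row in btc_rows:
            variants = "; ".join(
                f"{g.gene} ({'/'.join(sorted(g.flags))}, GScore {g.gscore:.3f})"
                for g in row.genes
            )
            lines.append(
                f"| {row.drug.name} | {row.drug.clinical_status.name} | "
                f"{row.drug.therapy_type.name} | {row.response.name} | "
                f"{row.drug.family} | {variants} | {row.evidence_class.name} | "
                f"{row.dscore:.3f} | {row.pgx_label or '-'} |")
    markdown = "\n".join(lines) + "\n"
    if format == "markdown":
        return markdown
    # minimal HTML wrapper around the markdown body
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        "<title>Genomic report</title></head>\n<body>\n<pre>\n"
        + markdown + "</pre>\n</body></html>\n"
    )


# ---------------------------------------------------------------------------
# machine-readable outputs

RESULTS_COLUMNS = [
    "rank", "drug", "status", "family", "therapy_type", "genes",
    "gene_gscores", "evidence_class", "response", "dscore",
    "alteration_flags", "pgx_label", "is_btc",
]


def results_table_tsv(result: QueryResult) -> str:
    """The ranked results table as TSV text (one row per drug-gene(s)
    association, ranking order)."""
    lines = ["\t".join(RESULTS_COLUMNS)]
    for rank, row in enumerate(result.rows, start=1):
        lines.append("\t".join([
            str(rank),
            row.drug.name,
            row.drug.clinical_status.name,
            row.drug.family,
            row.drug.therapy_type.name,
            ",".join(g.gene for g in row.genes),
            ",".join(f"{g.gscore:.6f}" for g in row.genes),
            row.evidence_class.name,
            row.response.name,
            f"{row.dscore:.6f}",
            ",".join(
                f"{g.gene}:{'|'.join(sorted(g.flags))}" for g in row.genes),
            row.pgx_label or "",
            "1" if row.is_btc else "0",
        ]))
    return "\n".join(lines) + "\n"


def pgx_report_json(recommendations: list[PgxRecommendation],
                    kb: KnowledgeBase) -> str:
    """Standalone pharmacogenetics report (machine-readable)."""
    drug_names = {d.drug_id: d.name for d in kb.drugs}
    payload = [
        {
            "drug": drug_names.get(rec.drug_id, rec.drug_id),
            "gene": rec.gene,
            "label": rec.label.name,
            "variant": rec.variant_key,
            "zygosity": rec.zygosity.name,
        }
        for rec in recommendations
    ]
    return json.dumps({"recommendations": payload}, indent=2, sort_keys=True) + "\n"


def write_outputs(
    result: QueryResult,
    profile: PatientProfile,
    kb: KnowledgeBase,
    out_dir: str | Path,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> RunSummary:
    """Write results.tsv, report.md, report.json and pgx_report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = summarize(result, profile, kb, config)
    (out / "results.tsv").write_text(results_table_tsv(result))
    (out / "report.md").write_text(render_report(summary, result.btcs, "markdown"))
    (out / "report.json").write_text(render_report(summary, result.btcs, "json"))
    (out / "pgx_report.json").write_text(pgx_report_json(result.pgx, kb))
    return summary
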