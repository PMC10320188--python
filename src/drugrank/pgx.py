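"""Simplified pharmacogenetics rules engine.

Matches germline variants against single-variant + zygosity rules (a
desk-scale stand-in for full star-allele diplotype calling) and produces
per-drug usage labels in the spirit of CPIC guidance, e.g. a heterozygous
decreased-function DPYD allele labelling fluoropyrimidines "moderately
recommended".  Labels annotate the results table; they never re-rank or
re-score rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterable, Sequence

from .inputs import Genotype, Origin, VariantRecord
from .kb import PgxLabel, PgxRule, Zygosity

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .prioritize import PrioritizedRow

#: severity order: stronger warnings dominate when several rules hit the
#: same drug
LABEL_SEVERITY = {
    PgxLabel.STRONGLY_NOT_RECOMMENDED: 2,
    PgxLabel.MODERATELY_RECOMMENDED: 1,
    PgxLabel.STANDARD: 0,
}


@dataclass(frozen=True)
class PgxRecommendation:
    drug_id: str
    gene: str
    label: PgxLabel
    variant_key: str
    zygosity: Genotype


def _zygosity_satisfied(required: Zygosity, observed: Genotype) -> bool:
    if required is Zygosity.ANY:
        return observed in (Genotype.HET, Genotype.HOM)
    if required is Zygosity.HET:
        # homozygous carriers satisfy a heterozygous requirement (stronger)
        return observed in (Genotype.HET, Genotype.HOM)
    return observed is Genotype.HOM


def match_pgx(
    germline_variants: Iterable[VariantRecord],
    rules: Sequence[PgxRule],
) -> list[PgxRecommendation]:
    """Fire every rule whose variant key and zygosity match; keep the most
    severe label per (drug, gene).  Output order is deterministic and
    independent of variant input order."""
    by_key: dict[str, VariantRecord] = {}
    for v in germline_variants:
        if v.origin is not Origin.GERMLINE:
            continue
        prev = by_key.get(v.key)
        # HOM dominates HET for the same site
        if prev is None or (v.genotype is Genotype.HOM and prev.genotype is not Genotype.HOM):
            by_key[v.key] = v

    best: dict[tuple[str, str], PgxRecommendation] = {}
    for rule in rules:
        variant = by_key.get(rule.variant_key)
        if variant is None:
            continue
        if not _zygosity_satisfied(rule.zygosity_required, variant.genotype):
            continue
        for drug_id in rule.affected_drugs:
            key = (drug_id, rule.gene)
            rec = PgxRecommendation(
                drug_id=drug_id,
                gene=rule.gene,
                label=rule.label,
                variant_key=rule.variant_key,
                zygosity=variant.genotype,
            )
            current = best.get(key)
            if current is None or LABEL_SEVERITY[rec.label] > LABEL_SEVERITY[current.label]:
                best[key] = rec
    return sorted(best.values(), key=lambda r: (r.drug_id, r.gene))


def annotate_rows(
    rows: "Sequence[PrioritizedRow]",
    recommendations: Sequence[PgxRecommendation],
) -> "list[PrioritizedRow]":
    """Fill ``pgx_label`` on rows whose drug has a recommendation.

    Order-preserving and idempotent; the most severe label across genes
    wins for a drug.
    """
    by_drug: dict[str, PgxLabel] = {}
    for rec in recommendations:
        current = by_drug.get(rec.drug_id)
        if current is None or LABEL_SEVERITY[rec.label] > LABEL_SEVERITY[current]:
            by_drug[rec.drug_id] = rec.label
    out = []
    for row in rows:
        label = by_drug.get(row.drug.drug_id)
        out.append(replace(row, pgx_label=label.name if label else None))
    return out
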