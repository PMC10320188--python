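"""Drug prioritization: evidence classification, dependency/pathway
expansion, query modes, ranking and Best Therapeutic Candidate selection.

The pipeline for one query is:

1. score every altered gene in the profile (GScore);
2. collect drug–gene evidence — direct-target and biomarker associations
   whose required alteration matches the gene's alterations, genetic
   dependencies whose context matches, and druggable downstream pathway
   members (discovery mode);
3. group evidence into rows per (drug, evidence class, response), score
   each row (DScore), filter by query mode, sort by (DScore desc, best
   GScore desc, drug name asc);
4. flag Best Therapeutic Candidates: rows whose every per-gene GScore
   exceeds 0.6 and whose DScore exceeds 0.7 (both strict).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

from .config import ScoringConfig, DEFAULT_CONFIG
from .dscore import (
    DScoreBreakdown, association_component, collective_impact,
    compute_dscore, indication_component, status_component, support_component,
)
from .errors import EmptyQueryError
from .gscore import GScoreBreakdown, gscore_for_gene
from .inputs import (
    CnvStatus, ExpressionClass, GeneEvidence, PatientProfile, QueryMode,
)
from .kb import (
    ALL_CANCER_TYPES, AssociationType, ClinicalStatus, DrugEntry,
    KnowledgeBase, Response,
)
from .pgx import PgxRecommendation, annotate_rows, match_pgx
from .prioritize_types import EvidenceClass
from .variant_scoring import variant_impact


@dataclass(frozen=True)
class QueryOptions:
    mode: QueryMode = QueryMode.CLINICAL
    cancer_type: str = ALL_CANCER_TYPES


@dataclass(frozen=True)
class GeneHit:
    """One gene contributing evidence to a drug row."""
    gene: str
    gscore: float  # effective (inherited for derived targets)
    breakdown: GScoreBreakdown
    #: alteration icons: which channels flag this gene (or its context gene
    #: for derived targets)
    flags: frozenset[str]


@dataclass
class PrioritizedRow:
    drug: DrugEntry
    evidence_class: EvidenceClass
    response: Response
    genes: tuple[GeneHit, ...]
    dscore_breakdown: DScoreBreakdown
    pgx_label: str | None = None
    is_btc: bool = False

    @property
    def dscore(self) -> float:
        return self.dscore_breakdown.dscore

    @property
    def best_gscore(self) -> float:
        return max(g.gscore for g in self.genes)

    @property
    def min_gscore(self) -> float:
        return min(g.gscore for g in self.genes)


@dataclass
class QueryResult:
    rows: list[PrioritizedRow]
    btcs: list[PrioritizedRow]
    gene_scores: dict[str, GScoreBreakdown]
    pgx: list[PgxRecommendation]
    options: QueryOptions


# ---------------------------------------------------------------------------
# required-alteration matching

def _has_oncogenic_snv(evidence: GeneEvidence, kb: KnowledgeBase,
                       config: ScoringConfig) -> bool:
    role = kb.annotation(evidence.gene).driver_role
    return any(
        variant_impact(v, role, config) >= config.prioritizer.oncogenic_impact
        for v in evidence.somatic + evidence.germline
    )


def matches_required(
    evidence: GeneEvidence,
    required: str | None,
    kb: KnowledgeBase,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> bool:
    """Does the gene's alteration profile satisfy the association's
    required-alteration pattern?

    Gene-list entries (assumed altered) satisfy every pattern — the query
    asserts the gene is actionably altered without saying how.
    """
    if not evidence.is_altered:
        return False
    if evidence.assumed_altered:
        return True
    if required is None or required == "ANY":
        return True
    if required == "SNV":
        return bool(evidence.somatic or evidence.germline)
    if required == "ONCOGENIC_SNV":
        return _has_oncogenic_snv(evidence, kb, config)
    if required == "AMP":
        return evidence.cnv is CnvStatus.AMP
    if required == "DEL":
        return evidence.cnv is CnvStatus.DEL
    if required == "OVEREXPR":
        return evidence.expression is ExpressionClass.OVER
    if required == "UNDEREXPR":
        return evidence.expression is ExpressionClass.UNDER
    raise ValueError(f"unknown alteration pattern {required!r}")


def _alteration_flags(evidence: GeneEvidence) -> frozenset[str]:
    flags = set()
    if evidence.somatic:
        flags.add("SNV")
    if evidence.germline:
        flags.add("GERMLINE")
    if evidence.cnv is not None:
        flags.add("CNV")
    if evidence.expression in (ExpressionClass.OVER, ExpressionClass.UNDER):
        flags.add("EXPR")
    if evidence.assumed_altered:
        flags.add("ASSUMED")
    return frozenset(flags)


def classify_evidence(
    gene: str,
    profile: PatientProfile,
    kb: KnowledgeBase,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> set[tuple[EvidenceClass, str]]:
    """Evidence classes the altered gene carries, with the linked drugs.

    Only the association-backed classes (direct target, biomarker) are
    assigned here; dependency and pathway classes arise from expansion.
    """
    evidence = profile.genes.get(gene)
    if evidence is None or not evidence.is_altered:
        return set()
    out: set[tuple[EvidenceClass, str]] = set()
    for assoc in kb.associations_for_gene(gene):
        if matches_required(evidence, assoc.required_alteration, kb, config):
            cls = (EvidenceClass.DIRECT_TARGET
                   if assoc.association_type is AssociationType.DIRECT_TARGET
                   else EvidenceClass.BIOMARKER)
            out.add((cls, assoc.drug_id))
    return out


# ---------------------------------------------------------------------------
# derived targets

@dataclass(frozen=True)
class DerivedTarget:
    gene: str  # the druggable target
    evidence_class: EvidenceClass
    source_gene: str  # the altered gene that implied it
    gscore: float  # inherited effective GScore


def expand_dependencies(
    profile: PatientProfile,
    kb: KnowledgeBase,
    gene_scores: dict[str, GScoreBreakdown],
    config: ScoringConfig = DEFAULT_CONFIG,
) -> list[DerivedTarget]:
    """Genetic-dependency targets implied by the profile.

    For each dependency pair whose context gene and alteration match,
    the dependent gene becomes a target inheriting the context gene's
    GScore times the dependency factor.  Duplicate emissions for the same
    dependent gene are merged keeping the best score.
    """
    best: dict[str, DerivedTarget] = {}
    for pair in kb.dependency_pairs:
        evidence = profile.genes.get(pair.context_gene)
        if evidence is None or pair.context_gene not in gene_scores:
            continue
        if not matches_required(evidence, pair.context_alteration, kb, config):
            continue
        score = gene_scores[pair.context_gene].gscore * config.prioritizer.dependency_factor
        current = best.get(pair.dependent_gene)
        if current is None or score > current.gscore:
            best[pair.dependent_gene] = DerivedTarget(
                gene=pair.dependent_gene,
                evidence_class=EvidenceClass.GENETIC_DEPENDENCY,
                source_gene=pair.context_gene,
                gscore=score,
            )
    return sorted(best.values(), key=lambda t: t.gene)


def expand_pathway(
    profile: PatientProfile,
    kb: KnowledgeBase,
    gene_scores: dict[str, GScoreBreakdown],
    config: ScoringConfig = DEFAULT_CONFIG,
) -> list[DerivedTarget]:
    """Druggable downstream pathway members of the altered genes.

    Breadth-first walk along directed pathway edges up to the configured
    depth; every reached gene with a direct-target drug is emitted with
    the source gene's GScore decayed per hop.  Cycles terminate via the
    per-source visited set; duplicates keep the best score.
    """
    adjacency: dict[str, list[str]] = {}
    for e in kb.pathway_edges:
        adjacency.setdefault(e.upstream_gene, []).append(e.downstream_gene)
    decay = config.prioritizer.pathway_decay
    max_depth = config.prioritizer.pathway_max_depth
    best: dict[str, DerivedTarget] = {}
    for source, breakdown in sorted(gene_scores.items()):
        evidence = profile.genes.get(source)
        if evidence is None or not evidence.is_altered:
            continue
        visited = {source}
        queue = deque([(source, 0)])
        while queue:
            node, depth = queue.popleft()
            if depth >= max_depth:
                continue
            for nxt in adjacency.get(node, []):
                if nxt in visited:
                    continue
                visited.add(nxt)
                queue.append((nxt, depth + 1))
                if kb.direct_target_drugs(nxt):
                    score = breakdown.gscore * decay ** (depth + 1)
                    current = best.get(nxt)
                    if current is None or score > current.gscore:
                        best[nxt] = DerivedTarget(
                            gene=nxt,
                            evidence_class=EvidenceClass.PATHWAY_MEMBER,
                            source_gene=source,
                            gscore=score,
                        )
    return sorted(best.values(), key=lambda t: t.gene)


# ---------------------------------------------------------------------------
# row assembly / ranking

def apply_mode(rows: list[PrioritizedRow], options: QueryOptions) -> list[PrioritizedRow]:
    """Query-mode filter.

    Clinical mode keeps clinically applicable rows only: approved or
    in-trial drugs, direct-target/biomarker/genetic-dependency evidence,
    and — when a specific cancer type is queried — drugs indicated for
    that cancer type.  Discovery mode keeps everything, so the clinical
    output is always a subset of the discovery output.
    """
    if options.mode is QueryMode.DISCOVERY:
        return list(rows)
    kept = []
    for row in rows:
        if row.drug.clinical_status not in (
                ClinicalStatus.APPROVED, ClinicalStatus.CLINICAL_TRIAL):
            continue
        if row.evidence_class is EvidenceClass.PATHWAY_MEMBER:
            continue
        if options.cancer_type != ALL_CANCER_TYPES:
            indications = row.drug.indications
            if options.cancer_type not in indications and "PAN_CANCER" not in indications:
                continue
        kept.append(row)
    return kept


def rank_and_select(
    rows: list[PrioritizedRow],
    config: ScoringConfig = DEFAULT_CONFIG,
) -> tuple[list[PrioritizedRow], list[PrioritizedRow]]:
    """Stable sort by (DScore desc, best GScore desc, drug name asc) and
    strict-threshold BTC selection."""
    ranked = sorted(
        rows, key=lambda r: (-r.dscore, -r.best_gscore, r.drug.name)
    )
    pc = config.prioritizer
    out = []
    for row in ranked:
        out.append(replace(
            row,
            is_btc=(row.min_gscore > pc.btc_gscore and row.dscore > pc.btc_dscore),
        ))
    btcs = [r for r in out if r.is_btc]
    return out, btcs


def _build_rows(
    profile: PatientProfile,
    kb: KnowledgeBase,
    options: QueryOptions,
    gene_scores: dict[str, GScoreBreakdown],
    config: ScoringConfig,
) -> list[PrioritizedRow]:
    # (drug_id, class, response) -> {gene: (gscore, breakdown, flags, n_sources)}
    cells: dict[tuple[str, EvidenceClass, Response], dict[str, tuple]] = {}

    def add(drug_id: str, cls: EvidenceClass, response: Response, gene: str,
            gscore: float, breakdown: GScoreBreakdown,
            flags: frozenset[str], n_sources: int) -> None:
        group = cells.setdefault((drug_id, cls, response), {})
        current = group.get(gene)
        if current is None or gscore > current[0]:
            group[gene] = (gscore, breakdown, flags, n_sources)
        elif gscore == current[0]:
            group[gene] = (gscore, breakdown, flags | current[2],
                           max(n_sources, current[3]))

    # association-backed evidence
    for gene in profile.altered_genes():
        evidence = profile.genes[gene]
        breakdown = gene_scores[gene]
        flags = _alteration_flags(evidence)
        for assoc in kb.associations_for_gene(gene):
            if not matches_required(evidence, assoc.required_alteration, kb, config):
                continue
            cls = (EvidenceClass.DIRECT_TARGET
                   if assoc.association_type is AssociationType.DIRECT_TARGET
                   else EvidenceClass.BIOMARKER)
            add(assoc.drug_id, cls, assoc.response, gene,
                breakdown.gscore, breakdown, flags, assoc.n_sources)

    # derived targets: drugs are the derived gene's direct-target drugs
    derived = expand_dependencies(profile, kb, gene_scores, config)
    derived += expand_pathway(profile, kb, gene_scores, config)
    for target in derived:
        source_ev = profile.genes[target.source_gene]
        flags = _alteration_flags(source_ev)
        source_breakdown = gene_scores[target.source_gene]
        for assoc in kb.direct_target_drugs(target.gene):
            add(assoc.drug_id, target.evidence_class, assoc.response,
                target.gene, target.gscore, source_breakdown, flags,
                assoc.n_sources)

    # per-drug collective impact over every linked queried gene (best
    # effective GScore per gene across classes)
    per_drug_gene_best: dict[str, dict[str, float]] = {}
    for (drug_id, _cls, _resp), group in cells.items():
        bucket = per_drug_gene_best.setdefault(drug_id, {})
        for gene, (gscore, *_rest) in group.items():
            bucket[gene] = max(bucket.get(gene, 0.0), gscore)

    rows: list[PrioritizedRow] = []
    for (drug_id, cls, response), group in cells.items():
        drug = kb.drug_by_id(drug_id)
        hits = tuple(
            GeneHit(gene=g, gscore=v[0], breakdown=v[1], flags=v[2])
            for g, v in sorted(group.items())
        )
        breakdown = compute_dscore(
            status=status_component(drug),
            indication=indication_component(drug, options.cancer_type),
            association=association_component(cls),
            support=support_component(max(v[3] for v in group.values()), config),
            collective=collective_impact(per_drug_gene_best[drug_id].values()),
            response=response,
            config=config,
        )
        rows.append(PrioritizedRow(
            drug=drug, evidence_class=cls, response=response,
            genes=hits, dscore_breakdown=breakdown,
        ))
    return rows


def run_query(
    profile: PatientProfile,
    kb: KnowledgeBase,
    options: QueryOptions | None = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> QueryResult:
    """End-to-end, deterministic prioritization of one patient profile."""
    if options is None:
        options = QueryOptions(mode=profile.mode, cancer_type=profile.cancer_type)
    if not profile.genes:
        raise EmptyQueryError("patient profile contains no genes")

    gene_scores = {
        gene: gscore_for_gene(profile.genes[gene], kb, options.cancer_type, config)
        for gene in profile.altered_genes()
    }
    rows = _build_rows(profile, kb, options, gene_scores, config)
    rows = apply_mode(rows, options)
    ranked, btcs = rank_and_select(rows, config)

    germline = [v for ev in profile.genes.values() for v in ev.germline]
    recommendations = match_pgx(germline, kb.pgx_rules)
    ranked = annotate_rows(ranked, recommendations)
    btcs = [r for r in ranked if r.is_btc]

    return QueryResult(
        rows=ranked, btcs=btcs, gene_scores=gene_scores,
        pgx=recommendations, options=options,
    )
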