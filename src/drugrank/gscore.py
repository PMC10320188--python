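"""Gene actionability score (GScore).

The GScore summarizes, per gene and in [0, 1], how relevant and actionable
a gene's alterations are.  It is a weighted sum of five components — the
strongest alteration's biological consequence, the population-frequency
rarity term, cancer-cell-line essentiality, druggability class, and
clinical implication level — plus a small bonus when several omics
channels concordantly alter the gene, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ScoringConfig, DEFAULT_CONFIG
from .errors import ConfigError
from .inputs import CnvStatus, ExpressionClass, GeneEvidence
from .kb import (
    ALL_CANCER_TYPES, AssociationType, ClinicalLevel, DriverRole,
    GeneAnnotation, KnowledgeBase,
)
from .variant_scoring import alteration_inputs, frequency_term

CLINICAL_LEVEL_SCORE = {
    ClinicalLevel.APPROVED_BIOMARKER: 1.0,
    ClinicalLevel.LATE_TRIALS: 0.75,
    ClinicalLevel.EARLY_TRIALS: 0.5,
    ClinicalLevel.PRECLINICAL: 0.25,
    ClinicalLevel.NONE: 0.0,
}

# druggability-class ladder: best available evidence wins
DRUGGABILITY_DIRECT = 1.0
DRUGGABILITY_BIOMARKER = 0.75
DRUGGABILITY_DEPENDENCY = 0.5
DRUGGABILITY_PATHWAY = 0.25


@dataclass(frozen=True)
class GScoreBreakdown:
    consequence_component: float
    frequency_component: float
    essentiality_component: float
    druggability_component: float
    clinical_component: float
    concordance_bonus: float
    gscore: float


def druggability_component(gene: str, kb: KnowledgeBase,
                           config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Best druggability evidence class available for ``gene``:
    direct target (1.0) > biomarker (0.75) > genetic dependency (0.5) >
    druggable downstream pathway member (0.25) > none (0.0)."""
    assoc_types = {a.association_type for a in kb.associations_for_gene(gene)}
    if AssociationType.DIRECT_TARGET in assoc_types:
        return DRUGGABILITY_DIRECT
    if AssociationType.BIOMARKER in assoc_types:
        return DRUGGABILITY_BIOMARKER
    if any(p.dependent_gene == gene for p in kb.dependency_pairs):
        return DRUGGABILITY_DEPENDENCY
    # breadth-first walk downstream looking for any directly-druggable gene
    adjacency: dict[str, list[str]] = {}
    for e in kb.pathway_edges:
        adjacency.setdefault(e.upstream_gene, []).append(e.downstream_gene)
    frontier, visited = [gene], {gene}
    for _ in range(config.prioritizer.pathway_max_depth):
        frontier = [
            nxt for node in frontier for nxt in adjacency.get(node, [])
            if nxt not in visited
        ]
        for node in frontier:
            visited.add(node)
            if kb.direct_target_drugs(node):
                return DRUGGABILITY_PATHWAY
    return 0.0


def clinical_component(annotation: GeneAnnotation, cancer_type: str,
                       config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Clinical-implication ladder, penalized off tumor type."""
    score = CLINICAL_LEVEL_SCORE[annotation.clinical_level]
    if cancer_type != ALL_CANCER_TYPES and score > 0:
        types = annotation.clinical_cancer_types
        if cancer_type not in types and "PAN_CANCER" not in types:
            score *= config.gscore.off_tumor_penalty
    return score


def concordance_bonus(evidence: GeneEvidence, driver_role: DriverRole,
                      config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Bonus for multiple omics channels altering the gene in the same
    driver direction (activation for oncogenes, loss for suppressors).

    Channels: variants, CNV, expression.  A variant of any kind counts;
    CNV and expression count only when concordant with the driver role.
    """
    channels = 0
    if evidence.somatic or evidence.germline or evidence.assumed_altered:
        channels += 1
    activating = driver_role in (DriverRole.ONCOGENE, DriverRole.BOTH)
    losing = driver_role in (DriverRole.TSG, DriverRole.BOTH)
    if (evidence.cnv is CnvStatus.AMP and activating) or (
            evidence.cnv is CnvStatus.DEL and losing):
        channels += 1
    if (evidence.expression is ExpressionClass.OVER and activating) or (
            evidence.expression is ExpressionClass.UNDER and losing):
        channels += 1
    schedule = config.gscore.concordance_bonus
    return schedule[min(channels, len(schedule) - 1)]


def compute_gscore(
    consequence: float,
    frequency: float,
    essentiality: float,
    druggability: float,
    clinical: float,
    bonus: float = 0.0,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> GScoreBreakdown:
    """Weighted combination of the five components plus the concordance
    bonus, capped at 1."""
    weights = config.gscore.weights
    expected = {"consequence", "frequency", "essentiality", "druggability", "clinical"}
    if set(weights) != expected:
        raise ConfigError(f"gscore weights must have keys {sorted(expected)}")
    components = {
        "consequence": consequence,
        "frequency": frequency,
        "essentiality": essentiality,
        "druggability": druggability,
        "clinical": clinical,
    }
    for name, value in components.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"gscore component {name} out of [0,1]: {value}")
    total = sum(weights[k] * components[k] for k in weights) + bonus
    return GScoreBreakdown(
        consequence_component=consequence,
        frequency_component=frequency,
        essentiality_component=essentiality,
        druggability_component=druggability,
        clinical_component=clinical,
        concordance_bonus=bonus,
        gscore=min(1.0, total),
    )


def gscore_for_gene(
    evidence: GeneEvidence,
    kb: KnowledgeBase,
    cancer_type: str,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> GScoreBreakdown:
    """End-to-end GScore for one profiled gene.

    Multiple alterations aggregate by max (a gene is as actionable as its
    strongest alteration); the frequency component is the max rarity term
    over the gene's variants, 1.0 when the gene carries no small variant.
    """
    annotation = kb.annotation(evidence.gene)
    impacts = alteration_inputs(evidence, annotation, config)
    consequence = max((a.impact for a in impacts), default=0.0)
    variants = evidence.somatic + evidence.germline
    frequency = max(
        (frequency_term(v.population_af, config) for v in variants),
        default=1.0,
    )
    return compute_gscore(
        consequence=consequence,
        frequency=frequency,
        essentiality=annotation.essentiality,
        druggability=druggability_component(evidence.gene, kb, config),
        clinical=clinical_component(annotation, cancer_type, config),
        bonus=concordance_bonus(evidence, annotation.driver_role, config),
        config=config,
    )
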