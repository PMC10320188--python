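"""Drug suitability score (DScore).

The DScore summarizes, per drug–gene(s) association and in [−1, 1], how
suitable a drug is for the queried tumor.  Its magnitude is a weighted sum
of five unit components — clinical status, indication match, evidence
class of the drug–gene relationship, curated-source support, and the
collective gene impact — and its sign encodes the response direction:
positive for sensitivity, negative for resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .config import ScoringConfig, DEFAULT_CONFIG
from .errors import ConfigError
from .kb import (
    ALL_CANCER_TYPES, ClinicalStatus, DrugEntry, Response,
)
from .prioritize_types import EvidenceClass

STATUS_SCORE = {
    ClinicalStatus.APPROVED: 1.0,
    ClinicalStatus.CLINICAL_TRIAL: 0.6,
    ClinicalStatus.EXPERIMENTAL: 0.2,
}

ASSOCIATION_SCORE = {
    EvidenceClass.DIRECT_TARGET: 1.0,
    EvidenceClass.BIOMARKER: 0.9,
    EvidenceClass.GENETIC_DEPENDENCY: 0.7,
    EvidenceClass.PATHWAY_MEMBER: 0.5,
}


@dataclass(frozen=True)
class DScoreBreakdown:
    status_component: float
    indication_component: float
    association_component: float
    support_component: float
    collective_impact: float
    response_sign: int  # +1 sensitivity, -1 resistance
    dscore: float


def status_component(drug: DrugEntry) -> float:
    return STATUS_SCORE[drug.clinical_status]


def indication_component(drug: DrugEntry, cancer_type: str) -> float:
    """1.0 when the drug is indicated for the queried cancer type (or the
    query spans all types), 0.5 for repurposing from another cancer
    indication, 0.25 for non-cancer drugs."""
    if not drug.indications:
        return 0.25
    if cancer_type == ALL_CANCER_TYPES:
        return 1.0
    if cancer_type in drug.indications or "PAN_CANCER" in drug.indications:
        return 1.0
    return 0.5


def association_component(evidence_class: EvidenceClass) -> float:
    if evidence_class not in ASSOCIATION_SCORE:
        raise ValueError(f"unknown evidence class {evidence_class!r}")
    return ASSOCIATION_SCORE[evidence_class]


def support_component(n_sources: int,
                      config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Curated-database support: linear in the source count, saturating."""
    if n_sources < 1:
        raise ValueError(f"n_sources must be >= 1, got {n_sources}")
    return min(1.0, n_sources / config.dscore.support_saturation)


def collective_impact(gscores: Iterable[float]) -> float:
    """Collective gene impact: a noisy-OR over the GScores of the queried
    druggable genes linked to the drug, ``1 − ∏(1 − g/2)``.

    Strictly increases with every additional positively-scored gene, so
    drugs targeting more druggable genes are given priority; bounded in
    [0, 1).
    """
    gscores = list(gscores)
    if not gscores:
        raise ValueError("collective_impact requires a non-empty gene set")
    return 1.0 - math.prod(1.0 - g / 2.0 for g in gscores)


def compute_dscore(
    status: float,
    indication: float,
    association: float,
    support: float,
    collective: float,
    response: Response,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> DScoreBreakdown:
    weights = config.dscore.weights
    expected = {"status", "indication", "association", "support", "collective"}
    if set(weights) != expected:
        raise ConfigError(f"dscore weights must have keys {sorted(expected)}")
    components = {
        "status": status,
        "indication": indication,
        "association": association,
        "support": support,
        "collective": collective,
    }
    for name, value in components.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"dscore component {name} out of [0,1]: {value}")
    magnitude = sum(weights[k] * components[k] for k in weights)
    sign = 1 if response is Response.SENSITIVITY else -1
    return DScoreBreakdown(
        status_component=status,
        indication_component=indication,
        association_component=association,
        support_component=support,
        collective_impact=collective,
        response_sign=sign,
        dscore=sign * magnitude,
    )
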