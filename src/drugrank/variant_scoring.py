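"""Per-alteration impact scoring.

Converts each alteration of a gene (SNV consequence, CNV status,
expression deregulation, assumed alteration from a gene-list query) onto a
common [0, 1] impact scale, and maps population allele frequency to a
rarity term.  All constants are read from :class:`VariantScoringConfig`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .config import ScoringConfig, DEFAULT_CONFIG
from .inputs import (
    CnvStatus, ExpressionClass, GeneEvidence, VariantRecord,
)
from .kb import DriverRole, GeneAnnotation

#: consequence terms that truncate the protein product
TRUNCATING_TERMS = frozenset({"frameshift", "stop_gained", "splice"})


class AlterationKind(enum.Enum):
    SNV = "SNV"
    GERMLINE_SNV = "GERMLINE_SNV"
    AMP = "AMP"
    DEL = "DEL"
    OVEREXPR = "OVEREXPR"
    UNDEREXPR = "UNDEREXPR"
    ASSUMED = "ASSUMED"


@dataclass(frozen=True)
class ConsequenceCall:
    term: str
    predicted_deleterious: bool = False


@dataclass(frozen=True)
class AlterationImpact:
    kind: AlterationKind
    impact: float  # in [0, 1]


def consequence_impact(
    call: ConsequenceCall,
    driver_role: DriverRole,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Impact of a coding consequence in [0, 1].

    Truncating consequences in a pure oncogene are down-weighted: loss of
    function rarely activates an oncogene.
    """
    vc = config.variant
    if call.term not in vc.consequence_impact:
        raise ValueError(f"unknown consequence term {call.term!r}")
    if call.term == "missense" and call.predicted_deleterious:
        score = vc.missense_deleterious
    else:
        score = vc.consequence_impact[call.term]
    if call.term in TRUNCATING_TERMS and driver_role is DriverRole.ONCOGENE:
        score *= vc.oncogene_truncating_factor
    return score


def frequency_term(
    population_af: float | None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Rarity term in [0, 1]: 1 for absent/rare alleles, 0 for common ones,
    log-linear in between.  Monotone non-increasing in the allele frequency.
    """
    vc = config.variant
    if population_af is None:
        return 1.0
    if not 0.0 <= population_af <= 1.0:
        raise ValueError(f"population_af out of [0,1]: {population_af}")
    if population_af <= vc.af_rare:
        return 1.0
    if population_af >= vc.af_common:
        return 0.0
    hi, lo = math.log10(vc.af_common), math.log10(vc.af_rare)
    return (hi - math.log10(population_af)) / (hi - lo)


def variant_impact(
    variant: VariantRecord,
    driver_role: DriverRole,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Impact of one variant: consequence impact, down-weighted when the
    variant is subclonal (VAF below the subclonal threshold).  A variant
    without consequence annotation scores the configurable
    ``unannotated_impact`` (generic non-synonymous)."""
    vc = config.variant
    if variant.consequence is None:
        score = vc.unannotated_impact
    else:
        score = consequence_impact(
            ConsequenceCall(variant.consequence, variant.predicted_deleterious),
            driver_role, config,
        )
    if variant.vaf is not None and variant.vaf < vc.subclonal_vaf:
        score *= vc.subclonal_factor
    return score


def alteration_inputs(
    evidence: GeneEvidence,
    annotation: GeneAnnotation,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> list[AlterationImpact]:
    """All per-alteration impacts for one gene, on the shared [0, 1] scale.

    CNV and expression impacts depend on the driver role: an amplified or
    overexpressed oncogene (or a deleted/underexpressed tumor suppressor)
    is a concordant, high-impact event; the opposite direction scores low.
    NEUTRAL or ABSENT expression contributes nothing.
    """
    vc = config.variant
    role = annotation.driver_role
    out: list[AlterationImpact] = []
    for v in evidence.somatic:
        out.append(AlterationImpact(AlterationKind.SNV, variant_impact(v, role, config)))
    for v in evidence.germline:
        out.append(AlterationImpact(
            AlterationKind.GERMLINE_SNV, variant_impact(v, role, config)))
    if evidence.cnv is CnvStatus.AMP:
        amp = vc.amp_oncogene if role in (DriverRole.ONCOGENE, DriverRole.BOTH) else vc.amp_other
        out.append(AlterationImpact(AlterationKind.AMP, amp))
    elif evidence.cnv is CnvStatus.DEL:
        dele = vc.del_tsg if role in (DriverRole.TSG, DriverRole.BOTH) else vc.del_other
        out.append(AlterationImpact(AlterationKind.DEL, dele))
    if evidence.expression is ExpressionClass.OVER:
        concordant = role in (DriverRole.ONCOGENE, DriverRole.BOTH)
        out.append(AlterationImpact(
            AlterationKind.OVEREXPR,
            vc.expr_concordant if concordant else vc.expr_discordant))
    elif evidence.expression is ExpressionClass.UNDER:
        concordant = role in (DriverRole.TSG, DriverRole.BOTH)
        out.append(AlterationImpact(
            AlterationKind.UNDEREXPR,
            vc.expr_concordant if concordant else vc.expr_discordant))
    if evidence.assumed_altered:
        out.append(AlterationImpact(AlterationKind.ASSUMED, vc.assumed_altered))
    return out
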