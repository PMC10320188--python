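"""Scoring configuration.

Every numeric constant used by the scoring engines lives here so users can
re-calibrate without touching code.  A YAML file with the block layout

.. code-block:: yaml

    variant_scoring:
      consequence_impact: {missense: 0.5, ...}
      subclonal_vaf: 0.05
    gscore:
      weights: {consequence: 0.25, frequency: 0.10, ...}
    dscore:
      weights: {status: 0.35, ...}
    prioritizer:
      pathway_max_depth: 3
    expression:
      over_percentile: 0.90

overrides any subset of the defaults (see :func:`load_config`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError

_WEIGHT_TOL = 1e-9


def _check_weights(name: str, weights: Mapping[str, float]) -> None:
    if any(w < 0 for w in weights.values()):
        raise ConfigError(f"{name} weights must be non-negative: {weights}")
    total = sum(weights.values())
    if abs(total - 1.0) > _WEIGHT_TOL:
        raise ConfigError(f"{name} weights must sum to 1 (got {total!r})")


def default_consequence_impact() -> dict[str, float]:
    return {
        "frameshift": 1.0,
        "stop_gained": 1.0,
        "splice": 1.0,
        "missense": 0.5,          # 0.8 when predicted_deleterious
        "inframe_indel": 0.6,
        "synonymous": 0.0,
        "other": 0.0,
    }


@dataclass(frozen=True)
class VariantScoringConfig:
    """Per-alteration impact tables and the rarity curve."""

    consequence_impact: dict[str, float] = field(default_factory=default_consequence_impact)
    missense_deleterious: float = 0.8
    #: loss-of-function in a pure oncogene is rarely activating
    oncogene_truncating_factor: float = 0.5
    #: impact assigned when a variant carries no consequence annotation
    unannotated_impact: float = 0.5
    #: population-AF below which a variant counts as fully rare
    af_rare: float = 1e-4
    #: population-AF above which a variant counts as common (term = 0)
    af_common: float = 1e-2
    #: variants with VAF below this are flagged subclonal
    subclonal_vaf: float = 0.05
    subclonal_factor: float = 0.8
    # non-SNV alterations mapped onto the same [0, 1] impact scale
    amp_oncogene: float = 0.9
    amp_other: float = 0.4
    del_tsg: float = 0.9
    del_other: float = 0.4
    expr_concordant: float = 0.7
    expr_discordant: float = 0.2
    assumed_altered: float = 0.8


@dataclass(frozen=True)
class GScoreConfig:
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "consequence": 0.25,
            "frequency": 0.10,
            "essentiality": 0.15,
            "druggability": 0.25,
            "clinical": 0.25,
        }
    )
    #: bonus schedule indexed by number of concordant altered channels
    concordance_bonus: tuple[float, ...] = (0.0, 0.0, 0.1, 0.2)
    #: penalty applied to the clinical component off-tumor-type
    off_tumor_penalty: float = 0.75

    def __post_init__(self) -> None:
        _check_weights("gscore", self.weights)


@dataclass(frozen=True)
class DScoreConfig:
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "status": 0.35,
            "indication": 0.20,
            "association": 0.20,
            "support": 0.10,
            "collective": 0.15,
        }
    )
    #: number of curated sources at which support saturates
    support_saturation: int = 5

    def __post_init__(self) -> None:
        _check_weights("dscore", self.weights)


@dataclass(frozen=True)
class PrioritizerConfig:
    pathway_max_depth: int = 3
    #: per-hop decay of the inherited GScore along pathway edges
    pathway_decay: float = 0.75
    #: GScore inheritance factor for genetic-dependency targets
    dependency_factor: float = 0.9
    #: strict thresholds for Best Therapeutic Candidates
    btc_gscore: float = 0.6
    btc_dscore: float = 0.7
    #: consequence impact at or above which an SNV counts as oncogenic
    oncogenic_impact: float = 0.8


@dataclass(frozen=True)
class ExpressionConfig:
    over_percentile: float = 0.90
    under_percentile: float = 0.10


@dataclass(frozen=True)
class ScoringConfig:
    variant: VariantScoringConfig = field(default_factory=VariantScoringConfig)
    gscore: GScoreConfig = field(default_factory=GScoreConfig)
    dscore: DScoreConfig = field(default_factory=DScoreConfig)
    prioritizer: PrioritizerConfig = field(default_factory=PrioritizerConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def digest(self) -> str:
        """Stable short hash of the full configuration, echoed in reports."""
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


DEFAULT_CONFIG = ScoringConfig()

_SECTION_MAP = {
    "variant_scoring": ("variant", VariantScoringConfig),
    "gscore": ("gscore", GScoreConfig),
    "dscore": ("dscore", DScoreConfig),
    "prioritizer": ("prioritizer", PrioritizerConfig),
    "expression": ("expression", ExpressionConfig),
}


def load_config(path: str | Path | None) -> ScoringConfig:
    """Load a YAML override file on top of the defaults.

    Unknown sections or keys raise :class:`ConfigError`; weight blocks are
    re-validated after merging.
    """
    if path is None:
        return DEFAULT_CONFIG
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    cfg = ScoringConfig()
    for section, values in raw.items():
        if section not in _SECTION_MAP:
            raise ConfigError(f"unknown config section {section!r}")
        attr, cls = _SECTION_MAP[section]
        current = getattr(cfg, attr)
        fields = {f for f in current.__dataclass_fields__}
        updates = {}
        for key, val in (values or {}).items():
            if key not in fields:
                raise ConfigError(f"unknown key {key!r} in section {section!r}")
            if isinstance(getattr(current, key), dict) and isinstance(val, dict):
                merged = dict(getattr(current, key))
                merged.update(val)
                val = merged
            updates[key] = val
        cfg = replace(cfg, **{attr: replace(current, **updates)})
    return cfg
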