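"""Randomized scoring-context simulation.

Draws large ensembles of synthetic gene and drug–gene association
contexts through the fixture generator and the scoring engines, used to
exercise the score-range and threshold laws (GScore in [0, 1], DScore in
[−1, 1], strict BTC gates) at scale.
"""

from __future__ import annotations

import random

from .config import ScoringConfig, DEFAULT_CONFIG
from .dscore import (
    ASSOCIATION_SCORE, STATUS_SCORE, collective_impact, compute_dscore,
    indication_component, support_component,
)
from .fixtures import generate_fixture_kb, generate_fixture_patient
from .gscore import compute_gscore, gscore_for_gene
from .kb import CANCER_TYPES, ClinicalStatus, DrugEntry, Response, TherapyType
from .prioritize import PrioritizedRow, QueryOptions, run_query
from .prioritize_types import EvidenceClass
from .inputs import QueryMode


def sample_gscores(seed: int, n: int,
                   config: ScoringConfig = DEFAULT_CONFIG) -> list[float]:
    """``n`` GScores from randomized synthetic gene contexts.

    Half the draws are random component vectors fed to the scoring engine
    directly; the other half run the full per-gene pipeline (alteration
    profile -> components -> weighted score) over randomized fixture
    knowledge bases and patients.
    """
    rng = random.Random(seed)
    out: list[float] = []
    bonus_levels = list(config.gscore.concordance_bonus)
    for _ in range(n // 2):
        out.append(compute_gscore(
            rng.random(), rng.random(), rng.random(), rng.random(),
            rng.random(), bonus=rng.choice(bonus_levels), config=config,
        ).gscore)
    kb = generate_fixture_kb(seed=rng.randrange(2**31), n_genes=60, n_drugs=30)
    while len(out) < n:
        profile = generate_fixture_patient(
            kb, seed=rng.randrange(2**31), n_altered=10, config=config)
        cancer_type = rng.choice(CANCER_TYPES + ("ALL",))
        for gene in profile.altered_genes():
            out.append(gscore_for_gene(
                profile.genes[gene], kb, cancer_type, config).gscore)
            if len(out) == n:
                break
    return out


def sample_dscores(seed: int, n: int,
                   config: ScoringConfig = DEFAULT_CONFIG
                   ) -> list[tuple[float, Response]]:
    """``n`` (DScore, response) pairs from randomized association contexts:
    random clinical status, indication scenario, evidence class, curated
    source count, collective-impact gene set and response direction."""
    rng = random.Random(seed)
    out: list[tuple[float, Response]] = []
    somatic_types = [c for c in CANCER_TYPES if c != "PAN_CANCER"]
    for i in range(n):
        drug = DrugEntry(
            drug_id=f"S{i}",
            name=f"SAMPLE{i}",
            family="synthetic",
            clinical_status=rng.choice(list(ClinicalStatus)),
            indications=frozenset(
                rng.sample(somatic_types, k=rng.randint(0, 3))),
            therapy_type=rng.choice(list(TherapyType)),
        )
        cancer_type = rng.choice(somatic_types + ["ALL"])
        response = rng.choice(list(Response))
        gscores = [rng.random() for _ in range(rng.randint(1, 4))]
        breakdown = compute_dscore(
            status=STATUS_SCORE[drug.clinical_status],
            indication=indication_component(drug, cancer_type),
            association=ASSOCIATION_SCORE[rng.choice(list(EvidenceClass))],
            support=support_component(rng.randint(1, 10), config),
            collective=collective_impact(gscores),
            response=response,
            config=config,
        )
        out.append((breakdown.dscore, response))
    return out


def run_randomized_queries(
    base_seed: int,
    n_runs: int,
    n_genes: int = 40,
    n_drugs: int = 25,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> list[PrioritizedRow]:
    """Full prioritizer runs on ``n_runs`` randomized knowledge bases and
    patients (per-run seeds derived from ``base_seed``); returns every
    ranked row across runs."""
    rows: list[PrioritizedRow] = []
    for i in range(1, n_runs + 1):
        seed = (base_seed * 1000 + i) % (2**31)
        kb = generate_fixture_kb(seed=seed, n_genes=n_genes, n_drugs=n_drugs)
        profile = generate_fixture_patient(kb, seed=seed + 7, config=config)
        result = run_query(
            profile, kb, QueryOptions(QueryMode.DISCOVERY, "ALL"), config)
        rows.extend(result.rows)
    return rows
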