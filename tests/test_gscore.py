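"""Gene actionability score: component ladders, weighted combination,
range and monotonicity laws."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from drugrank.config import DEFAULT_CONFIG
from drugrank.errors import ConfigError
from drugrank.gscore import (
    clinical_component, compute_gscore, concordance_bonus,
    druggability_component, gscore_for_gene,
)
from drugrank.inputs import (
    CnvStatus, ExpressionClass, GeneEvidence, Origin, VariantRecord,
)
from drugrank.kb import (
    AssociationType, ClinicalLevel, ClinicalStatus, DependencyPair,
    DriverRole, DrugEntry, DrugGeneAssociation, GeneAnnotation,
    KnowledgeBase, PathwayEdge, Response,
)

unit = st.floats(min_value=0.0, max_value=1.0)


def _mini_kb():
    """A drug targets C; A sits two hops upstream of C; D is a dependency."""
    return KnowledgeBase(
        drugs=[DrugEntry("D1", "drugone", "kinase inhibitor",
                         ClinicalStatus.APPROVED, frozenset({"SKIN"}))],
        associations=[
            DrugGeneAssociation("D1", "C", AssociationType.DIRECT_TARGET,
                                Response.SENSITIVITY, 3),
            DrugGeneAssociation("D1", "E", AssociationType.BIOMARKER,
                                Response.SENSITIVITY, 2),
        ],
        gene_annotations=[GeneAnnotation(g) for g in "ABCDE"],
        dependency_pairs=[DependencyPair("C", "ANY", "D")],
        pathway_edges=[PathwayEdge("A", "B"), PathwayEdge("B", "C")],
    )


class TestDruggabilityLadder:
    def test_direct_target_in_curated_kb(self, curated_kb):
        assert druggability_component("BRAF", curated_kb) == 1.0

    def test_ladder_values(self):
        kb = _mini_kb()
        assert druggability_component("C", kb) == 1.0   # direct target
        assert druggability_component("E", kb) == 0.75  # biomarker
        assert druggability_component("D", kb) == 0.5   # dependency
        assert druggability_component("A", kb) == 0.25  # downstream druggable
        assert druggability_component("B", kb) == 0.25

    def test_unknown_gene_scores_zero(self, curated_kb):
        assert druggability_component("NOSUCHGENE", curated_kb) == 0.0


class TestClinicalLadder:
    @pytest.mark.parametrize("level,expected", [
        (ClinicalLevel.APPROVED_BIOMARKER, 1.0),
        (ClinicalLevel.LATE_TRIALS, 0.75),
        (ClinicalLevel.EARLY_TRIALS, 0.5),
        (ClinicalLevel.PRECLINICAL, 0.25),
        (ClinicalLevel.NONE, 0.0),
    ])
    def test_matching_tumor_type(self, level, expected):
        ann = GeneAnnotation("X", clinical_level=level,
                             clinical_cancer_types=frozenset({"SKIN"}))
        assert clinical_component(ann, "SKIN") == pytest.approx(expected)

    def test_off_tumor_penalty(self):
        ann = GeneAnnotation("X", clinical_level=ClinicalLevel.LATE_TRIALS,
                             clinical_cancer_types=frozenset({"BREAST"}))
        assert clinical_component(ann, "SKIN") == pytest.approx(0.75 * 0.75)

    def test_pan_cancer_and_all_escape_penalty(self):
        pan = GeneAnnotation("X", clinical_level=ClinicalLevel.APPROVED_BIOMARKER,
                             clinical_cancer_types=frozenset({"PAN_CANCER"}))
        assert clinical_component(pan, "SKIN") == 1.0
        other = GeneAnnotation("X", clinical_level=ClinicalLevel.APPROVED_BIOMARKER,
                               clinical_cancer_types=frozenset({"BREAST"}))
        assert clinical_component(other, "ALL") == 1.0


class TestConcordanceBonus:
    def _variant(self, gene):
        return VariantRecord("7", 1, "A", "T", Origin.SOMATIC, gene=gene)

    def test_single_channel_no_bonus(self):
        ev = GeneEvidence("BRAF", somatic=[self._variant("BRAF")])
        assert concordance_bonus(ev, DriverRole.ONCOGENE) == 0.0

    def test_two_concordant_channels(self):
        ev = GeneEvidence("G6PD", somatic=[self._variant("G6PD")],
                          expression=ExpressionClass.OVER)
        assert concordance_bonus(ev, DriverRole.ONCOGENE) == 0.1

    def test_three_concordant_channels(self):
        ev = GeneEvidence("X", somatic=[self._variant("X")],
                          cnv=CnvStatus.AMP, expression=ExpressionClass.OVER)
        assert concordance_bonus(ev, DriverRole.ONCOGENE) == 0.2

    def test_discordant_channels_do_not_count(self):
        # deletion + overexpression of an oncogene: only expression concords
        ev = GeneEvidence("X", somatic=[self._variant("X")],
                          cnv=CnvStatus.DEL, expression=ExpressionClass.OVER)
        assert concordance_bonus(ev, DriverRole.ONCOGENE) == 0.1


class TestComputeGScore:
    def test_extremes(self):
        assert compute_gscore(1, 1, 1, 1, 1).gscore == 1.0
        assert compute_gscore(0, 0, 0, 0, 0).gscore == 0.0

    def test_cap_after_bonus(self):
        # weighted sum 0.97 + bonus 0.1 caps at 1 (from 1.07)
        out = compute_gscore(1.0, 1.0, 0.8, 1.0, 1.0, bonus=0.1)
        assert out.gscore == 1.0

    def test_weighted_combination(self):
        out = compute_gscore(0.8, 1.0, 0.6, 0.75, 0.5)
        expected = 0.25 * 0.8 + 0.10 * 1.0 + 0.15 * 0.6 + 0.25 * 0.75 + 0.25 * 0.5
        assert out.gscore == pytest.approx(expected, abs=1e-12)

    def test_bad_weights_rejected(self):
        from drugrank.config import GScoreConfig
        with pytest.raises(ConfigError):
            GScoreConfig(weights={"consequence": 0.5, "frequency": 0.5,
                                  "essentiality": 0.5, "druggability": 0.0,
                                  "clinical": 0.0})

    @given(unit, unit, unit, unit, unit, st.sampled_from([0.0, 0.1, 0.2]))
    @settings(max_examples=500, derandomize=True)
    def test_range_and_oracle(self, c, f, e, d, cl, bonus):
        """Engine output matches an independent recomputation of the
        weighted sum and respects the [0, 1] range."""
        out = compute_gscore(c, f, e, d, cl, bonus=bonus)
        w = DEFAULT_CONFIG.gscore.weights
        brute = (w["consequence"] * c + w["frequency"] * f
                 + w["essentiality"] * e + w["druggability"] * d
                 + w["clinical"] * cl + bonus)
        assert out.gscore == pytest.approx(min(1.0, brute), abs=1e-12)
        assert 0.0 <= out.gscore <= 1.0

    @given(unit, unit, unit, unit, unit, unit)
    @settings(max_examples=300, derandomize=True)
    def test_monotone_in_each_component(self, c, f, e, d, cl, bump):
        base = compute_gscore(c, f, e, d, cl).gscore
        assert compute_gscore(min(1, c + bump), f, e, d, cl).gscore >= base
        assert compute_gscore(c, min(1, f + bump), e, d, cl).gscore >= base
        assert compute_gscore(c, f, e, min(1, d + bump), cl).gscore >= base


def test_gscore_for_gene_melanoma_braf(curated_kb, melanoma_profile):
    """The oncogenic BRAF mutation in the melanoma profile scores high:
    deleterious missense (0.8), rare, essential, directly druggable and an
    approved biomarker in skin."""
    out = gscore_for_gene(melanoma_profile.genes["BRAF"], curated_kb, "SKIN")
    expected = 0.25 * 0.8 + 0.10 * 1.0 + 0.15 * 0.8 + 0.25 * 1.0 + 0.25 * 1.0
    assert out.gscore == pytest.approx(expected)


def test_gscore_for_gene_randomized_in_range(curated_kb):
    rng = random.Random(0)
    genes = [g.gene for g in curated_kb.gene_annotations]
    for _ in range(200):
        gene = rng.choice(genes)
        ev = GeneEvidence(
            gene,
            somatic=[VariantRecord("1", rng.randint(1, 10**6), "A", "T",
                                   Origin.SOMATIC, gene=gene,
                                   consequence=rng.choice(
                                       ["missense", "stop_gained", "synonymous"]),
                                   population_af=rng.choice(
                                       [None, 10 ** rng.uniform(-5, -1)]))],
            cnv=rng.choice([None, CnvStatus.AMP, CnvStatus.DEL]),
            expression=rng.choice(list(ExpressionClass)),
        )
        out = gscore_for_gene(ev, curated_kb, rng.choice(["SKIN", "ALL"]))
        assert 0.0 <= out.gscore <= 1.0
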