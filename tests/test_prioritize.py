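"""Evidence classification, dependency/pathway expansion, query modes,
ranking and BTC selection."""

import dataclasses
import random

import pytest

from drugrank.config import DEFAULT_CONFIG
from drugrank.dscore import DScoreBreakdown
from drugrank.errors import EmptyQueryError
from drugrank.fixtures import generate_fixture_kb, generate_fixture_patient
from drugrank.gscore import GScoreBreakdown, gscore_for_gene
from drugrank.inputs import (
    CnvRecord, CnvStatus, Origin, QueryMode, VariantRecord, build_profile,
)
from drugrank.kb import (
    AssociationType, ClinicalStatus, DependencyPair, DriverRole, DrugEntry,
    DrugGeneAssociation, GeneAnnotation, KnowledgeBase, PathwayEdge, Response,
)
from drugrank.prioritize import (
    EvidenceClass, GeneHit, PrioritizedRow, QueryOptions, apply_mode,
    classify_evidence, expand_dependencies, expand_pathway, rank_and_select,
    run_query,
)


def _oncogenic_variant(gene, chrom="7", pos=100):
    return VariantRecord(chrom, pos, "A", "T", Origin.SOMATIC, gene=gene,
                         consequence="missense", predicted_deleterious=True)


def _scores(profile, kb, cancer_type="ALL"):
    return {
        g: gscore_for_gene(profile.genes[g], kb, cancer_type)
        for g in profile.altered_genes()
    }


class TestClassifyEvidence:
    def test_braf_direct_target(self, curated_kb, melanoma_profile):
        classes = classify_evidence("BRAF", melanoma_profile, curated_kb)
        assert (EvidenceClass.DIRECT_TARGET, "CUR_VEMURAFENIB") in classes

    def test_map2k1_biomarker_for_vemurafenib(self, curated_kb, melanoma_profile):
        classes = classify_evidence("MAP2K1", melanoma_profile, curated_kb)
        assert (EvidenceClass.BIOMARKER, "CUR_VEMURAFENIB") in classes

    def test_unaltered_gene_empty(self, curated_kb, melanoma_profile):
        assert classify_evidence("PIK3CA", melanoma_profile, curated_kb) == set()

    def test_required_alteration_gates_matching(self, curated_kb):
        # CDKN2A's trametinib biomarker requires a deletion: an SNV alone
        # must not fire it
        profile = build_profile(somatic=[_oncogenic_variant("CDKN2A")])
        assert classify_evidence("CDKN2A", profile, curated_kb) == set()
        profile = build_profile(cnvs=[CnvRecord("CDKN2A", CnvStatus.DEL)])
        assert (EvidenceClass.BIOMARKER, "CUR_TRAMETINIB") in \
            classify_evidence("CDKN2A", profile, curated_kb)


class TestExpandDependencies:
    def test_braf_context_emits_map2k1(self, curated_kb, melanoma_profile):
        scores = _scores(melanoma_profile, curated_kb, "SKIN")
        targets = expand_dependencies(melanoma_profile, curated_kb, scores)
        (t,) = [t for t in targets if t.gene == "MAP2K1"]
        assert t.evidence_class is EvidenceClass.GENETIC_DEPENDENCY
        assert t.gscore == pytest.approx(scores["BRAF"].gscore * 0.9)

    def test_no_context_match_no_emissions(self, curated_kb):
        profile = build_profile(genes=["PIK3CA"])
        scores = _scores(profile, curated_kb)
        # PIK3CA matches no dependency context in the curated kb
        assert expand_dependencies(profile, curated_kb, scores) == []

    def test_two_matching_pairs_merge_keeping_best(self):
        kb = KnowledgeBase(
            drugs=[DrugEntry("D1", "d1", "f", ClinicalStatus.APPROVED,
                             frozenset({"SKIN"}))],
            associations=[DrugGeneAssociation(
                "D1", "T", AssociationType.DIRECT_TARGET,
                Response.SENSITIVITY, 3)],
            gene_annotations=[
                GeneAnnotation("A", driver_role=DriverRole.ONCOGENE,
                               essentiality=0.9),
                GeneAnnotation("B"), GeneAnnotation("T"),
            ],
            dependency_pairs=[DependencyPair("A", "SNV", "T"),
                              DependencyPair("B", "SNV", "T")],
        )
        profile = build_profile(somatic=[
            _oncogenic_variant("A"), _oncogenic_variant("B", pos=200)])
        scores = _scores(profile, kb)
        targets = expand_dependencies(profile, kb, scores)
        assert len(targets) == 1
        best = max(scores["A"].gscore, scores["B"].gscore) * 0.9
        assert targets[0].gscore == pytest.approx(best)


class TestExpandPathway:
    def _chain_kb(self, edges):
        genes = sorted({g for e in edges for g in e})
        return KnowledgeBase(
            drugs=[DrugEntry("D1", "d1", "f", ClinicalStatus.APPROVED,
                             frozenset({"SKIN"}))],
            associations=[DrugGeneAssociation(
                "D1", "C", AssociationType.DIRECT_TARGET,
                Response.SENSITIVITY, 3)],
            gene_annotations=[GeneAnnotation(g) for g in genes],
            pathway_edges=[PathwayEdge(u, v) for u, v in edges],
        )

    def test_depth_two_decay(self):
        kb = self._chain_kb([("A", "B"), ("B", "C")])
        profile = build_profile(somatic=[_oncogenic_variant("A")])
        scores = _scores(profile, kb)
        targets = expand_pathway(profile, kb, scores)
        (t,) = [t for t in targets if t.gene == "C"]
        assert t.gscore == pytest.approx(scores["A"].gscore * 0.75 ** 2)

    def test_no_druggable_descendant_empty(self):
        kb = self._chain_kb([("A", "B")])
        kb.associations = []
        kb.validate()
        profile = build_profile(somatic=[_oncogenic_variant("A")])
        assert expand_pathway(profile, kb, _scores(profile, kb)) == []

    def test_cycle_terminates_without_duplicates(self):
        kb = self._chain_kb([("A", "B"), ("B", "A"), ("B", "C")])
        profile = build_profile(somatic=[_oncogenic_variant("A")])
        targets = expand_pathway(profile, kb, _scores(profile, kb))
        assert [t.gene for t in targets] == ["C"]


def _row(drug, cls, gscore, dscore, response=Response.SENSITIVITY):
    gb = GScoreBreakdown(0, 0, 0, 0, 0, 0, gscore)
    db = DScoreBreakdown(0, 0, 0, 0, 0,
                         1 if response is Response.SENSITIVITY else -1, dscore)
    return PrioritizedRow(
        drug=drug, evidence_class=cls, response=response,
        genes=(GeneHit("GX", gscore, gb, frozenset({"SNV"})),),
        dscore_breakdown=db,
    )


class TestApplyModeAndRanking:
    def _drug(self, status=ClinicalStatus.APPROVED, name="adrug",
              indications=("SKIN",)):
        return DrugEntry(f"D_{name}", name, "f", status, frozenset(indications))

    def test_clinical_drops_experimental_and_pathway(self):
        rows = [
            _row(self._drug(ClinicalStatus.EXPERIMENTAL, "exp"),
                 EvidenceClass.DIRECT_TARGET, 0.9, 0.9),
            _row(self._drug(name="pathway"), EvidenceClass.PATHWAY_MEMBER, 0.9, 0.9),
            _row(self._drug(name="keep"), EvidenceClass.BIOMARKER, 0.9, 0.9),
        ]
        clinical = apply_mode(rows, QueryOptions(QueryMode.CLINICAL, "SKIN"))
        assert [r.drug.name for r in clinical] == ["KEEP"]
        discovery = apply_mode(rows, QueryOptions(QueryMode.DISCOVERY, "SKIN"))
        assert len(discovery) == 3

    def test_clinical_specific_type_requires_indication(self):
        rows = [_row(self._drug(name="offtype", indications=("BREAST",)),
                     EvidenceClass.DIRECT_TARGET, 0.9, 0.9)]
        assert apply_mode(rows, QueryOptions(QueryMode.CLINICAL, "SKIN")) == []
        assert len(apply_mode(rows, QueryOptions(QueryMode.CLINICAL, "ALL"))) == 1

    def test_empty_rows(self):
        assert apply_mode([], QueryOptions(QueryMode.CLINICAL, "ALL")) == []

    def test_sort_key(self):
        rows = [
            _row(self._drug(name="bbb"), EvidenceClass.BIOMARKER, 0.5, 0.8),
            _row(self._drug(name="aaa"), EvidenceClass.BIOMARKER, 0.9, 0.8),
            _row(self._drug(name="ccc"), EvidenceClass.BIOMARKER, 0.9, 0.9),
        ]
        ranked, _ = rank_and_select(rows)
        assert [r.drug.name for r in ranked] == ["CCC", "AAA", "BBB"]

    def test_name_tiebreak(self):
        rows = [
            _row(self._drug(name="zeta"), EvidenceClass.BIOMARKER, 0.9, 0.8),
            _row(self._drug(name="alpha"), EvidenceClass.BIOMARKER, 0.9, 0.8),
        ]
        ranked, _ = rank_and_select(rows)
        assert [r.drug.name for r in ranked] == ["ALPHA", "ZETA"]

    def test_btc_thresholds_strict(self):
        inside = _row(self._drug(name="in"), EvidenceClass.BIOMARKER, 0.8, 0.9)
        g_boundary = _row(self._drug(name="gb"), EvidenceClass.BIOMARKER, 0.6, 0.9)
        d_boundary = _row(self._drug(name="db"), EvidenceClass.BIOMARKER, 0.8, 0.7)
        ranked, btcs = rank_and_select([inside, g_boundary, d_boundary])
        assert {r.drug.name for r in btcs} == {"IN"}
        flagged = {r.drug.name: r.is_btc for r in ranked}
        assert not flagged["GB"] and not flagged["DB"]

    def test_resistance_rows_never_btc(self):
        row = _row(self._drug(name="res"), EvidenceClass.BIOMARKER, 0.9, -0.9,
                   response=Response.RESISTANCE)
        _, btcs = rank_and_select([row])
        assert btcs == []


class TestRunQuery:
    def test_empty_profile_rejected(self, curated_kb):
        from drugrank.inputs import PatientProfile
        empty = PatientProfile(genes={}, cancer_type="ALL",
                               mode=QueryMode.CLINICAL)
        with pytest.raises(EmptyQueryError):
            run_query(empty, curated_kb)

    def test_mode_subset_law(self):
        """Clinical output is a subset of discovery output as
        drug-gene-evidence sets, over randomized fixtures."""
        for seed in range(10):
            kb = generate_fixture_kb(seed=seed, n_genes=30, n_drugs=20)
            profile = generate_fixture_patient(kb, seed=seed + 1000)
            clin = run_query(profile, kb, QueryOptions(QueryMode.CLINICAL, "ALL"))
            disc = run_query(profile, kb, QueryOptions(QueryMode.DISCOVERY, "ALL"))

            def keyset(res):
                return {(r.drug.drug_id, r.evidence_class, r.response,
                         tuple(g.gene for g in r.genes)) for r in res.rows}

            assert keyset(clin) <= keyset(disc)

    def test_permutation_invariance(self, curated_kb, melanoma_files):
        from drugrank import parse_cnv_tsv, parse_rnk, parse_vcf
        from drugrank.report import results_table_tsv
        somatic = parse_vcf(melanoma_files["somatic"], Origin.SOMATIC)
        cnvs = parse_cnv_tsv(melanoma_files["cnv"])
        expr = parse_rnk(melanoma_files["rnk"])
        options = QueryOptions(QueryMode.DISCOVERY, "SKIN")
        baseline = None
        for perm_seed in range(3):
            s, e = list(somatic), list(expr)
            random.Random(perm_seed).shuffle(s)
            random.Random(perm_seed).shuffle(e)
            profile = build_profile(somatic=s, cnvs=cnvs, expr=e,
                                    cancer_type="SKIN")
            table = results_table_tsv(run_query(profile, curated_kb, options))
            if baseline is None:
                baseline = table
            assert table == baseline

    def test_expansion_is_monotone_in_kb_edges(self, melanoma_profile, curated_kb):
        """Adding a dependency pair or pathway edge never shrinks the
        discovery result set."""
        options = QueryOptions(QueryMode.DISCOVERY, "SKIN")
        base = run_query(melanoma_profile, curated_kb, options)
        bigger = dataclasses.replace(curated_kb)
        bigger.dependency_pairs = curated_kb.dependency_pairs + [
            DependencyPair("G6PD", "ANY", "PIK3CA")]
        bigger.pathway_edges = curated_kb.pathway_edges + [
            PathwayEdge("MTOR", "PIK3CA")]
        extended = run_query(melanoma_profile, bigger, options)

        def keyset(res):
            return {(r.drug.drug_id, r.evidence_class, r.response)
                    for r in res.rows}

        assert keyset(base) <= keyset(extended)

    def test_melanoma_btc_genes_all_above_threshold(
            self, curated_kb, melanoma_profile):
        res = run_query(melanoma_profile, curated_kb,
                        QueryOptions(QueryMode.CLINICAL, "SKIN"))
        assert res.btcs
        for row in res.btcs:
            assert row.dscore > 0.7
            assert all(g.gscore > 0.6 for g in row.genes)
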