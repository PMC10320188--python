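"""Synthetic and curated fixture generation.

Two kinds of fixtures are produced, both deterministic for a fixed seed:

* randomized knowledge bases and patient profiles, sized for exhaustive
  desk-scale testing (defaults: 50 genes / 30 drugs, enough for ranking
  ties without defeating brute-force oracles);
* a curated set of hand-written rows reproducing two reference clinical
  scenarios — a BRAF-mutant melanoma (vemurafenib/trametinib, MAP2K1
  dependency, CDKN2A deletion biomarker, MTOR repurposing) and a
  PIK3CA-mutant breast carcinoma (alpelisib alone and combined with
  fulvestrant, approved chemotherapies, and a heterozygous DPYD
  decreased-function allele gating fluoropyrimidines).

Curated patient input files (VCF / CNV TSV / RNK) are written as plain
text so the parsers are exercised end to end.
"""

from __future__ import annotations

import random
from pathlib import Path

from .config import ScoringConfig, DEFAULT_CONFIG
from .inputs import (
    CnvRecord, CnvStatus, ExpressionRecord, Origin, PatientProfile,
    QueryMode, VariantRecord, Genotype, build_profile,
)
from .kb import (
    CANCER_TYPES, AssociationType, ClinicalLevel, ClinicalStatus,
    DependencyPair, DriverRole, DrugEntry, DrugGeneAssociation,
    FunctionEffect, GeneAnnotation, KnowledgeBase, PathwayEdge, PgxLabel,
    PgxRule, Response, TherapyType, Zygosity,
)

_CONSEQUENCE_TERMS = (
    "frameshift", "stop_gained", "splice", "missense", "inframe_indel",
    "synonymous", "other",
)
_FAMILIES = (
    "RAF inhibitor", "MEK inhibitor", "PI3K inhibitor", "kinase inhibitor",
    "antimetabolite", "alkylating agent", "monoclonal antibody",
    "hormone antagonist",
)
_PATTERNS = ("SNV", "ONCOGENIC_SNV", "AMP", "DEL", "OVEREXPR", "UNDEREXPR", "ANY")

#: the DPYD decreased-function site used by the curated breast scenario
DPYD_VARIANT_KEY = "1:97915614:T:C"


# ---------------------------------------------------------------------------
# curated rows

def _curated_gene_annotations() -> list[GeneAnnotation]:
    return [
        GeneAnnotation("BRAF", DriverRole.ONCOGENE, 0.8,
                       ClinicalLevel.APPROVED_BIOMARKER, frozenset({"SKIN"})),
        GeneAnnotation("MAP2K1", DriverRole.ONCOGENE, 0.7,
                       ClinicalLevel.APPROVED_BIOMARKER, frozenset({"SKIN"})),
        GeneAnnotation("G6PD", DriverRole.ONCOGENE, 0.5,
                       ClinicalLevel.EARLY_TRIALS, frozenset({"SKIN"})),
        GeneAnnotation("CDKN2A", DriverRole.TSG, 0.6,
                       ClinicalLevel.LATE_TRIALS, frozenset({"SKIN"})),
        GeneAnnotation("MTOR", DriverRole.ONCOGENE, 0.7,
                       ClinicalLevel.APPROVED_BIOMARKER,
                       frozenset({"KIDNEY", "BREAST"})),
        GeneAnnotation("PIK3CA", DriverRole.ONCOGENE, 0.8,
                       ClinicalLevel.APPROVED_BIOMARKER, frozenset({"BREAST"})),
        GeneAnnotation("DPYD", DriverRole.NONE, 0.0,
                       ClinicalLevel.NONE, frozenset()),
    ]


def _curated_drugs() -> list[DrugEntry]:
    def drug(did, name, family, status, indications, therapy):
        return DrugEntry(did, name, family, status, frozenset(indications), therapy)

    a, c, t = ClinicalStatus.APPROVED, TherapyType.CHEMOTHERAPY, TherapyType.TARGETED
    return [
        drug("CUR_VEMURAFENIB", "vemurafenib", "RAF inhibitor", a, {"SKIN"}, t),
        drug("CUR_TRAMETINIB", "trametinib", "MEK inhibitor", a, {"SKIN"}, t),
        drug("CUR_EVEROLIMUS", "everolimus", "MTOR inhibitor", a,
             {"KIDNEY", "BREAST"}, t),
        drug("CUR_SIROLIMUS", "sirolimus", "MTOR inhibitor", a, {"KIDNEY"}, t),
        drug("CUR_ALPELISIB", "alpelisib", "PI3K inhibitor", a, {"BREAST"}, t),
        drug("CUR_ALPELISIB_FULVESTRANT", "alpelisib + fulvestrant",
             "PI3K inhibitor + ER antagonist", a, {"BREAST"}, t),
        drug("CUR_CAPECITABINE", "capecitabine", "fluoropyrimidine", a,
             {"BREAST", "COLON"}, c),
        drug("CUR_GEMCITABINE", "gemcitabine", "antimetabolite", a,
             {"BREAST", "PANCREAS"}, c),
        drug("CUR_DOCETAXEL", "docetaxel", "taxane", a, {"BREAST", "PROSTATE"}, c),
        drug("CUR_FLUOROURACIL", "fluorouracil", "fluoropyrimidine", a,
             {"BREAST", "COLON"}, c),
    ]


def _curated_associations() -> list[DrugGeneAssociation]:
    D, B = AssociationType.DIRECT_TARGET, AssociationType.BIOMARKER
    S = Response.SENSITIVITY
    rows = [
        ("CUR_VEMURAFENIB", "BRAF", D, S, 5, "ONCOGENIC_SNV"),
        ("CUR_VEMURAFENIB", "MAP2K1", B, S, 3, "SNV"),
        ("CUR_TRAMETINIB", "MAP2K1", D, S, 5, "ANY"),
        ("CUR_TRAMETINIB", "BRAF", B, S, 5, "ONCOGENIC_SNV"),
        ("CUR_TRAMETINIB", "G6PD", B, S, 2, "SNV"),
        ("CUR_TRAMETINIB", "CDKN2A", B, S, 3, "DEL"),
        ("CUR_EVEROLIMUS", "MTOR", D, S, 3, "ONCOGENIC_SNV"),
        ("CUR_SIROLIMUS", "MTOR", D, S, 3, "ONCOGENIC_SNV"),
        ("CUR_ALPELISIB", "PIK3CA", D, S, 5, "ONCOGENIC_SNV"),
        ("CUR_ALPELISIB_FULVESTRANT", "PIK3CA", D, S, 4, "ONCOGENIC_SNV"),
        ("CUR_CAPECITABINE", "PIK3CA", B, S, 3, "SNV"),
        ("CUR_GEMCITABINE", "PIK3CA", B, S, 3, "SNV"),
        ("CUR_DOCETAXEL", "PIK3CA", B, S, 3, "SNV"),
        ("CUR_FLUOROURACIL", "PIK3CA", B, S, 3, "SNV"),
    ]
    return [DrugGeneAssociation(*row) for row in rows]


def _curated_rows(kb: KnowledgeBase) -> None:
    kb.gene_annotations.extend(_curated_gene_annotations())
    kb.drugs.extend(_curated_drugs())
    kb.associations.extend(_curated_associations())
    kb.dependency_pairs.append(
        DependencyPair("BRAF", "ONCOGENIC_SNV", "MAP2K1"))
    kb.pathway_edges.extend([
        PathwayEdge("BRAF", "MAP2K1"),
        PathwayEdge("PIK3CA", "MTOR"),
    ])
    kb.pgx_rules.append(PgxRule(
        gene="DPYD",
        variant_key=DPYD_VARIANT_KEY,
        function_effect=FunctionEffect.DECREASED,
        zygosity_required=Zygosity.HET,
        affected_drugs=frozenset({"CUR_FLUOROURACIL", "CUR_CAPECITABINE"}),
        label=PgxLabel.MODERATELY_RECOMMENDED,
    ))


# ---------------------------------------------------------------------------
# randomized knowledge base

def generate_fixture_kb(
    seed: int,
    n_genes: int = 50,
    n_drugs: int = 30,
    curated: bool = False,
) -> KnowledgeBase:
    """Deterministic randomized knowledge base; ``curated=True`` appends
    the hand-written melanoma/breast scenario rows."""
    if n_genes < 0 or n_drugs < 0:
        raise ValueError("n_genes and n_drugs must be non-negative")
    rng = random.Random(seed)
    somatic_types = [c for c in CANCER_TYPES if c != "PAN_CANCER"]

    genes = [f"G{i:03d}" for i in range(n_genes)]
    gene_annotations = [
        GeneAnnotation(
            gene=g,
            driver_role=rng.choices(
                list(DriverRole), weights=[3, 3, 1, 3])[0],
            essentiality=round(rng.random(), 6),
            clinical_level=rng.choice(list(ClinicalLevel)),
            clinical_cancer_types=frozenset(
                rng.sample(CANCER_TYPES, k=rng.randint(0, 2))),
        )
        for g in genes
    ]

    drugs = []
    for i in range(n_drugs):
        has_cancer_ind = rng.random() < 0.8
        drugs.append(DrugEntry(
            drug_id=f"D{i:03d}",
            name=f"DRUG{i:03d}",
            family=rng.choice(_FAMILIES),
            clinical_status=rng.choices(
                list(ClinicalStatus), weights=[4, 3, 3])[0],
            indications=frozenset(
                rng.sample(somatic_types, k=rng.randint(1, 3))
                if has_cancer_ind else []),
            therapy_type=rng.choice(list(TherapyType)),
        ))

    associations: list[DrugGeneAssociation] = []
    seen: set[tuple] = set()
    if genes:
        for d in drugs:
            for gene in rng.sample(genes, k=min(len(genes), rng.randint(1, 3))):
                atype = rng.choices(list(AssociationType), weights=[2, 3])[0]
                response = rng.choices(list(Response), weights=[4, 1])[0]
                key = (d.drug_id, gene, atype, response)
                if key in seen:
                    continue
                seen.add(key)
                associations.append(DrugGeneAssociation(
                    drug_id=d.drug_id,
                    gene=gene,
                    association_type=atype,
                    response=response,
                    n_sources=rng.randint(1, 8),
                    required_alteration=rng.choice(_PATTERNS + (None,) * 3),
                ))

    dependency_pairs: list[DependencyPair] = []
    if len(genes) >= 2:
        for _ in range(n_genes // 5):
            context, dependent = rng.sample(genes, k=2)
            dependency_pairs.append(DependencyPair(
                context, rng.choice(("SNV", "ONCOGENIC_SNV", "AMP", "DEL", "ANY")),
                dependent))

    pathway_edges: list[PathwayEdge] = []
    if len(genes) >= 2:
        seen_edges: set[tuple[str, str]] = set()
        for _ in range(n_genes):
            up, down = rng.sample(genes, k=2)
            if (up, down) not in seen_edges:
                seen_edges.add((up, down))
                pathway_edges.append(PathwayEdge(up, down))

    pgx_rules: list[PgxRule] = []
    if genes and drugs:
        for i in range(3):
            pgx_rules.append(PgxRule(
                gene=rng.choice(genes),
                variant_key=f"{rng.randint(1, 22)}:{rng.randint(10_000, 9_999_999)}:A:G",
                function_effect=rng.choice(
                    (FunctionEffect.DECREASED, FunctionEffect.NO_FUNCTION)),
                zygosity_required=rng.choice(list(Zygosity)),
                affected_drugs=frozenset(
                    d.drug_id for d in rng.sample(drugs, k=min(len(drugs), 2))),
                label=rng.choice(
                    (PgxLabel.STRONGLY_NOT_RECOMMENDED,
                     PgxLabel.MODERATELY_RECOMMENDED)),
            ))

    kb = KnowledgeBase(
        drugs=drugs,
        associations=associations,
        gene_annotations=gene_annotations,
        dependency_pairs=dependency_pairs,
        pathway_edges=pathway_edges,
        pgx_rules=pgx_rules,
        version=f"fixture-{seed}",
    )
    if curated:
        _curated_rows(kb)
    kb.validate()
    return kb


# ---------------------------------------------------------------------------
# randomized patient profiles

def generate_fixture_patient(
    kb: KnowledgeBase,
    seed: int,
    cancer_type: str = "ALL",
    mode: QueryMode = QueryMode.DISCOVERY,
    n_altered: int = 8,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> PatientProfile:
    """Random multi-omics patient over the knowledge base's gene space."""
    rng = random.Random(seed)
    genes = [g.gene for g in kb.gene_annotations]
    if not genes:
        raise ValueError("knowledge base has no genes to alter")
    altered = rng.sample(genes, k=min(n_altered, len(genes)))

    somatic: list[VariantRecord] = []
    germline: list[VariantRecord] = []
    cnvs: list[CnvRecord] = []
    for i, gene in enumerate(altered):
        channel_draw = rng.random()
        if channel_draw < 0.8:
            origin = Origin.GERMLINE if rng.random() < 0.15 else Origin.SOMATIC
            record = VariantRecord(
                chrom=str(rng.randint(1, 22)),
                pos=10_000 + 137 * i + rng.randint(0, 50),
                ref=rng.choice("ACGT"),
                alt=rng.choice("ACGT"),
                origin=origin,
                genotype=rng.choice((Genotype.HET, Genotype.HOM)),
                vaf=round(rng.uniform(0.02, 0.95), 3),
                gene=gene,
                consequence=rng.choice(_CONSEQUENCE_TERMS),
                predicted_deleterious=rng.random() < 0.5,
                population_af=(
                    None if rng.random() < 0.5
                    else round(10 ** rng.uniform(-5, -1.5), 8)),
            )
            (germline if origin is Origin.GERMLINE else somatic).append(record)
        if rng.random() < 0.4:
            cnvs.append(CnvRecord(gene, rng.choice(list(CnvStatus))))

    expr = [
        ExpressionRecord(gene, round(rng.gauss(0.0, 3.0), 4))
        for gene in genes
    ]
    return build_profile(
        somatic=somatic, germline=germline, cnvs=cnvs, expr=expr,
        genes=[], cancer_type=cancer_type, mode=mode, config=config,
    )


# ---------------------------------------------------------------------------
# curated patient input files

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Consequence term">
##INFO=<ID=DELETERIOUS,Number=0,Type=Flag,Description="Predicted deleterious">
##INFO=<ID=POPAF,Number=A,Type=Float,Description="Population allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=1>
##contig=<ID=3>
##contig=<ID=7>
##contig=<ID=15>
##contig=<ID=X>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPATIENT
"""


def _write_vcf(path: Path, rows: list[str]) -> None:
    path.write_text(_VCF_HEADER + "".join(row + "\n" for row in rows))


def write_melanoma_patient(directory: str | Path) -> dict[str, Path]:
    """Multi-omics inputs for the curated melanoma scenario:
    ``somatic.vcf`` (BRAF, MAP2K1, G6PD, MTOR oncogenic mutations),
    ``cnv.tsv`` (CDKN2A deletion) and ``expr.rnk`` (MAP2K1/G6PD
    overexpressed, CDKN2A underexpressed among 16 neutral background
    genes)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    somatic = directory / "somatic.vcf"
    _write_vcf(somatic, [
        "7\t140453136\t.\tA\tT\t.\tPASS\t"
        "GENE=BRAF;CONSEQ=missense;DELETERIOUS\tGT:AD:DP\t0/1:60,40:100",
        "15\t66727451\t.\tC\tT\t.\tPASS\t"
        "GENE=MAP2K1;CONSEQ=missense;DELETERIOUS\tGT:AD:DP\t0/1:70,30:100",
        "X\t153760484\t.\tG\tA\t.\tPASS\t"
        "GENE=G6PD;CONSEQ=missense;DELETERIOUS\tGT:AD:DP\t0/1:55,45:100",
        "1\t11288758\t.\tT\tC\t.\tPASS\t"
        "GENE=MTOR;CONSEQ=missense;DELETERIOUS\tGT:AD:DP\t0/1:65,35:100",
    ])

    cnv = directory / "cnv.tsv"
    cnv.write_text("gene\tstatus\nCDKN2A\tDEL\n")

    rnk = directory / "expr.rnk"
    lines = ["# melanoma patient expression ranking"]
    lines.append("G6PD\t9.0")
    lines.append("MAP2K1\t8.0")
    for i in range(16):  # neutral background so percentiles are meaningful
        lines.append(f"NTRX{i:02d}\t{6.0 - 0.7 * i:.2f}")
    lines.append("CDKN2A\t-9.0")
    rnk.write_text("\n".join(lines) + "\n")

    return {"somatic": somatic, "cnv": cnv, "rnk": rnk}


def write_breast_patient(directory: str | Path) -> dict[str, Path]:
    """Small-variant inputs for the curated breast scenario:
    ``somatic.vcf`` (oncogenic PIK3CA mutation) and ``germline.vcf``
    (heterozygous DPYD decreased-function variant)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    somatic = directory / "somatic.vcf"
    _write_vcf(somatic, [
        "3\t178936091\t.\tG\tA\t.\tPASS\t"
        "GENE=PIK3CA;CONSEQ=missense;DELETERIOUS\tGT:AD:DP\t0/1:50,50:100",
    ])

    germline = directory / "germline.vcf"
    chrom, pos, ref, alt = DPYD_VARIANT_KEY.split(":")
    _write_vcf(germline, [
        f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
        "GENE=DPYD;CONSEQ=missense;POPAF=0.005\tGT:AD:DP\t0/1:48,52:100",
    ])

    return {"somatic": somatic, "germline": germline}
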