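"""Knowledge-base schema, validation and TSV persistence.

The knowledge base is a directory of six plain TSV tables (UTF-8, header
row, ``#`` comment lines ignored, enums serialized by name)::

    drugs.tsv             drug_id name family clinical_status indications therapy_type
    associations.tsv      drug_id gene association_type response n_sources required_alteration
    gene_annotations.tsv  gene driver_role essentiality clinical_level clinical_cancer_types
    dependencies.tsv      context_gene context_alteration dependent_gene
    pathway_edges.tsv     upstream_gene downstream_gene
    pgx_rules.tsv         gene variant_key function_effect zygosity_required affected_drugs label

Set-valued cells are comma-joined (sorted); empty cells mean "absent".
``load_knowledge_base`` / ``write_knowledge_base`` satisfy the round-trip
law ``load(write(kb)) == kb``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import IntegrityError, MissingTableError, SchemaError

#: flat controlled vocabulary of cancer-type codes; ``ALL`` is a query
#: wildcard, not a member of this list.
CANCER_TYPES = (
    "SKIN", "BREAST", "LUNG", "COLON", "KIDNEY", "BLOOD",
    "PANCREAS", "BRAIN", "OVARY", "PROSTATE", "PAN_CANCER",
)
ALL_CANCER_TYPES = "ALL"


class ClinicalStatus(enum.Enum):
    APPROVED = "APPROVED"
    CLINICAL_TRIAL = "CLINICAL_TRIAL"
    EXPERIMENTAL = "EXPERIMENTAL"


class TherapyType(enum.Enum):
    TARGETED = "TARGETED"
    CHEMOTHERAPY = "CHEMOTHERAPY"
    HORMONAL = "HORMONAL"
    IMMUNOTHERAPY = "IMMUNOTHERAPY"
    OTHER = "OTHER"


class AssociationType(enum.Enum):
    DIRECT_TARGET = "DIRECT_TARGET"
    BIOMARKER = "BIOMARKER"


class Response(enum.Enum):
    SENSITIVITY = "SENSITIVITY"
    RESISTANCE = "RESISTANCE"


class DriverRole(enum.Enum):
    ONCOGENE = "ONCOGENE"
    TSG = "TSG"
    BOTH = "BOTH"
    NONE = "NONE"


class ClinicalLevel(enum.Enum):
    APPROVED_BIOMARKER = "APPROVED_BIOMARKER"
    LATE_TRIALS = "LATE_TRIALS"
    EARLY_TRIALS = "EARLY_TRIALS"
    PRECLINICAL = "PRECLINICAL"
    NONE = "NONE"


class FunctionEffect(enum.Enum):
    NO_FUNCTION = "NO_FUNCTION"
    DECREASED = "DECREASED"
    NORMAL = "NORMAL"


class Zygosity(enum.Enum):
    HET = "HET"
    HOM = "HOM"
    ANY = "ANY"


class PgxLabel(enum.Enum):
    STRONGLY_NOT_RECOMMENDED = "STRONGLY_NOT_RECOMMENDED"
    MODERATELY_RECOMMENDED = "MODERATELY_RECOMMENDED"
    STANDARD = "STANDARD"


#: alteration-pattern tokens accepted in ``required_alteration`` and
#: ``context_alteration`` cells.
ALTERATION_TOKENS = (
    "SNV", "ONCOGENIC_SNV", "AMP", "DEL", "OVEREXPR", "UNDEREXPR", "ANY",
)

_WS = re.compile(r"\s+")


def normalize_drug_name(name: str) -> str:
    """Uppercase, trim and collapse internal whitespace.

    Combination therapies are a single entry whose name joins components
    with `` + `` (e.g. ``ALPELISIB + FULVESTRANT``).
    """
    return _WS.sub(" ", name.strip()).upper()


def normalize_gene(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class DrugEntry:
    drug_id: str
    name: str
    family: str
    clinical_status: ClinicalStatus
    indications: frozenset[str] = frozenset()  # empty = non-cancer indication
    therapy_type: TherapyType = TherapyType.OTHER

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_drug_name(self.name))
        object.__setattr__(self, "indications", frozenset(self.indications))


@dataclass(frozen=True)
class DrugGeneAssociation:
    drug_id: str
    gene: str
    association_type: AssociationType
    response: Response
    n_sources: int
    required_alteration: str | None = None  # pattern token, None = ANY

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise SchemaError(
                f"n_sources must be >= 1 for {self.drug_id}/{self.gene}"
            )
        if self.required_alteration is not None and self.required_alteration not in ALTERATION_TOKENS:
            raise SchemaError(
                f"unknown required_alteration {self.required_alteration!r}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    driver_role: DriverRole = DriverRole.NONE
    essentiality: float = 0.0  # cancer-cell-line dependency strength
    clinical_level: ClinicalLevel = ClinicalLevel.NONE
    clinical_cancer_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.essentiality <= 1.0:
            raise SchemaError(f"essentiality out of [0,1] for {self.gene}")
        object.__setattr__(
            self, "clinical_cancer_types", frozenset(self.clinical_cancer_types)
        )


@dataclass(frozen=True)
class DependencyPair:
    """A genetic dependency: in tumors where ``context_gene`` carries
    ``context_alteration``, ``dependent_gene`` is a selective vulnerability
    (from genome-wide CRISPR loss-of-function screens)."""

    context_gene: str
    context_alteration: str  # pattern token
    dependent_gene: str

    def __post_init__(self) -> None:
        if self.context_gene == self.dependent_gene:
            raise SchemaError(f"dependency self-pair for {self.context_gene}")
        if self.context_alteration not in ALTERATION_TOKENS:
            raise SchemaError(
                f"unknown context_alteration {self.context_alteration!r}"
            )


@dataclass(frozen=True)
class PathwayEdge:
    upstream_gene: str
    downstream_gene: str

    def __post_init__(self) -> None:
        if self.upstream_gene == self.downstream_gene:
            raise SchemaError(f"pathway self-loop at {self.upstream_gene}")


@dataclass(frozen=True)
class PgxRule:
    gene: str
    variant_key: str  # "chrom:pos:ref:alt" or a star-allele tag
    function_effect: FunctionEffect
    zygosity_required: Zygosity
    affected_drugs: frozenset[str]
    label: PgxLabel

    def __post_init__(self) -> None:
        if not self.affected_drugs:
            raise SchemaError(f"pgx rule on {self.gene} affects no drugs")
        object.__setattr__(self, "affected_drugs", frozenset(self.affected_drugs))


@dataclass
class KnowledgeBase:
    drugs: list[DrugEntry] = field(default_factory=list)
    associations: list[DrugGeneAssociation] = field(default_factory=list)
    gene_annotations: list[GeneAnnotation] = field(default_factory=list)
    dependency_pairs: list[DependencyPair] = field(default_factory=list)
    pathway_edges: list[PathwayEdge] = field(default_factory=list)
    pgx_rules: list[PgxRule] = field(default_factory=list)
    version: str = "0"

    # -- lookups -----------------------------------------------------------
    def drug_by_id(self, drug_id: str) -> DrugEntry:
        return self._drug_index()[drug_id]

    def drug_by_name(self, name: str) -> DrugEntry | None:
        norm = normalize_drug_name(name)
        for d in self.drugs:
            if d.name == norm:
                return d
        return None

    def annotation(self, gene: str) -> GeneAnnotation:
        """Annotation for ``gene``; a neutral default row if unknown."""
        return self._gene_index().get(gene, GeneAnnotation(gene=gene))

    def associations_for_gene(self, gene: str) -> list[DrugGeneAssociation]:
        return [a for a in self.associations if a.gene == gene]

    def direct_target_drugs(self, gene: str) -> list[DrugGeneAssociation]:
        return [
            a for a in self.associations
            if a.gene == gene and a.association_type is AssociationType.DIRECT_TARGET
        ]

    def _drug_index(self) -> dict[str, DrugEntry]:
        return {d.drug_id: d for d in self.drugs}

    def _gene_index(self) -> dict[str, GeneAnnotation]:
        return {g.gene: g for g in self.gene_annotations}

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`IntegrityError` on any dangling reference or
        duplicate key."""
        offenders: list[str] = []
        drug_ids = {d.drug_id for d in self.drugs}
        genes = {g.gene for g in self.gene_annotations}

        names = [d.name for d in self.drugs]
        for name in sorted({n for n in names if names.count(n) > 1}):
            offenders.append(f"duplicate drug name {name!r}")
        seen_assoc: set[tuple] = set()
        for a in self.associations:
            key = (a.drug_id, a.gene, a.association_type, a.response)
            if key in seen_assoc:
                offenders.append(f"duplicate association {key}")
            seen_assoc.add(key)
            if a.drug_id not in drug_ids:
                offenders.append(f"association references unknown drug {a.drug_id!r}")
            if a.gene not in genes:
                offenders.append(f"association references unknown gene {a.gene!r}")
        for p in self.dependency_pairs:
            for g in (p.context_gene, p.dependent_gene):
                if g not in genes:
                    offenders.append(f"dependency references unknown gene {g!r}")
        for e in self.pathway_edges:
            for g in (e.upstream_gene, e.downstream_gene):
                if g not in genes:
                    offenders.append(f"pathway edge references unknown gene {g!r}")
        for r in self.pgx_rules:
            if r.gene not in genes:
                offenders.append(f"pgx rule references unknown gene {r.gene!r}")
            for d in r.affected_drugs:
                if d not in drug_ids:
                    offenders.append(f"pgx rule references unknown drug {d!r}")
        if offenders:
            raise IntegrityError(
                "knowledge base failed integrity check:\n  "
                + "\n  ".join(sorted(set(offenders)))
            )


# ---------------------------------------------------------------------------
# TSV persistence

TABLE_FILES = (
    "drugs.tsv",
    "associations.tsv",
    "gene_annotations.tsv",
    "dependencies.tsv",
    "pathway_edges.tsv",
    "pgx_rules.tsv",
)

_VERSION_FILE = "VERSION"


def _join_set(values: frozenset[str]) -> str:
    return ",".join(sorted(values))


def _split_set(cell: str) -> frozenset[str]:
    if not cell:
        return frozenset()
    return frozenset(tok for tok in cell.split(",") if tok)


def _read_table(directory: Path, filename: str, columns: list[str]) -> pd.DataFrame:
    path = directory / filename
    if not path.is_file():
        raise MissingTableError(f"missing knowledge-base table: {filename}")
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{filename}: missing columns {missing}")
    return df


def _parse_enum(cls, cell: str, filename: str, row: int):
    try:
        return cls[cell]
    except KeyError:
        raise SchemaError(
            f"{filename} row {row}: {cell!r} is not a valid {cls.__name__}"
        ) from None


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Load and validate the six-table knowledge base at ``path``."""
    directory = Path(path)
    if not directory.is_dir():
        raise MissingTableError(f"knowledge-base directory not found: {directory}")

    df = _read_table(directory, "drugs.tsv",
                     ["drug_id", "name", "family", "clinical_status",
                      "indications", "therapy_type"])
    drugs = [
        DrugEntry(
            drug_id=r.drug_id,
            name=r.name,
            family=r.family,
            clinical_status=_parse_enum(ClinicalStatus, r.clinical_status, "drugs.tsv", i),
            indications=_split_set(r.indications),
            therapy_type=_parse_enum(TherapyType, r.therapy_type, "drugs.tsv", i),
        )
        for i, r in enumerate(df.itertuples(), start=1)
    ]

    df = _read_table(directory, "associations.tsv",
                     ["drug_id", "gene", "association_type", "response",
                      "n_sources", "required_alteration"])
    associations = []
    for i, r in enumerate(df.itertuples(), start=1):
        try:
            n_sources = int(r.n_sources)
        except ValueError:
            raise SchemaError(
                f"associations.tsv row {i}: n_sources {r.n_sources!r} not an integer"
            ) from None
        associations.append(DrugGeneAssociation(
            drug_id=r.drug_id,
            gene=r.gene,
            association_type=_parse_enum(AssociationType, r.association_type,
                                         "associations.tsv", i),
            response=_parse_enum(Response, r.response, "associations.tsv", i),
            n_sources=n_sources,
            required_alteration=r.required_alteration or None,
        ))

    df = _read_table(directory, "gene_annotations.tsv",
                     ["gene", "driver_role", "essentiality", "clinical_level",
                      "clinical_cancer_types"])
    gene_annotations = [
        GeneAnnotation(
            gene=r.gene,
            driver_role=_parse_enum(DriverRole, r.driver_role,
                                    "gene_annotations.tsv", i),
            essentiality=float(r.essentiality),
            clinical_level=_parse_enum(ClinicalLevel, r.clinical_level,
                                       "gene_annotations.tsv", i),
            clinical_cancer_types=_split_set(r.clinical_cancer_types),
        )
        for i, r in enumerate(df.itertuples(), start=1)
    ]

    df = _read_table(directory, "dependencies.tsv",
                     ["context_gene", "context_alteration", "dependent_gene"])
    dependency_pairs = [
        DependencyPair(r.context_gene, r.context_alteration, r.dependent_gene)
        for r in df.itertuples()
    ]

    df = _read_table(directory, "pathway_edges.tsv",
                     ["upstream_gene", "downstream_gene"])
    pathway_edges = [
        PathwayEdge(r.upstream_gene, r.downstream_gene) for r in df.itertuples()
    ]

    df = _read_table(directory, "pgx_rules.tsv",
                     ["gene", "variant_key", "function_effect",
                      "zygosity_required", "affected_drugs", "label"])
    pgx_rules = [
        PgxRule(
            gene=r.gene,
            variant_key=r.variant_key,
            function_effect=_parse_enum(FunctionEffect, r.function_effect,
                                        "pgx_rules.tsv", i),
            zygosity_required=_parse_enum(Zygosity, r.zygosity_required,
                                          "pgx_rules.tsv", i),
            affected_drugs=_split_set(r.affected_drugs),
            label=_parse_enum(PgxLabel, r.label, "pgx_rules.tsv", i),
        )
        for i, r in enumerate(df.itertuples(), start=1)
    ]

    version_path = directory / _VERSION_FILE
    version = version_path.read_text().strip() if version_path.is_file() else "0"

    kb = KnowledgeBase(
        drugs=drugs,
        associations=associations,
        gene_annotations=gene_annotations,
        dependency_pairs=dependency_pairs,
        pathway_edges=pathway_edges,
        pgx_rules=pgx_rules,
        version=version,
    )
    kb.validate()
    return kb


def write_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    """Write ``kb`` as the six-table TSV directory at ``path``."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "drug_id": d.drug_id,
                "name": d.name,
                "family": d.family,
                "clinical_status": d.clinical_status.name,
                "indications": _join_set(d.indications),
                "therapy_type": d.therapy_type.name,
            }
            for d in kb.drugs
        ],
        columns=["drug_id", "name", "family", "clinical_status",
                 "indications", "therapy_type"],
    ).to_csv(directory / "drugs.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "drug_id": a.drug_id,
                "gene": a.gene,
                "association_type": a.association_type.name,
                "response": a.response.name,
                "n_sources": a.n_sources,
                "required_alteration": a.required_alteration or "",
            }
            for a in kb.associations
        ],
        columns=["drug_id", "gene", "association_type", "response",
                 "n_sources", "required_alteration"],
    ).to_csv(directory / "associations.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "gene": g.gene,
                "driver_role": g.driver_role.name,
                "essentiality": repr(g.essentiality),
                "clinical_level": g.clinical_level.name,
                "clinical_cancer_types": _join_set(g.clinical_cancer_types),
            }
            for g in kb.gene_annotations
        ],
        columns=["gene", "driver_role", "essentiality", "clinical_level",
                 "clinical_cancer_types"],
    ).to_csv(directory / "gene_annotations.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "context_gene": p.context_gene,
                "context_alteration": p.context_alteration,
                "dependent_gene": p.dependent_gene,
            }
            for p in kb.dependency_pairs
        ],
        columns=["context_gene", "context_alteration", "dependent_gene"],
    ).to_csv(directory / "dependencies.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"upstream_gene": e.upstream_gene, "downstream_gene": e.downstream_gene}
            for e in kb.pathway_edges
        ],
        columns=["upstream_gene", "downstream_gene"],
    ).to_csv(directory / "pathway_edges.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "variant_key": r.variant_key,
                "function_effect": r.function_effect.name,
                "zygosity_required": r.zygosity_required.name,
                "affected_drugs": _join_set(r.affected_drugs),
                "label": r.label.name,
            }
            for r in kb.pgx_rules
        ],
        columns=["gene", "variant_key", "function_effect",
                 "zygosity_required", "affected_drugs", "label"],
    ).to_csv(directory / "pgx_rules.tsv", sep="\t", index=False)

    (directory / _VERSION_FILE).write_text(kb.version + "\n")
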