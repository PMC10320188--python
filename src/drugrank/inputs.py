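"""Patient-side input parsing and per-gene profile assembly.

Four input channels are supported and merged into a :class:`PatientProfile`:

* somatic / germline small variants (VCF 4.x, parsed with :mod:`pysam`);
* gene-level copy-number calls (two-column TSV: gene, AMP|DEL);
* a gene-expression ranking (GSEA-style ``.rnk``: gene, signed score);
* a plain gene list (one symbol per line) — such genes enter the profile
  as *assumed altered*.

Variants may be pre-annotated with the INFO keys ``GENE`` (symbol),
``CONSEQ`` (controlled consequence term), ``DELETERIOUS`` (flag) and
``POPAF`` (per-ALT population allele frequency).  Unannotated variants can
be assigned genes through a toy interval gene model supplied by the caller.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .errors import EmptyQueryError, FormatError
from .config import ScoringConfig, DEFAULT_CONFIG
from .kb import normalize_gene

logger = logging.getLogger(__name__)


class Origin(enum.Enum):
    SOMATIC = "SOMATIC"
    GERMLINE = "GERMLINE"


class Genotype(enum.Enum):
    HET = "HET"
    HOM = "HOM"
    UNKNOWN = "UNKNOWN"


class CnvStatus(enum.Enum):
    AMP = "AMP"
    DEL = "DEL"


class ExpressionClass(enum.Enum):
    OVER = "OVER"
    UNDER = "UNDER"
    NEUTRAL = "NEUTRAL"
    ABSENT = "ABSENT"


class QueryMode(enum.Enum):
    CLINICAL = "CLINICAL"
    DISCOVERY = "DISCOVERY"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    origin: Origin
    genotype: Genotype = Genotype.UNKNOWN
    vaf: float | None = None
    gene: str | None = None
    consequence: str | None = None
    predicted_deleterious: bool = False
    population_af: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        for name in ("vaf", "population_af"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise FormatError(f"{name} out of [0,1]: {v}")

    @property
    def key(self) -> str:
        """``chrom:pos:ref:alt`` — matches PgxRule.variant_key."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class CnvRecord:
    gene: str
    status: CnvStatus


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    rank_value: float


@dataclass
class GeneEvidence:
    """Merged multi-channel alteration evidence for one gene."""

    gene: str
    somatic: list[VariantRecord] = field(default_factory=list)
    germline: list[VariantRecord] = field(default_factory=list)
    cnv: CnvStatus | None = None
    expression: ExpressionClass = ExpressionClass.ABSENT
    expression_percentile: float | None = None
    assumed_altered: bool = False

    @property
    def is_altered(self) -> bool:
        return bool(
            self.somatic or self.germline or self.cnv is not None
            or self.expression in (ExpressionClass.OVER, ExpressionClass.UNDER)
            or self.assumed_altered
        )


@dataclass
class PatientProfile:
    genes: dict[str, GeneEvidence]
    cancer_type: str
    mode: QueryMode

    def altered_genes(self) -> list[str]:
        return sorted(g for g, ev in self.genes.items() if ev.is_altered)


# ---------------------------------------------------------------------------
# VCF

GeneModel = Sequence[tuple[str, int, int, str]]  # chrom, start, end (1-based incl.), gene


def _lookup_gene(model: GeneModel | None, chrom: str, pos: int) -> str | None:
    if not model:
        return None
    for mchrom, start, end, gene in model:
        if mchrom == chrom and start <= pos <= end:
            return gene
    return None


def _scalar(value, alt_index: int):
    """Extract the per-ALT element from a pysam INFO value (Number=A)."""
    if isinstance(value, tuple):
        if alt_index < len(value):
            return value[alt_index]
        return value[0]
    return value


def parse_vcf(
    path: str | Path,
    origin: Origin,
    gene_model: GeneModel | None = None,
) -> list[VariantRecord]:
    """Parse a VCF into per-ALT :class:`VariantRecord` s.

    Multiallelic sites are split into one record per ALT allele.  Genotype
    comes from the first sample's GT relative to that allele; VAF from
    AD/DP when present.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    records: list[VariantRecord] = []
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts):
                allele_number = alt_index + 1
                genotype = Genotype.UNKNOWN
                vaf = None
                if rec.samples:
                    sample = rec.samples[0]
                    gt = sample.get("GT")
                    if gt and all(a is not None for a in gt):
                        hits = sum(1 for a in gt if a == allele_number)
                        if hits == len(gt) and hits > 0:
                            genotype = Genotype.HOM
                        elif hits > 0:
                            genotype = Genotype.HET
                    ad = sample.get("AD")
                    if ad is not None and allele_number < len(ad) and ad[allele_number] is not None:
                        depth = sample.get("DP")
                        if depth is None:
                            depth = sum(a for a in ad if a is not None)
                        if depth:
                            vaf = min(1.0, ad[allele_number] / depth)
                info = rec.info
                gene = info.get("GENE")
                if gene is None:
                    gene = _lookup_gene(gene_model, rec.chrom, rec.pos)
                popaf = info.get("POPAF")
                records.append(VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    origin=origin,
                    genotype=genotype,
                    vaf=vaf,
                    gene=normalize_gene(gene) if gene else None,
                    consequence=info.get("CONSEQ"),
                    predicted_deleterious=bool(info.get("DELETERIOUS")),
                    population_af=(
                        float(_scalar(popaf, alt_index)) if popaf is not None else None
                    ),
                ))
    return records


# ---------------------------------------------------------------------------
# CNV TSV

def parse_cnv_tsv(path: str | Path) -> list[CnvRecord]:
    """Parse a two-column ``gene<TAB>status`` TSV; status is AMP or DEL
    (case-insensitive).  A leading header row is detected and skipped.
    Duplicate genes: last status wins, with a warning."""
    records: list[CnvRecord] = []
    seen: dict[str, int] = {}
    first_data_line = True
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path} line {lineno}: expected 2 columns")
            gene, status_token = normalize_gene(parts[0]), parts[1].strip().upper()
            if first_data_line:
                first_data_line = False
                if status_token not in CnvStatus.__members__:
                    continue  # header row
            if status_token not in CnvStatus.__members__:
                raise FormatError(
                    f"{path} line {lineno}: unknown CNV status {parts[1]!r}"
                )
            record = CnvRecord(gene, CnvStatus[status_token])
            if gene in seen:
                logger.warning("duplicate CNV call for %s; keeping the last", gene)
                records[seen[gene]] = record
            else:
                seen[gene] = len(records)
                records.append(record)
    return records


# ---------------------------------------------------------------------------
# RNK

def parse_rnk(path: str | Path) -> list[ExpressionRecord]:
    """Parse a GSEA-style ``.rnk`` file (gene, signed score; ``#`` comments
    ignored).  Duplicate genes keep the extreme-|value| entry at the first
    occurrence's position (first wins on a tie), with a warning."""
    records: list[ExpressionRecord] = []
    seen: dict[str, int] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path} line {lineno}: expected 2 columns")
            gene = normalize_gene(parts[0])
            try:
                value = float(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: non-numeric score {parts[1]!r}"
                ) from None
            if value != value or value in (float("inf"), float("-inf")):
                raise FormatError(f"{path} line {lineno}: non-finite score")
            if gene in seen:
                idx = seen[gene]
                logger.warning("duplicate RNK entry for %s; keeping extreme value", gene)
                if abs(value) > abs(records[idx].rank_value):
                    records[idx] = ExpressionRecord(gene, value)
            else:
                seen[gene] = len(records)
                records.append(ExpressionRecord(gene, value))
    return records


# ---------------------------------------------------------------------------
# Gene list

def parse_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; uppercased, de-duplicated, order preserved."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            symbol = normalize_gene(line)
            if symbol and not symbol.startswith("#") and symbol not in seen:
                seen.add(symbol)
                out.append(symbol)
    return out


# ---------------------------------------------------------------------------
# Profile assembly

def _expression_class(
    percentile: float, config: ScoringConfig
) -> ExpressionClass:
    if percentile >= config.expression.over_percentile:
        return ExpressionClass.OVER
    if percentile <= config.expression.under_percentile:
        return ExpressionClass.UNDER
    return ExpressionClass.NEUTRAL


def build_profile(
    somatic: Iterable[VariantRecord] = (),
    germline: Iterable[VariantRecord] = (),
    cnvs: Iterable[CnvRecord] = (),
    expr: Iterable[ExpressionRecord] = (),
    genes: Iterable[str] = (),
    cancer_type: str = "ALL",
    mode: QueryMode = QueryMode.CLINICAL,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> PatientProfile:
    """Merge all channels into a per-gene :class:`PatientProfile`.

    Expression classes come from the percentile of each gene's rank value
    within the supplied RNK (OVER at/above the 90th, UNDER at/below the
    10th by default).  NEUTRAL expression alone does not create a profile
    entry — a transcriptome-wide ranking would otherwise flood the profile
    with unaltered genes.
    """
    somatic = list(somatic)
    germline = list(germline)
    cnvs = list(cnvs)
    expr = list(expr)
    genes = list(genes)
    if not (somatic or germline or cnvs or expr or genes):
        raise EmptyQueryError("all input channels are empty")

    entries: dict[str, GeneEvidence] = {}

    def entry(gene: str) -> GeneEvidence:
        gene = normalize_gene(gene)
        if gene not in entries:
            entries[gene] = GeneEvidence(gene=gene)
        return entries[gene]

    for rec in sorted(somatic, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        if rec.gene:
            entry(rec.gene).somatic.append(rec)
    for rec in sorted(germline, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        if rec.gene:
            entry(rec.gene).germline.append(rec)
    for rec in cnvs:
        entry(rec.gene).cnv = rec.status
    if expr:
        values = sorted(r.rank_value for r in expr)
        n = len(values)
        for rec in expr:
            # mid-rank percentile in (0, 1]
            below = sum(1 for v in values if v < rec.rank_value)
            ties = sum(1 for v in values if v == rec.rank_value)
            percentile = (below + 0.5 * (ties + 1)) / n if n > 1 else 0.5
            percentile = min(1.0, percentile)
            cls = _expression_class(percentile, config)
            if cls is ExpressionClass.NEUTRAL and rec.gene not in entries:
                continue
            ev = entry(rec.gene)
            ev.expression = cls
            ev.expression_percentile = percentile
    for gene in genes:
        entry(gene).assumed_altered = True

    return PatientProfile(genes=entries, cancer_type=cancer_type, mode=mode)
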