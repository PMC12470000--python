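"""Domain types for de novo variant classification in trio-WGS cohorts.

The central object is :class:`VariantRecord`, one annotated variant
observation in one subject, carrying every input the rule engine needs:
population allele frequencies (two sources, typically gnomAD genomes and
exomes; for mitochondrial variants, homoplasmic and heteroplasmic
frequencies), computational conservation scores (PhyloP, PhastCons), a
manually recorded conservation verdict where the scores disagree, splice
predictor scores, mitochondrial heteroplasmy percentages for subject and
mother, and bookkeeping flags (IGV/SVPlot verification, known-pathogenic
CNV, same-gene companion variant, laboratory report status).

Gene-level evidence lives in :class:`GeneAnnotation`: the published-ASD-
association ladder (A1 strongest direct association, A2, A3, B0 one-degree
indirect, B1-B3 weak/absent), the SFARI confidence score, and whether the
gene is well-established autosomal-recessive-only (a single de novo hit
implies carrier status).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class VariantClass(str, Enum):
    MISSENSE = "missense"
    SILENT = "silent"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    SPLICE = "splice"
    INFRAME_INDEL = "inframe_indel"
    CNV_DUP = "cnv_dup"
    CNV_DEL = "cnv_del"
    ANEUPLOIDY = "aneuploidy"
    RRNA = "rrna"
    UTR = "utr"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"


#: Classes that may span more than one gene symbol.
MULTI_GENE_CLASSES = frozenset(
    {VariantClass.CNV_DUP, VariantClass.CNV_DEL, VariantClass.ANEUPLOIDY}
)

#: Classes counted as altering the amino-acid code of a protein.
CODING_CLASSES = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.SILENT,
        VariantClass.FRAMESHIFT,
        VariantClass.NONSENSE,
        VariantClass.SPLICE,
        VariantClass.INFRAME_INDEL,
        VariantClass.CNV_DUP,
        VariantClass.CNV_DEL,
        VariantClass.ANEUPLOIDY,
    }
)


class Genome(str, Enum):
    NUCLEAR = "nuclear"
    MITO = "mito"


class Inheritance(str, Enum):
    DE_NOVO = "de_novo"
    INHERITED_MATERNAL = "inherited_maternal"
    INHERITED_PATERNAL = "inherited_paternal"
    INHERITED_UNPHASED = "inherited_unphased"


class ManualConservation(str, Enum):
    """Verdict recorded from a manual genome-browser conservation review."""

    HIGH_MAMMALS = "high_mammals"
    HIGH_VERTEBRATES = "high_vertebrates"
    HIGH_AMNIOTES = "high_amniotes"
    LOW_MAMMALS = "low_mammals"
    POOR_ALIGNMENT = "poor_alignment"
    NONE = "none"


class LabReportStatus(str, Enum):
    NOT_LISTED = "not_listed"
    POSITIVE = "positive"
    UNCERTAIN = "uncertain"
    OTHER_VARIANTS = "other_variants"
    SUPPLEMENTARY = "supplementary"
    NEGATIVE = "negative"
    LIKELY_NEGATIVE = "likely_negative"


class GeneCategory(str, Enum):
    A1 = "A1"
    A2 = "A2"
    A3 = "A3"
    B0 = "B0"
    B1 = "B1"
    B2 = "B2"
    B3 = "B3"


#: Ladder order, most direct ASD association first.
CATEGORY_ORDER = [
    GeneCategory.A1,
    GeneCategory.A2,
    GeneCategory.A3,
    GeneCategory.B0,
    GeneCategory.B1,
    GeneCategory.B2,
    GeneCategory.B3,
]


class SfariScore(str, Enum):
    S1 = "1"
    S2 = "2"
    S3 = "3"
    SYNDROMIC = "S"
    NONE = "none"


class Reason(str, Enum):
    """Machine-readable exclusion reasons, in canonical report order."""

    GENE_NOT_ASSOCIATED = "gene_not_associated"
    NOT_CONSERVED = "not_conserved"
    NOT_RARE = "not_rare"
    AR_CARRIER = "ar_carrier"
    HETEROPLASMY_FAIL = "heteroplasmy_fail"
    SPLICE_SCORE_FAIL = "splice_score_fail"
    SILENT_EXCLUDED_BY_MODE = "silent_excluded_by_mode"
    NOT_VERIFIED = "not_verified"
    NONCODING_CLASS = "noncoding_class"


REASON_ORDER = list(Reason)


@dataclass(frozen=True)
class VariantRecord:
    subject_id: str
    gene_symbols: tuple[str, ...]
    variant_class: VariantClass
    genome: Genome = Genome.NUCLEAR
    chromosome: str = ""
    inheritance: Inheritance = Inheritance.DE_NOVO
    allele_freq_1: Optional[float] = None
    allele_freq_2: Optional[float] = None
    phylop: Optional[float] = None
    phastcons: Optional[float] = None
    manual_conservation: ManualConservation = ManualConservation.NONE
    splice_rf: Optional[float] = None
    splice_ada: Optional[float] = None
    heteroplasmy_subject_pct: Optional[float] = None
    heteroplasmy_mother_pct: Optional[float] = None
    verified_real: bool = True
    known_pathogenic_cnv: bool = False
    companion_rare_conserved_variant: bool = False
    lab_report_status: LabReportStatus = LabReportStatus.NOT_LISTED
    possible_mosaic: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.gene_symbols, tuple):
            object.__setattr__(self, "gene_symbols", tuple(self.gene_symbols))

    @property
    def is_de_novo(self) -> bool:
        return self.inheritance is Inheritance.DE_NOVO


@dataclass(frozen=True)
class GeneAnnotation:
    symbol: str
    category: GeneCategory
    sfari_score: SfariScore = SfariScore.NONE
    ar_only: bool = False
    coding: bool = True

    @property
    def is_sfari(self) -> bool:
        return self.sfari_score is not SfariScore.NONE


@dataclass(frozen=True)
class ClassificationResult:
    record: VariantRecord
    is_pdv: bool
    reasons: tuple[Reason, ...]
    rule_trace: tuple[tuple[str, str], ...] = ()
    warnings: tuple[str, ...] = ()


class ClassLabel(str, Enum):
    """Variant classes tallied for SFARI enrichment."""

    DN_MISSENSE_PDV = "dn_missense_pdv"
    DN_SILENT_PDV = "dn_silent_pdv"
    INH_MISSENSE = "inh_missense"
    INH_SILENT = "inh_silent"
    INH_UTR = "inh_utr"
    INH_UPDOWNSTREAM = "inh_updownstream"


@dataclass(frozen=True)
class ClassTally:
    class_label: ClassLabel
    n_subjects: int
    n_variants: int
    n_sfari: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_sfari <= self.n_variants):
            raise ValueError(
                f"{self.class_label.value}: n_sfari ({self.n_sfari}) must lie "
                f"in [0, n_variants={self.n_variants}]"
            )
        if self.n_subjects <= 0 and self.n_variants > 0:
            raise ValueError("variants tallied with zero subjects")

    @property
    def per_subject(self) -> float:
        return self.n_variants / self.n_subjects if self.n_subjects else 0.0

    @property
    def sfari_fraction(self) -> float:
        return self.n_sfari / self.n_variants if self.n_variants else 0.0


class TriState(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SubjectPhenotype:
    subject_id: str
    sex: str = "unknown"
    age_years: Optional[float] = None
    id_moderate_or_worse: TriState = TriState.UNKNOWN
    nonverbal: TriState = TriState.UNKNOWN
    epilepsy: TriState = TriState.UNKNOWN
    regression: TriState = TriState.UNKNOWN
    tics: TriState = TriState.UNKNOWN


# ---------------------------------------------------------------------------
# Non-coding gene-symbol filter
# ---------------------------------------------------------------------------

#: RNA-gene symbol prefixes removed before tallying protein-coding genes.
RNA_GENE_PREFIXES = (
    "LCA", "LINC", "LINP", "LNC", "METAZOA", "MIR", "MIRNA", "PIRNA",
    "PIWIL", "RN7", "RNA", "RNU", "RNV", "RPL", "SNOR", "SNRNA", "TRNA",
    "YRNA",
)

# "U<digits>" is U immediately followed by a digit (U1, U6atac ...), so that
# ordinary coding symbols such as UNKL or USP20 are retained.
_U_RNA_RE = re.compile(r"^U\d")
_ANTISENSE_RE = re.compile(r"AS\d+$")
# Pseudogene suffix: require >=3 leading characters so short symbols are not
# swallowed by the suffix rule.
_PSEUDOGENE_RE = re.compile(r"^.{3,}P\d+$")


def is_noncoding_symbol(symbol: str) -> bool:
    """True if a gene symbol denotes an RNA gene, antisense gene or pseudogene.

    Matching is case-insensitive (symbols are uppercased first). RNA genes
    are recognised by prefix (LCA, LINC, MIR, RNU, SNOR, TRNA, U<digit>, ...),
    antisense genes by an ``AS<digits>`` suffix, pseudogenes by a
    ``P<digits>`` suffix.

    >>> is_noncoding_symbol("MIR21")
    True
    >>> is_noncoding_symbol("SHANK3")
    False
    """
    if not symbol:
        raise ValueError("empty gene symbol")
    s = symbol.upper()
    if any(s.startswith(p) for p in RNA_GENE_PREFIXES):
        return True
    if _U_RNA_RE.match(s):
        return True
    if _ANTISENSE_RE.search(s.replace("-", "")):
        return True
    if _PSEUDOGENE_RE.match(s):
        return True
    return False


def filter_noncoding_symbols(records: list[VariantRecord]) -> list[VariantRecord]:
    """Drop records whose every gene symbol is a non-coding symbol."""
    return [
        r for r in records
        if not all(is_noncoding_symbol(g) for g in r.gene_symbols)
    ]


# ---------------------------------------------------------------------------
# Record validation
# ---------------------------------------------------------------------------

def _in_unit_interval(x: Optional[float]) -> bool:
    return x is None or 0.0 <= x <= 1.0


def validate_record(record: VariantRecord) -> list[str]:
    """Return a list of invariant violations (empty when the record is valid).

    Pure and idempotent: the record is never mutated. Each violation names
    the offending field.
    """
    v: list[str] = []
    if not record.subject_id:
        v.append("subject_id: must be non-empty")
    if len(record.gene_symbols) < 1:
        v.append("gene_symbols: at least one symbol required")
    if (
        len(record.gene_symbols) > 1
        and record.variant_class not in MULTI_GENE_CLASSES
    ):
        v.append(
            "gene_symbols: multiple symbols only allowed for CNV/aneuploidy "
            f"classes, not {record.variant_class.value}"
        )
    for name in ("allele_freq_1", "allele_freq_2", "phastcons",
                 "splice_rf", "splice_ada"):
        if not _in_unit_interval(getattr(record, name)):
            v.append(f"{name}: must lie in [0, 1]")
    for name in ("heteroplasmy_subject_pct", "heteroplasmy_mother_pct"):
        x = getattr(record, name)
        if x is not None and not 0.0 <= x <= 100.0:
            v.append(f"{name}: must lie in [0, 100]")
    if (
        record.genome is Genome.MITO
        and record.is_de_novo
        and record.heteroplasmy_subject_pct is None
    ):
        v.append(
            "heteroplasmy_subject_pct: required for de novo mitochondrial "
            "records"
        )
    if record.genome is Genome.NUCLEAR and (
        record.heteroplasmy_subject_pct is not None
        or record.heteroplasmy_mother_pct is not None
    ):
        v.append("heteroplasmy_subject_pct: only meaningful for mito records")
    return v


__all__ = [
    "VariantClass", "Genome", "Inheritance", "ManualConservation",
    "LabReportStatus", "GeneCategory", "SfariScore", "Reason", "ClassLabel",
    "TriState", "VariantRecord", "GeneAnnotation", "ClassificationResult",
    "ClassTally", "SubjectPhenotype", "CATEGORY_ORDER", "REASON_ORDER",
    "MULTI_GENE_CLASSES", "CODING_CLASSES", "RNA_GENE_PREFIXES",
    "is_noncoding_symbol", "filter_noncoding_symbols", "validate_record",
]
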