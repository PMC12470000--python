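"""Principal Diagnostic Variant (PDV) rule engine.

A de novo variant is called a PDV when it is (i) real — confirmed by manual
read inspection (IGV for small variants, SVPlot for structural ones);
(ii) coding — it alters the amino-acid code; (iii) rare — population
allelic prevalence below 1/10,000, combining the available frequency
sources; (iv) evolutionarily conserved — at least moderately, through
mammals; and (v) in a gene with a published direct (A1–A3) or one-degree
indirect (B0) association with autism. Three special rules modify this:
structural variants that are widely considered Pathogenic are PDVs
regardless of prevalence; a de novo hit in a well-established
autosomal-recessive-only gene indicates carrier status and is excluded
unless a second rare, conserved same-gene variant is present; and de novo
mitochondrial variants are judged by heteroplasmy (subject >=40% and >=2x
the mother's level) rather than by the nuclear rarity/conservation rules.

All rules are evaluated exhaustively, never short-circuited, so exclusion
tallies can be cross-tabulated by full reason combination.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

from .io import CohortBundle
from .model import (
    ClassificationResult,
    GeneAnnotation,
    GeneCategory,
    Genome,
    ManualConservation,
    Reason,
    REASON_ORDER,
    VariantClass,
    VariantRecord,
)


class RuleOutcome(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    EXEMPT = "exempt"


class Conservation(str, Enum):
    CONSERVED = "conserved"
    NOT_CONSERVED = "not_conserved"
    EXEMPT = "exempt"


#: Classes for which nucleotide-level conservation is not scored: the
#: consequence does not hinge on a single conserved base (truncating and
#: synonymous changes, structural variants — a large deletion removes
#: conserved nucleotides by construction).
CONSERVATION_EXEMPT_CLASSES = frozenset({
    VariantClass.SILENT, VariantClass.FRAMESHIFT, VariantClass.NONSENSE,
    VariantClass.CNV_DUP, VariantClass.CNV_DEL, VariantClass.ANEUPLOIDY,
    VariantClass.RRNA,
})

#: Classes that never yield a PDV (not protein-coding consequences).
NONCODING_CLASSES = frozenset({
    VariantClass.UTR, VariantClass.UPSTREAM, VariantClass.DOWNSTREAM,
    VariantClass.RRNA,
})


@dataclass(frozen=True)
class EngineOptions:
    """Thresholds of the classification rules.

    Defaults are the study's operating point: allelic prevalence < 1e-4
    (~population prevalence 2e-4); conservation assumed present when both
    PhyloP and PhastCons exceed 0.7 and absent when both fall below 0.4,
    the recorded manual genome-browser verdict deciding disagreements;
    splice predictors pass above 0.6 on either score; mitochondrial
    heteroplasmy passes at subject >=40% and >=2x the maternal percentage.
    """

    include_silent: bool = True
    freq_threshold: float = 1e-4
    cons_high: float = 0.7
    cons_low: float = 0.4
    splice_threshold: float = 0.6
    het_min_pct: float = 40.0
    het_ratio: float = 2.0
    manual_conservation_accepts: frozenset[ManualConservation] = frozenset({
        ManualConservation.HIGH_MAMMALS,
        ManualConservation.HIGH_VERTEBRATES,
        ManualConservation.HIGH_AMNIOTES,
    })
    eligible_categories: frozenset[GeneCategory] = frozenset({
        GeneCategory.A1, GeneCategory.A2, GeneCategory.A3, GeneCategory.B0,
    })
    strict_gene_resolution: bool = True

    def __post_init__(self) -> None:
        if self.cons_low > self.cons_high:
            raise ValueError("cons_low must not exceed cons_high")
        for name in ("freq_threshold", "splice_threshold", "het_min_pct",
                     "het_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _options_from_mapping(data: Mapping) -> "EngineOptions":
    kwargs: dict = {}
    simple = ("include_silent", "freq_threshold", "cons_high", "cons_low",
              "splice_threshold", "het_min_pct", "het_ratio",
              "strict_gene_resolution")
    for key in simple:
        if key in data:
            kwargs[key] = data[key]
    if "manual_conservation_accepts" in data:
        kwargs["manual_conservation_accepts"] = frozenset(
            ManualConservation(v) for v in data["manual_conservation_accepts"])
    if "eligible_categories" in data:
        kwargs["eligible_categories"] = frozenset(
            GeneCategory(v) for v in data["eligible_categories"])
    unknown = set(data) - set(simple) - {"manual_conservation_accepts",
                                         "eligible_categories"}
    if unknown:
        raise ValueError(f"unknown engine option(s): {sorted(unknown)}")
    return EngineOptions(**kwargs)


def load_options(path) -> "EngineOptions":
    """Read engine options from a TOML file (top level or an ``[engine]``
    table); unspecified keys keep their defaults."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return _options_from_mapping(data.get("engine", data))


DEFAULT_OPTIONS = EngineOptions()


class UnresolvedGeneError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Individual rules
# ---------------------------------------------------------------------------

def assess_rarity(
    af1: Optional[float],
    af2: Optional[float],
    known_pathogenic_cnv: bool = False,
    options: EngineOptions = DEFAULT_OPTIONS,
) -> tuple[RuleOutcome, Optional[str]]:
    """Population-rarity rule.

    A variant widely considered Pathogenic passes regardless of prevalence.
    Otherwise the combined prevalence over the available sources (the mean
    of the frequencies present) must be strictly below the threshold —
    combining sources this way reproduces the recorded borderline outcomes
    (a variant at 0.99e-4/1.4e-4 combined 1.2e-4 fails; one at
    0.85e-4/1.1e-4 combined 0.98e-4 passes). With no frequency observed at
    all the outcome is indeterminate and treated as pass with a warning.
    """
    if known_pathogenic_cnv:
        return RuleOutcome.PASS, None
    present = [f for f in (af1, af2) if f is not None]
    if not present:
        return RuleOutcome.PASS, "no population frequency available; rarity indeterminate"
    combined = sum(present) / len(present)
    if combined < options.freq_threshold:
        return RuleOutcome.PASS, None
    return RuleOutcome.FAIL, None


def assess_conservation(
    variant_class: VariantClass,
    phylop: Optional[float],
    phastcons: Optional[float],
    manual: ManualConservation = ManualConservation.NONE,
    options: EngineOptions = DEFAULT_OPTIONS,
) -> tuple[Conservation, Optional[str]]:
    """Evolutionary-conservation rule for single-nucleotide consequences.

    Truncating, synonymous and structural classes are exempt. For
    missense/splice/in-frame classes: conserved when both PhyloP and
    PhastCons exceed ``cons_high``; not conserved when both fall below
    ``cons_low``; otherwise the recorded manual genome-browser verdict
    decides (no verdict with disagreeing scores counts as not conserved,
    with a warning).
    """
    if variant_class in CONSERVATION_EXEMPT_CLASSES:
        return Conservation.EXEMPT, None
    if variant_class in NONCODING_CLASSES:
        return Conservation.EXEMPT, None
    both_present = phylop is not None and phastcons is not None
    if both_present:
        if phylop > options.cons_high and phastcons > options.cons_high:
            return Conservation.CONSERVED, None
        if phylop < options.cons_low and phastcons < options.cons_low:
            return Conservation.NOT_CONSERVED, None
    if manual in options.manual_conservation_accepts:
        return Conservation.CONSERVED, None
    if manual is ManualConservation.NONE:
        return (Conservation.NOT_CONSERVED,
                "conservation scores inconclusive and no manual verdict "
                "recorded; treated as not conserved")
    return Conservation.NOT_CONSERVED, None


def assess_gene(
    annotations: Sequence[GeneAnnotation],
    options: EngineOptions = DEFAULT_OPTIONS,
) -> RuleOutcome:
    """Gene-association rule: eligible iff any spanned gene's category is
    published directly (A1–A3) or one-degree-indirectly (B0) ASD-associated.
    """
    if not annotations:
        raise ValueError("at least one gene annotation required")
    if any(a.category in options.eligible_categories for a in annotations):
        return RuleOutcome.PASS
    return RuleOutcome.FAIL


def assess_ar(gene: GeneAnnotation, companion_flag: bool = False) -> RuleOutcome:
    """Autosomal-recessive carrier rule: a single de novo hit in an AR-only
    gene indicates carrier status unless a second rare conserved same-gene
    variant is recorded (phase possibly unknown)."""
    if gene.ar_only and not companion_flag:
        return RuleOutcome.FAIL
    return RuleOutcome.PASS


def assess_mtdna(
    het_subject: Optional[float],
    het_mother: Optional[float],
    options: EngineOptions = DEFAULT_OPTIONS,
) -> tuple[RuleOutcome, Optional[str]]:
    """Mitochondrial heteroplasmy rule: subject >= ``het_min_pct`` percent
    and >= ``het_ratio`` times the maternal heteroplasmy (0% in the mother
    satisfies the ratio). An untested mother fails, with a warning."""
    if het_subject is None:
        return RuleOutcome.FAIL, "subject heteroplasmy missing"
    if het_mother is None:
        return (RuleOutcome.FAIL,
                "maternal heteroplasmy not measured; rule presumes a "
                "maternal measurement")
    if het_subject < options.het_min_pct:
        return RuleOutcome.FAIL, None
    if het_subject >= options.het_ratio * het_mother:
        return RuleOutcome.PASS, None
    return RuleOutcome.FAIL, None


def assess_splice(
    splice_rf: Optional[float],
    splice_ada: Optional[float],
    conservation: Conservation,
    options: EngineOptions = DEFAULT_OPTIONS,
) -> RuleOutcome:
    """Splice-site rule: either predictor above the threshold, or — when no
    prediction is available — a conserved nucleotide."""
    scores = [s for s in (splice_rf, splice_ada) if s is not None]
    if any(s > options.splice_threshold for s in scores):
        return RuleOutcome.PASS
    if not scores and conservation is Conservation.CONSERVED:
        return RuleOutcome.PASS
    return RuleOutcome.FAIL


# ---------------------------------------------------------------------------
# Full classification
# ---------------------------------------------------------------------------

def _resolve_genes(
    record: VariantRecord,
    genes: Mapping[str, GeneAnnotation],
    options: EngineOptions,
) -> tuple[list[GeneAnnotation], bool]:
    """Annotations for the record's symbols; second element is True when an
    unresolved symbol was downgraded (permissive mode)."""
    found, missing = [], []
    for sym in record.gene_symbols:
        if sym in genes:
            found.append(genes[sym])
        else:
            missing.append(sym)
    if missing and options.strict_gene_resolution:
        raise UnresolvedGeneError(
            f"unresolved gene symbol(s) {missing} for subject "
            f"{record.subject_id} ({record.label!r})"
        )
    return found, bool(missing)


def classify_variant(
    record: VariantRecord,
    genes: Mapping[str, GeneAnnotation],
    options: EngineOptions = DEFAULT_OPTIONS,
) -> ClassificationResult:
    """Classify one de novo variant; pure function of (record, options).

    Every rule is evaluated and every failure is accumulated as a reason,
    so downstream reports can cross-tabulate exclusion-reason combinations.
    """
    if not record.is_de_novo:
        raise ValueError("classify_variant applies to de novo records only")

    reasons: set[Reason] = set()
    trace: list[tuple[str, str]] = []
    warnings: list[str] = []
    is_mito = record.genome is Genome.MITO

    # 1. real
    if not record.verified_real:
        reasons.add(Reason.NOT_VERIFIED)
    trace.append(("verified_real", "pass" if record.verified_real else "fail"))

    # 2. coding consequence class
    if record.variant_class in NONCODING_CLASSES:
        reasons.add(Reason.NONCODING_CLASS)
        trace.append(("coding_class", "fail"))
    elif record.variant_class is VariantClass.SILENT and not options.include_silent:
        reasons.add(Reason.SILENT_EXCLUDED_BY_MODE)
        trace.append(("coding_class", "silent_excluded"))
    else:
        trace.append(("coding_class", "pass"))

    # 3. gene association (best category over spanned genes)
    annotations, downgraded = _resolve_genes(record, genes, options)
    if downgraded:
        warnings.append("unresolved gene symbol downgraded to not-associated")
    if not annotations:
        gene_outcome = RuleOutcome.FAIL
    else:
        gene_outcome = assess_gene(annotations, options)
    if gene_outcome is RuleOutcome.FAIL:
        reasons.add(Reason.GENE_NOT_ASSOCIATED)
    trace.append(("gene_association", gene_outcome.value))

    # 4. AR carrier status (single-gene variants only)
    if len(annotations) == 1 and record.variant_class not in (
        VariantClass.CNV_DUP, VariantClass.CNV_DEL, VariantClass.ANEUPLOIDY
    ):
        ar_outcome = assess_ar(
            annotations[0], record.companion_rare_conserved_variant)
        if ar_outcome is RuleOutcome.FAIL:
            reasons.add(Reason.AR_CARRIER)
        trace.append(("ar_carrier", ar_outcome.value))
    else:
        trace.append(("ar_carrier", "exempt"))

    # 5. rarity (mtDNA variants are judged by heteroplasmy instead)
    if is_mito:
        trace.append(("rarity", "exempt"))
    else:
        rarity, warn = assess_rarity(
            record.allele_freq_1, record.allele_freq_2,
            record.known_pathogenic_cnv, options)
        if warn:
            warnings.append(warn)
        if rarity is RuleOutcome.FAIL:
            reasons.add(Reason.NOT_RARE)
        trace.append(("rarity", rarity.value))

    # 6. conservation (mtDNA exempt; heteroplasmy rule governs)
    if is_mito:
        conservation = Conservation.EXEMPT
        trace.append(("conservation", "exempt"))
    else:
        conservation, warn = assess_conservation(
            record.variant_class, record.phylop, record.phastcons,
            record.manual_conservation, options)
        if warn:
            warnings.append(warn)
        if conservation is Conservation.NOT_CONSERVED:
            reasons.add(Reason.NOT_CONSERVED)
        trace.append(("conservation", conservation.value))

    # 7. splice predictors
    if record.variant_class is VariantClass.SPLICE:
        splice = assess_splice(record.splice_rf, record.splice_ada,
                               conservation, options)
        if splice is RuleOutcome.FAIL:
            reasons.add(Reason.SPLICE_SCORE_FAIL)
        trace.append(("splice", splice.value))
    else:
        trace.append(("splice", "exempt"))

    # 8. mitochondrial heteroplasmy
    if is_mito:
        het, warn = assess_mtdna(record.heteroplasmy_subject_pct,
                                 record.heteroplasmy_mother_pct, options)
        if warn:
            warnings.append(warn)
        if het is RuleOutcome.FAIL:
            reasons.add(Reason.HETEROPLASMY_FAIL)
        trace.append(("heteroplasmy", het.value))
    else:
        trace.append(("heteroplasmy", "exempt"))

    ordered = tuple(r for r in REASON_ORDER if r in reasons)
    return ClassificationResult(
        record=record,
        is_pdv=not ordered,
        reasons=ordered,
        rule_trace=tuple(trace),
        warnings=tuple(warnings),
    )


def classify_cohort(
    bundle: CohortBundle,
    options: EngineOptions = DEFAULT_OPTIONS,
) -> dict[str, list[ClassificationResult]]:
    """Classify every de novo record; subjects with no de novo variants map
    to an empty list (the phenotype roster defines the cohort)."""
    results: dict[str, list[ClassificationResult]] = {
        sid: [] for sid in bundle.subject_ids
    }
    for record in bundle.de_novo:
        results.setdefault(record.subject_id, []).append(
            classify_variant(record, bundle.genes, options))
    return results


def pdv_records(
    classifications: Mapping[str, Sequence[ClassificationResult]],
) -> list[ClassificationResult]:
    """Flatten to the PDV calls only, in subject order."""
    out = []
    for sid in classifications:
        out.extend(r for r in classifications[sid] if r.is_pdv)
    return out


__all__ = [
    "EngineOptions", "DEFAULT_OPTIONS", "RuleOutcome", "Conservation",
    "UnresolvedGeneError", "CONSERVATION_EXEMPT_CLASSES", "NONCODING_CLASSES",
    "assess_rarity", "assess_conservation", "assess_gene", "assess_ar",
    "assess_mtdna", "assess_splice", "classify_variant", "classify_cohort",
    "pdv_records",
]
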