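"""Subject-level reporting: diagnostic yield, exclusion-reason breakdown,
laboratory-report concordance, and phenotype 2x2 associations.

The cohort roster comes from the phenotype table, so subjects with zero de
novo variants still appear in the yield histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Mapping, Optional, Sequence

from .model import (
    ClassificationResult,
    LabReportStatus,
    Reason,
    SubjectPhenotype,
    TriState,
    VariantClass,
)
from .stats import fisher_exact_two_tailed

#: Laboratory report designations counted as "listed" for concordance.
LAB_LISTED_STATUSES = frozenset({
    LabReportStatus.POSITIVE, LabReportStatus.UNCERTAIN,
    LabReportStatus.OTHER_VARIANTS, LabReportStatus.SUPPLEMENTARY,
    LabReportStatus.NEGATIVE, LabReportStatus.LIKELY_NEGATIVE,
})

#: ... of which these are "indeterminate or better".
LAB_INDETERMINATE_OR_BETTER = frozenset({
    LabReportStatus.POSITIVE, LabReportStatus.UNCERTAIN,
    LabReportStatus.OTHER_VARIANTS, LabReportStatus.SUPPLEMENTARY,
})


@dataclass(frozen=True)
class YieldReport:
    n_subjects: int
    n_with_pdv: int
    pdv_count_histogram: dict[int, int]
    pdv_counts_by_class: dict[str, int]
    exclusion_tally: dict[tuple[str, ...], int]
    lab_listed_total: int
    lab_listed_pdv: int
    lab_listed_subjects: int
    lab_indeterminate_or_better_subjects: int

    @property
    def total_pdvs(self) -> int:
        return sum(self.pdv_counts_by_class.values())

    @property
    def yield_fraction(self) -> float:
        return self.n_with_pdv / self.n_subjects if self.n_subjects else 0.0


def diagnostic_yield(
    classifications: Mapping[str, Sequence[ClassificationResult]],
) -> YieldReport:
    """Summarise PDV calls per subject.

    ``classifications`` must cover the whole roster (classify_cohort maps
    zero-variant subjects to empty lists).
    """
    histogram: Counter[int] = Counter()
    by_class: Counter[str] = Counter()
    exclusions: Counter[tuple[str, ...]] = Counter()
    lab_total = lab_pdv = 0
    lab_subjects: set[str] = set()
    lab_indet_subjects: set[str] = set()

    for sid, results in classifications.items():
        n_pdv = 0
        for res in results:
            if res.is_pdv:
                n_pdv += 1
                by_class[res.record.variant_class.value] += 1
            else:
                exclusions[tuple(r.value for r in res.reasons)] += 1
            if res.record.lab_report_status in LAB_LISTED_STATUSES:
                lab_total += 1
                lab_pdv += int(res.is_pdv)
                lab_subjects.add(sid)
                if res.record.lab_report_status in LAB_INDETERMINATE_OR_BETTER:
                    lab_indet_subjects.add(sid)
        histogram[n_pdv] += 1

    return YieldReport(
        n_subjects=len(classifications),
        n_with_pdv=sum(v for k, v in histogram.items() if k > 0),
        pdv_count_histogram=dict(sorted(histogram.items())),
        pdv_counts_by_class=dict(sorted(by_class.items())),
        exclusion_tally=dict(sorted(exclusions.items())),
        lab_listed_total=lab_total,
        lab_listed_pdv=lab_pdv,
        lab_listed_subjects=len(lab_subjects),
        lab_indeterminate_or_better_subjects=len(lab_indet_subjects),
    )


def exclusion_breakdown(
    classifications: Mapping[str, Sequence[ClassificationResult]],
) -> dict[tuple[str, ...], int]:
    """Each excluded de novo variant counted once under its full ordered
    reason combination."""
    out: Counter[tuple[str, ...]] = Counter()
    for results in classifications.values():
        for res in results:
            if not res.is_pdv:
                out[tuple(r.value for r in res.reasons)] += 1
    return dict(sorted(out.items()))


def phenotype_association(
    phenotypes: Sequence[SubjectPhenotype],
    classifications: Mapping[str, Sequence[ClassificationResult]],
    feature: str,
) -> tuple[tuple[int, int, int, int], float]:
    """2x2 association of a tri-state phenotype feature with PDV carriage.

    Returns ((a, b, c, d), p) where rows are feature yes/no and columns are
    has-PDV / no-PDV; subjects with unknown feature status are dropped from
    both margins. p is the two-tailed Fisher exact test.
    """
    has_pdv = {
        sid: any(r.is_pdv for r in results)
        for sid, results in classifications.items()
    }
    a = b = c = d = 0
    informative = 0
    for p in phenotypes:
        value: TriState = getattr(p, feature)
        if value is TriState.UNKNOWN:
            continue
        informative += 1
        pdv = has_pdv.get(p.subject_id, False)
        if value is TriState.YES:
            if pdv:
                a += 1
            else:
                b += 1
        else:
            if pdv:
                c += 1
            else:
                d += 1
    if informative == 0:
        raise ValueError(f"no informative subjects for feature {feature!r}")
    return (a, b, c, d), fisher_exact_two_tailed(a, b, c, d)


def yield_report_dict(report: YieldReport) -> dict:
    """JSON-ready rendering of a YieldReport."""
    return {
        "n_subjects": report.n_subjects,
        "n_with_pdv": report.n_with_pdv,
        "yield_pct": 100.0 * report.yield_fraction,
        "total_pdvs": report.total_pdvs,
        "pdv_count_histogram": {str(k): v
                                for k, v in report.pdv_count_histogram.items()},
        "pdv_counts_by_class": report.pdv_counts_by_class,
        "exclusion_tally": {"+".join(k) if k else "(none)": v
                            for k, v in report.exclusion_tally.items()},
        "lab_listed_total": report.lab_listed_total,
        "lab_listed_pdv": report.lab_listed_pdv,
        "lab_listed_subjects": report.lab_listed_subjects,
        "lab_indeterminate_or_better_subjects":
            report.lab_indeterminate_or_better_subjects,
    }


def yield_report_text(report: YieldReport) -> str:
    lines = [
        f"Subjects: {report.n_subjects}",
        f"Subjects with >=1 de novo PDV: {report.n_with_pdv} "
        f"({100 * report.yield_fraction:.0f}%)",
        f"Total de novo PDVs: {report.total_pdvs}",
        "PDVs per subject: " + ", ".join(
            f"{k}: {v}" for k, v in report.pdv_count_histogram.items()),
        "PDVs by class: " + ", ".join(
            f"{k}: {v}" for k, v in report.pdv_counts_by_class.items()),
        f"Laboratory-report-listed de novo variants: {report.lab_listed_total} "
        f"(classified PDV: {report.lab_listed_pdv}) across "
        f"{report.lab_listed_subjects} subjects "
        f"({report.lab_indeterminate_or_better_subjects} with an "
        f"indeterminate-or-better designation)",
        "Exclusions by reason combination:",
    ]
    for combo, n in report.exclusion_tally.items():
        lines.append(f"  {'+'.join(combo)}: {n}")
    return "\n".join(lines) + "\n"


__all__ = [
    "YieldReport", "diagnostic_yield", "exclusion_breakdown",
    "phenotype_association", "yield_report_dict", "yield_report_text",
    "LAB_LISTED_STATUSES", "LAB_INDETERMINATE_OR_BETTER",
]
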