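"""SFARI gene-set enrichment across variant classes.

Each variant class (de novo missense PDVs, de novo silent PDVs, inherited
missense / silent / UTR / up+downstream) is summarised as a 2x2 table of
SFARI-listed versus not, and classes are compared pairwise with a
two-tailed Fisher exact test and a Woolf (logit) confidence interval for
the odds ratio. The up/downstream class — variants in the ~1 kb
non-transcribed flanks — serves as the internal control: its SFARI
proportion is expected to match the genome-wide baseline (1114 SFARI genes
of ~20,000, 5.57%).

The Fisher p-value is the point-probability two-tailed definition: the sum
of hypergeometric point probabilities, at fixed margins, over all tables no
more probable than the observed one (a relative tolerance guards float
ties). The computation is done in log space so tables with margins in the
tens of thousands are exact to working precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .model import (
    ClassLabel,
    ClassificationResult,
    ClassTally,
    Genome,
    SfariScore,
    VariantClass,
)

#: z for a two-sided 95% interval.
Z_95 = 1.959964

#: Relative tolerance for "as or more extreme" probability ties.
TIE_RTOL = 1e-7


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Point-probability method: with row and column margins fixed, sum the
    hypergeometric probabilities of every table whose point probability is
    at most that of the observed table (within relative tolerance 1e-7).
    Log-space evaluation keeps the sum exact for margins >= 20,000.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    n = a + b + c + d
    r1 = a + b      # first row margin
    c1 = a + c      # first column margin
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0  # degenerate margins: only one table possible
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n, c1, r1)
    log_obs = logpmf[a - lo]
    # tables as or more extreme than observed, with tolerance for float ties
    mask = logpmf <= log_obs + math.log1p(TIE_RTOL)
    # log-sum-exp over the selected tables
    m = logpmf[mask].max()
    p = float(np.exp(m) * np.exp(logpmf[mask] - m).sum())
    return min(p, 1.0)


def odds_ratio_ci(
    a: int, b: int, c: int, d: int, alpha: float = 0.05,
    haldane: bool = False,
) -> tuple[float, float, float]:
    """Odds ratio (a·d)/(b·c) with the Woolf (logit) confidence interval:
    exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d)).

    Zero cells are an error unless ``haldane`` applies the Haldane–Anscombe
    +0.5 correction to every cell.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    if any(x == 0 for x in cells):
        if not haldane:
            raise ValueError(
                "zero cell in 2x2 table; pass haldane=True for the "
                "Haldane–Anscombe +0.5 correction")
        cells = [x + 0.5 for x in cells]
    a_, b_, c_, d_ = cells
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    from scipy.stats import norm
    z = Z_95 if abs(alpha - 0.05) < 1e-12 else float(norm.ppf(1 - alpha / 2))
    log_or = math.log(a_ * d_ / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return (math.exp(log_or),
            math.exp(log_or - z * se),
            math.exp(log_or + z * se))


@dataclass(frozen=True)
class EnrichmentResult:
    """One class-vs-class SFARI enrichment comparison."""

    class_a: ClassLabel
    class_b: ClassLabel
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_two_tailed: float
    a: int  # class_a SFARI
    b: int  # class_a non-SFARI
    c: int  # class_b SFARI
    d: int  # class_b non-SFARI


@dataclass(frozen=True)
class ComparisonMatrix:
    labels: tuple[ClassLabel, ...]
    cells: Mapping[tuple[ClassLabel, ClassLabel], EnrichmentResult]

    def get(self, class_a: ClassLabel, class_b: ClassLabel) -> EnrichmentResult:
        return self.cells[(class_a, class_b)]


def compare_pair(tally_a: ClassTally, tally_b: ClassTally) -> EnrichmentResult:
    a = tally_a.n_sfari
    b = tally_a.n_variants - tally_a.n_sfari
    c = tally_b.n_sfari
    d = tally_b.n_variants - tally_b.n_sfari
    or_, lo, hi = odds_ratio_ci(a, b, c, d)
    p = fisher_exact_two_tailed(a, b, c, d)
    return EnrichmentResult(
        class_a=tally_a.class_label, class_b=tally_b.class_label,
        odds_ratio=or_, ci_low=lo, ci_high=hi, p_two_tailed=p,
        a=a, b=b, c=c, d=d,
    )


def compare_classes(
    tallies: Sequence[ClassTally],
    pairs: Optional[Sequence[tuple[ClassLabel, ClassLabel]]] = None,
) -> ComparisonMatrix:
    """Pairwise SFARI enrichment over the requested class pairs (all
    ordered off-diagonal pairs by default)."""
    by_label = {t.class_label: t for t in tallies}
    labels = tuple(by_label)
    if pairs is None:
        pairs = [(x, y) for x in labels for y in labels if x != y]
    cells = {}
    for x, y in pairs:
        if x == y:
            raise ValueError(f"class compared with itself: {x.value}")
        cells[(x, y)] = compare_pair(by_label[x], by_label[y])
    return ComparisonMatrix(labels=labels, cells=cells)


def sfari_baseline(n_sfari_genes: int = 1114,
                   n_total_genes: int = 20000) -> float:
    """Genome-wide SFARI membership baseline, as a percentage."""
    if n_total_genes <= 0 or n_sfari_genes < 0:
        raise ValueError("gene counts must be positive")
    return 100.0 * n_sfari_genes / n_total_genes


def bonferroni(p_values: Iterable[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni adjustment: min(1, p·m); m defaults to len(p_values)."""
    ps = list(p_values)
    m = len(ps) if m is None else m
    if m < len(ps):
        raise ValueError("m must be at least the number of p-values")
    return [min(1.0, p * m) for p in ps]


# ---------------------------------------------------------------------------
# Tally construction from classifications
# ---------------------------------------------------------------------------

_DN_CLASS_FOR = {
    VariantClass.MISSENSE: ClassLabel.DN_MISSENSE_PDV,
    VariantClass.SILENT: ClassLabel.DN_SILENT_PDV,
}

_INH_CLASS_FOR = {
    VariantClass.MISSENSE: ClassLabel.INH_MISSENSE,
    VariantClass.SILENT: ClassLabel.INH_SILENT,
    VariantClass.UTR: ClassLabel.INH_UTR,
    VariantClass.UPSTREAM: ClassLabel.INH_UPDOWNSTREAM,
    VariantClass.DOWNSTREAM: ClassLabel.INH_UPDOWNSTREAM,
}


def _is_sfari(record, genes) -> bool:
    return any(
        sym in genes and genes[sym].sfari_score is not SfariScore.NONE
        for sym in record.gene_symbols
    )


def build_tallies(
    classifications: Mapping[str, Sequence[ClassificationResult]],
    bundle,
    subject_subsets: Optional[Mapping[ClassLabel, Sequence[str]]] = None,
) -> list[ClassTally]:
    """Per-class (variants, SFARI) tallies feeding the enrichment tests.

    De novo classes count PDV calls only, excluding structural and
    mitochondrial records (small nuclear variants only, matching how the
    genome-wide inherited tallies are constructed). Inherited classes count
    every variant of that class among the designated subject subset (the
    whole roster by default). SFARI membership is per gene annotation.
    """
    subject_subsets = subject_subsets or {}
    genes = bundle.genes
    roster = list(bundle.subject_ids)

    counts: dict[ClassLabel, list[int]] = {
        label: [0, 0] for label in ClassLabel
    }
    subjects_for: dict[ClassLabel, set[str]] = {}
    for label in ClassLabel:
        subset = subject_subsets.get(label)
        subjects_for[label] = set(subset) if subset is not None else set(roster)

    for sid, results in classifications.items():
        for res in results:
            rec = res.record
            if rec.genome is Genome.MITO:
                continue
            label = _DN_CLASS_FOR.get(rec.variant_class)
            if label is None or not res.is_pdv:
                continue
            if sid not in subjects_for[label]:
                continue
            counts[label][0] += 1
            counts[label][1] += int(_is_sfari(rec, genes))

    for rec in bundle.variants:
        if rec.is_de_novo or rec.genome is Genome.MITO:
            continue
        label = _INH_CLASS_FOR.get(rec.variant_class)
        if label is None or rec.subject_id not in subjects_for[label]:
            continue
        counts[label][0] += 1
        counts[label][1] += int(_is_sfari(rec, genes))

    return [
        ClassTally(
            class_label=label,
            n_subjects=len(subjects_for[label]),
            n_variants=counts[label][0],
            n_sfari=counts[label][1],
        )
        for label in ClassLabel
    ]


# ---------------------------------------------------------------------------
# Report emission
# ---------------------------------------------------------------------------

def round_or(x: float) -> float:
    """Round an odds ratio to 2 significant figures for report output."""
    if x <= 0:
        raise ValueError("odds ratio must be positive")
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + 1)


def enrichment_report(
    tallies: Sequence[ClassTally],
    matrix: ComparisonMatrix,
) -> dict:
    """JSON-ready summary mirroring the published layout: per-class totals,
    per-subject averages, SFARI counts and percentages, pairwise p/OR/CI."""
    per_class = {
        t.class_label.value: {
            "n_subjects": t.n_subjects,
            "n_variants": t.n_variants,
            "per_subject": t.per_subject,
            "n_sfari": t.n_sfari,
            "sfari_per_subject": t.n_sfari / t.n_subjects if t.n_subjects else 0.0,
            "pct_sfari": 100.0 * t.sfari_fraction,
        }
        for t in tallies
    }
    comparisons = {
        f"{x.value}_vs_{y.value}": {
            "p": r.p_two_tailed,
            "odds_ratio": r.odds_ratio,
            "odds_ratio_2sf": round_or(r.odds_ratio),
            "ci95": [r.ci_low, r.ci_high],
            "table": [r.a, r.b, r.c, r.d],
        }
        for (x, y), r in matrix.cells.items()
    }
    return {"classes": per_class, "comparisons": comparisons,
            "sfari_baseline_pct": sfari_baseline()}


def enrichment_tsv(tallies: Sequence[ClassTally],
                   matrix: ComparisonMatrix) -> str:
    """TSV rendering of the per-class summary plus pairwise comparisons."""
    lines = ["statistic\t" + "\t".join(t.class_label.value for t in tallies)]

    def fmt_row(name, fn):
        lines.append(name + "\t" + "\t".join(fn(t) for t in tallies))

    fmt_row("n_subjects", lambda t: str(t.n_subjects))
    fmt_row("n_variants", lambda t: str(t.n_variants))
    fmt_row("variants_per_subject", lambda t: f"{t.per_subject:g}")
    fmt_row("n_sfari", lambda t: str(t.n_sfari))
    fmt_row("pct_sfari", lambda t: f"{100 * t.sfari_fraction:.2f}%")
    lines.append("")
    lines.append("class_a\tclass_b\tp\todds_ratio\tci_low\tci_high")
    for (x, y), r in matrix.cells.items():
        lines.append(
            f"{x.value}\t{y.value}\t{r.p_two_tailed:.3g}\t"
            f"{round_or(r.odds_ratio):g}\t{r.ci_low:.3g}\t{r.ci_high:.3g}")
    return "\n".join(lines) + "\n"


__all__ = [
    "EnrichmentResult", "ComparisonMatrix", "fisher_exact_two_tailed",
    "odds_ratio_ci", "compare_pair", "compare_classes", "sfari_baseline",
    "bonferroni", "build_tallies", "round_or", "enrichment_report",
    "enrichment_tsv", "Z_95",
]
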