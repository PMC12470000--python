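"""Synthetic-cohort generator with recorded ground truth.

Generates cohorts with the statistical structure the analysis assumes, so
the classification engine and the enrichment tests can be validated
end-to-end without real data:

* de novo coding variant counts per subject are Poisson (mean 1.5, the
  rate observed in severely affected ASD cohorts; 0.2-0.3 is typical of
  unaffected individuals and is supported as an alternative);
* variant classes follow a configurable mixture (default: the packaged
  cohort's empirical mix);
* inherited variant counts per subject are Poisson per class (defaults
  157 missense, 90.5 silent, 287 UTR, 327 up/downstream — genome-wide
  per-subject averages);
* SFARI gene membership is Bernoulli on the odds scale: the odds of a
  variant falling in a SFARI-listed gene are ``class_or x baseline odds``
  (baseline 5.57%, the SFARI share of ~20,000 genes), so a configured
  class odds ratio is exactly the estimand of the enrichment test;
* every de novo variant is planted either as a PDV (fields drawn to pass
  every rule) or as a non-PDV with a planted exclusion reason (fields
  drawn to fail exactly that rule), and the planting is recorded as
  ground truth.

One pseudorandom stream is derived per subject from (seed, subject index),
so a subject's variants are reproducible under subject-count changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import CohortBundle
from .model import (
    GeneAnnotation,
    GeneCategory,
    Genome,
    Inheritance,
    ManualConservation,
    Reason,
    SfariScore,
    SubjectPhenotype,
    TriState,
    VariantClass,
    VariantRecord,
)
from .stats import fisher_exact_two_tailed, odds_ratio_ci

#: Empirical de novo class mixture of the packaged cohort (148 of its 151
#: de novo variants; the mitochondrial and aneuploidy rows are folded into
#: their consequence classes — the generator emulates nuclear variation).
DEFAULT_CLASS_MIX: dict[VariantClass, float] = {
    VariantClass.MISSENSE: 93 / 148,
    VariantClass.SILENT: 30 / 148,
    VariantClass.FRAMESHIFT: 10 / 148,
    VariantClass.NONSENSE: 3 / 148,
    VariantClass.SPLICE: 2 / 148,
    VariantClass.INFRAME_INDEL: 1 / 148,
    VariantClass.CNV_DUP: 5 / 148,
    VariantClass.CNV_DEL: 4 / 148,
}

#: Genome-wide inherited variants per subject, by class.
DEFAULT_INHERITED_MEANS: dict[VariantClass, float] = {
    VariantClass.MISSENSE: 157.0,
    VariantClass.SILENT: 90.5,
    VariantClass.UTR: 287.0,
    VariantClass.UPSTREAM: 163.5,
    VariantClass.DOWNSTREAM: 163.5,
}

#: Exclusion reasons the generator can plant, per class constraint.
_PLANTABLE_REASONS = (
    Reason.GENE_NOT_ASSOCIATED,
    Reason.NOT_RARE,
    Reason.NOT_CONSERVED,
    Reason.AR_CARRIER,
)

_CONSERVATION_SCORED = frozenset({
    VariantClass.MISSENSE, VariantClass.SPLICE, VariantClass.INFRAME_INDEL,
})
_CNV_CLASSES = frozenset({VariantClass.CNV_DUP, VariantClass.CNV_DEL})


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 100
    dnv_rate: float = 1.5
    class_mix: Mapping[VariantClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    inherited_means: Mapping[VariantClass, float] = field(
        default_factory=lambda: dict(DEFAULT_INHERITED_MEANS))
    sfari_baseline: float = 0.0557
    class_or: Mapping[VariantClass, float] = field(default_factory=dict)
    pdv_pass_fraction: float = 0.54
    n_genes: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if self.dnv_rate < 0 or any(m < 0 for m in self.inherited_means.values()):
            raise ValueError("rates must be non-negative")
        total = sum(self.class_mix.values())
        if self.class_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total})")
        if not 0 < self.sfari_baseline < 1:
            raise ValueError("sfari_baseline must lie in (0, 1)")
        if any(or_ <= 0 for or_ in self.class_or.values()):
            raise ValueError("class odds ratios must be positive")
        if not 0 <= self.pdv_pass_fraction <= 1:
            raise ValueError("pdv_pass_fraction must lie in [0, 1]")

    def sfari_prob(self, vclass: VariantClass) -> float:
        """Per-variant SFARI membership probability: odds-scale shift of the
        baseline by the class odds ratio."""
        base_odds = self.sfari_baseline / (1 - self.sfari_baseline)
        odds = self.class_or.get(vclass, 1.0) * base_odds
        return odds / (1 + odds)


@dataclass(frozen=True)
class PlantedVariant:
    subject_id: str
    label: str
    variant_class: VariantClass
    inherited: bool
    is_pdv: bool
    planted_reason: Optional[Reason]
    is_sfari: bool


@dataclass
class GroundTruth:
    planted: list[PlantedVariant]
    config: SimulationConfig

    def pdv_labels(self) -> set[tuple[str, str]]:
        return {(p.subject_id, p.label) for p in self.planted
                if p.is_pdv and not p.inherited}

    def class_sfari_counts(self, inherited: bool) -> dict[VariantClass, tuple[int, int]]:
        out: dict[VariantClass, list[int]] = {}
        for p in self.planted:
            if p.inherited is not inherited:
                continue
            n, k = out.setdefault(p.variant_class, [0, 0])
            out[p.variant_class] = [n + 1, k + int(p.is_sfari)]
        return {c: (n, k) for c, (n, k) in out.items()}


# ---------------------------------------------------------------------------
# Gene pool
# ---------------------------------------------------------------------------

def _build_gene_pool(config: SimulationConfig) -> dict[str, GeneAnnotation]:
    """Synthetic symbols G000001..: strata crossing SFARI membership x
    (eligible / ineligible / eligible-AR-only) so planting can pick a gene
    from the needed stratum without disturbing SFARI probabilities."""
    genes: dict[str, GeneAnnotation] = {}
    n = config.n_genes
    # thirds: eligible, ineligible, AR-only eligible
    eligible_cats = [GeneCategory.A1, GeneCategory.A2, GeneCategory.A3,
                     GeneCategory.B0]
    ineligible_cats = [GeneCategory.B1, GeneCategory.B2, GeneCategory.B3]
    for i in range(n):
        sym = f"G{i + 1:06d}"
        sfari = (i % 2 == 0)  # half the pool SFARI: every stratum non-empty
        stratum = i % 6 // 2  # 0 eligible, 1 ineligible, 2 AR eligible
        if stratum == 1:
            cat = ineligible_cats[i % len(ineligible_cats)]
            ar = False
        else:
            cat = eligible_cats[i % len(eligible_cats)]
            ar = stratum == 2
        genes[sym] = GeneAnnotation(
            symbol=sym, category=cat,
            sfari_score=SfariScore.S2 if sfari else SfariScore.NONE,
            ar_only=ar, coding=True,
        )
    return genes


def _pick_gene(rng, genes_index, sfari: bool, stratum: str) -> str:
    return str(rng.choice(genes_index[(sfari, stratum)]))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> tuple[CohortBundle, GroundTruth]:
    """Draw a cohort; identical configs give identical bundles."""
    genes = _build_gene_pool(config)
    # index gene pool by (sfari, stratum)
    genes_index: dict[tuple[bool, str], list[str]] = {}
    for sym, g in genes.items():
        if g.ar_only:
            stratum = "ar"
        elif g.category in (GeneCategory.A1, GeneCategory.A2,
                            GeneCategory.A3, GeneCategory.B0):
            stratum = "eligible"
        else:
            stratum = "ineligible"
        genes_index.setdefault((g.is_sfari, stratum), []).append(sym)

    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])

    variants: list[VariantRecord] = []
    phenotypes: list[SubjectPhenotype] = []
    planted: list[PlantedVariant] = []

    for idx in range(config.n_subjects):
        sid = f"S{idx + 1:04d}"
        rng = np.random.default_rng([config.seed, idx + 1])

        # --- de novo variants
        n_dnv = int(rng.poisson(config.dnv_rate))
        for j in range(n_dnv):
            vclass = classes[int(rng.choice(len(classes), p=probs))]
            sfari = bool(rng.random() < config.sfari_prob(vclass))
            as_pdv = bool(rng.random() < config.pdv_pass_fraction)
            label = f"{sid}_dnv{j + 1}_{vclass.value}"
            rec, reason = _plant_de_novo(
                rng, sid, label, vclass, sfari, as_pdv, genes_index, config)
            variants.append(rec)
            planted.append(PlantedVariant(
                subject_id=sid, label=label, variant_class=vclass,
                inherited=False, is_pdv=reason is None,
                planted_reason=reason, is_sfari=sfari))

        # --- inherited variants
        for vclass, mean in config.inherited_means.items():
            k = int(rng.poisson(mean))
            p_sfari = config.sfari_prob(vclass)
            sfari_draws = rng.random(k) < p_sfari
            for j in range(k):
                sfari = bool(sfari_draws[j])
                gene = _pick_gene(rng, genes_index, sfari, "eligible")
                label = f"{sid}_inh_{vclass.value}_{j + 1}"
                variants.append(VariantRecord(
                    subject_id=sid, label=label, gene_symbols=(gene,),
                    variant_class=vclass, genome=Genome.NUCLEAR,
                    chromosome="1",
                    inheritance=Inheritance.INHERITED_UNPHASED,
                    allele_freq_1=0.01, allele_freq_2=0.01,
                ))
                planted.append(PlantedVariant(
                    subject_id=sid, label=label, variant_class=vclass,
                    inherited=True, is_pdv=False, planted_reason=None,
                    is_sfari=sfari))

        # --- phenotype row (features independent of genotype)
        phenotypes.append(SubjectPhenotype(
            subject_id=sid,
            sex="female" if rng.random() < 0.2 else "male",
            age_years=float(rng.integers(4, 18)),
            id_moderate_or_worse=TriState.YES if rng.random() < 0.85 else TriState.NO,
            nonverbal=TriState.YES if rng.random() < 0.29 else TriState.NO,
            epilepsy=TriState.YES if rng.random() < 0.31 else TriState.NO,
            regression=TriState.YES if rng.random() < 0.57 else TriState.NO,
            tics=TriState.YES if rng.random() < 0.09 else TriState.NO,
        ))

    bundle = CohortBundle(
        variants=variants, genes=genes, phenotypes=phenotypes,
        provenance=f"synthetic cohort (seed={config.seed}, "
                   f"n={config.n_subjects})",
    )
    return bundle, GroundTruth(planted=planted, config=config)


def _plant_de_novo(rng, sid, label, vclass, sfari, as_pdv, genes_index,
                   config) -> tuple[VariantRecord, Optional[Reason]]:
    """Draw a de novo record that the rule engine will classify exactly as
    planted; returns (record, planted_reason-or-None)."""
    thr = 1e-4  # defaults of the engine; planting targets them

    def passing_fields() -> dict:
        f = dict(
            allele_freq_1=float(rng.uniform(0, thr * 0.5)),
            allele_freq_2=float(rng.uniform(0, thr * 0.5)),
        )
        if vclass in _CONSERVATION_SCORED:
            f["phylop"] = float(rng.uniform(0.8, 1.2))
            f["phastcons"] = float(rng.uniform(0.8, 1.0))
        if vclass is VariantClass.SPLICE:
            f["splice_rf"] = float(rng.uniform(0.7, 1.0))
            f["splice_ada"] = float(rng.uniform(0.7, 1.0))
        return f

    if as_pdv:
        gene = _pick_gene(rng, genes_index, sfari, "eligible")
        rec = VariantRecord(
            subject_id=sid, label=label, gene_symbols=(gene,),
            variant_class=vclass, genome=Genome.NUCLEAR, chromosome="1",
            inheritance=Inheritance.DE_NOVO, **passing_fields(),
        )
        return rec, None

    allowed = [Reason.GENE_NOT_ASSOCIATED, Reason.NOT_RARE, Reason.AR_CARRIER]
    if vclass in _CONSERVATION_SCORED:
        allowed.append(Reason.NOT_CONSERVED)
    if vclass in _CNV_CLASSES:
        allowed = [Reason.GENE_NOT_ASSOCIATED, Reason.NOT_RARE]
    reason = allowed[int(rng.choice(len(allowed)))]

    fields = passing_fields()
    stratum = "eligible"
    if reason is Reason.GENE_NOT_ASSOCIATED:
        stratum = "ineligible"
    elif reason is Reason.AR_CARRIER:
        stratum = "ar"
    elif reason is Reason.NOT_RARE:
        fields["allele_freq_1"] = float(rng.uniform(thr * 3, 0.01))
        fields["allele_freq_2"] = float(rng.uniform(thr * 3, 0.01))
    elif reason is Reason.NOT_CONSERVED:
        fields["phylop"] = float(rng.uniform(-1.0, 0.3))
        fields["phastcons"] = float(rng.uniform(0.0, 0.3))
        if vclass is VariantClass.SPLICE:
            # keep splice predictors passing so only conservation fails
            pass
    gene = _pick_gene(rng, genes_index, sfari, stratum)
    rec = VariantRecord(
        subject_id=sid, label=label, gene_symbols=(gene,),
        variant_class=vclass, genome=Genome.NUCLEAR, chromosome="1",
        inheritance=Inheritance.DE_NOVO, **fields,
    )
    return rec, reason


# ---------------------------------------------------------------------------
# Calibration of the enrichment comparison design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationSummary:
    n_reps: int
    alpha: float
    true_or: float
    rejection_rate: float
    mean_odds_ratio: float
    ci_coverage: float


def calibration_study(
    n_case: int,
    n_control: int,
    true_or: float = 1.0,
    baseline: float = 0.0557,
    n_reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> CalibrationSummary:
    """Monte-Carlo check of the class-vs-control comparison design.

    Each replicate draws SFARI counts for a case class of ``n_case``
    variants (SFARI probability = odds-scale shift of ``baseline`` by
    ``true_or``) and a control class of ``n_control`` variants at baseline,
    then runs the Fisher test and the Woolf interval. Reports the rejection
    rate at ``alpha`` (type-I error when true_or == 1), the mean estimated
    odds ratio, and the fraction of intervals covering ``true_or``
    (replicates with a zero cell use the Haldane correction).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    rng = np.random.default_rng([seed, 0x5EED % 2**16])
    base_odds = baseline / (1 - baseline)
    p_case = true_or * base_odds / (1 + true_or * base_odds)
    k_case = rng.binomial(n_case, p_case, size=n_reps)
    k_ctrl = rng.binomial(n_control, baseline, size=n_reps)

    rejections = 0
    covered = 0
    log_ors = []
    for a, c in zip(k_case.tolist(), k_ctrl.tolist()):
        b, d = n_case - a, n_control - c
        p = fisher_exact_two_tailed(a, b, c, d)
        # p lies in (0, 1]; alpha >= 1 means every replicate rejects
        rejections += int(p < alpha or alpha >= 1.0)
        zero = 0 in (a, b, c, d)
        or_, lo, hi = odds_ratio_ci(a, b, c, d, haldane=zero)
        covered += int(lo <= true_or <= hi)
        log_ors.append(np.log(or_))
    return CalibrationSummary(
        n_reps=n_reps, alpha=alpha, true_or=true_or,
        rejection_rate=rejections / n_reps,
        mean_odds_ratio=float(np.exp(np.mean(log_ors))),
        ci_coverage=covered / n_reps,
    )


__all__ = [
    "SimulationConfig", "PlantedVariant", "GroundTruth",
    "CalibrationSummary", "DEFAULT_CLASS_MIX", "DEFAULT_INHERITED_MEANS",
    "generate_cohort", "calibration_study",
]
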