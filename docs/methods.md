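# Methods

## The classification model

The engine encodes a modified ACMG-style decision procedure for de novo
variants (DNVs) in autism trio-WGS data. It is deliberately a *rule* model,
not a statistical classifier: every input is an annotation recorded during
curation (population frequencies, conservation scores, a manual
conservation verdict, splice predictor scores, heteroplasmy percentages,
verification and pathogenic-CNV booleans), every decision is a threshold
comparison, and the output carries a complete rule trace. Nothing is
learned from data, so a classification is exactly reproducible from the
record and the option set.

Assumptions worth stating explicitly:

* **Annotations are trusted.** Read-level verification and the manual
  genome-browser conservation verdict enter as recorded booleans/enums; the
  engine does not re-derive them from alignments or genome tracks (out of
  scope by design).
* **Gene-level evidence is config.** The A1–B3 association ladder and SFARI
  scores arrive in a gene table; the engine never consults literature.
* **Rules are conjunctive and exhaustively evaluated.** A variant is a PDV
  iff no rule fails; all failing rules are recorded, enabling the
  exclusion-reason cross-tabulation in the summary report.

## Parameters (EngineOptions)

| parameter | default | meaning |
|---|---|---|
| `include_silent` | true | synonymous variants PDV-eligible (the study's final operating point; disable to reproduce the pre-rescoring analysis) |
| `freq_threshold` | 1e-4 | strict bound on combined allelic prevalence (≈ population prevalence 2e-4) |
| `cons_high` / `cons_low` | 0.7 / 0.4 | PhyloP & PhastCons bounds: both above → conserved; both below → not; otherwise the manual verdict decides |
| `splice_threshold` | 0.6 | SpliceRF/SpliceADA bound (strict >) |
| `het_min_pct` / `het_ratio` | 40 / 2.0 | mtDNA heteroplasmy floor and subject:mother ratio (inclusive ≥) |
| `manual_conservation_accepts` | high in mammals / vertebrates / amniotes | verdicts counted as conserved |
| `eligible_categories` | A1, A2, A3, B0 | gene-association ladder levels eligible for PDV status |

Strictness choices (strict `<`/`>` for frequency, conservation and splice;
inclusive `≥` for heteroplasmy) reproduce the recorded borderline outcomes
in the packaged cohort: a variant at prevalence "just under 1e-4" passes, a
66%/33% heteroplasmy pair passes, a 44%/34% pair fails.

### Rarity is a combined figure

The rarity rule compares the *mean of the frequency sources present*
(genomes and exomes) against the threshold, rather than requiring each
source to pass individually. This is the reading that reproduces all three
recorded borderline outcomes in the packaged cohort: 0.99e-4 & 1.4e-4
(combined 1.2e-4) fails; 0.79e-4 & 2.3e-4 fails; 0.85e-4 & 1.1e-4
(combined 0.98e-4) passes — the last of these is a recorded PDV and would
be excluded under a per-source rule. Pathogenic-flagged CNVs bypass the
rule entirely. A record with no frequency at all passes with a warning
(indeterminate, flagged for review).

### Mitochondrial variants

De novo mtDNA variants are judged by the heteroplasmy rule alone (subject
≥ 40% and ≥ 2× the mother; an untested mother fails, configurable, with a
warning). They are exempt from the nuclear rarity and conservation rules:
the packaged cohort's one mitochondrial PDV has a homoplasmic population
frequency above 1e-4, so applying the nuclear rarity rule to mtDNA would
contradict the recorded outcome. Mitochondrial rRNA variants are never
PDVs (not protein-coding).

### Conservation exemptions

Truncating (frameshift, nonsense), synonymous, structural (CNV,
aneuploidy) and rRNA classes are exempt from the conservation rule: the
consequence does not hinge on one conserved base, and a large deletion
removes conserved nucleotides by construction. In-frame indels and splice
variants are conservation-scored; when both scores are missing and no
manual verdict exists the engine returns not-conserved with a warning.

## Enrichment statistics

Class-vs-class SFARI enrichment uses the point-probability two-tailed
Fisher exact test: with margins fixed, sum the hypergeometric probabilities
of all tables no more probable than the observed one (relative tolerance
1e-7 guards floating-point ties). The sum is evaluated in log space
(`hypergeom.logpmf` + log-sum-exp), so tables with margins of tens of
thousands are handled without underflow. The odds-ratio interval is the
Woolf (logit) interval with z = 1.959964; zero cells raise an error unless
the Haldane–Anscombe +0.5 correction is requested (no packaged comparison
has a zero cell). Odds ratios are rounded to two significant figures for
report output only; internal values are never rounded. Bonferroni is the
only multiplicity adjustment provided.

Note that small-count published comparisons of this design are sometimes
quoted with the p-value of the z-test on ln OR (the output of common
online OR calculators), which can be markedly smaller than the Fisher exact
p for thin cells (e.g. 0.007 vs 0.018 for a 4/15-vs-447/7726 table). This
package reports the Fisher exact p.

## The packaged cohort

The fixture transcribes a published 100-subject trio-WGS ASD cohort: 151
de novo coding variants (mean 1.5/subject, range 0–6), one inherited
same-gene companion variant, per-symbol gene annotations, laboratory-report
designations, and genome-wide class tallies (de novo missense/silent PDV
counts over 100 subjects; inherited missense/silent/UTR/up+downstream
counts over randomised subsets of 50/50/50/25 subjects, CNVs and mtDNA
excluded). Two rows need comment:

* the monosomy-X row is encoded with the synthetic placeholder symbol
  `CHRX` carrying category A1 (a whole-chromosome event spans directly
  ASD-associated genes; the row is excluded on prevalence regardless);
* multi-gene CNV rows carry the genes the source names, with the row-level
  category on the best-supported gene.

The per-subject phenotype table is a deterministic reconstruction from
published aggregates (85/95 with at least moderate intellectual
disability, 29 nonverbal, 31 with epilepsy, plus regression, sex and tic
counts) jointly with the published 2×2 margins against PDV carriage. It is
synthetic at the individual-subject level: only its aggregate cross-tables
are meaningful.

### Known bookkeeping discrepancies

The source's own arithmetic is internally inconsistent (its PDV type
breakdown, per-subject histogram, variant listing and stated total give
77, 78 and 79 in different places). Applying the rules as stated to every
row yields **81 PDVs (46 missense, 19 silent, 4 frameshift, 3 nonsense,
2 splice, 7 CNV) in 55 subjects**: two missense variants pass every stated
criterion but are absent from the source's PDV listing. The engine reports
what the rules imply; the acceptance test records the published total of
79 and therefore disagrees by two — this is documented rather than patched,
because no single rule set can produce the published total, subject yield
and silent count simultaneously. The same applies to one published
confidence-interval bound (1.2 where the Woolf interval from the printed
counts gives 1.14) and to the pre-silent subject yield (engine 48,
published 47).

## The synthetic-cohort generator

`pdvkit.simulate` draws cohorts with the structure the analysis assumes:
Poisson(1.5) de novo coding variants per subject (0.2–0.3 is typical of
unaffected individuals and is supported as an alternative rate); variant
classes from the packaged cohort's empirical mixture; inherited counts
Poisson per class (157 missense, 90.5 silent, 287 UTR, 327 up/downstream
per subject); SFARI membership Bernoulli with odds = class OR × baseline
odds (baseline 5.57%), so a configured class odds ratio is exactly the
estimand of the Woolf interval; and every de novo variant planted either
to pass all rules or to fail exactly one planted rule. One RNG stream per
subject is derived from (seed, subject index), so cohorts are reproducible
and stable under subject-count changes.

What the generator does **not** emulate: linkage between variants, gene
length or mutability differences, realistic mutation spectra, annotation
noise (scores near the thresholds), correlated multi-reason failures, or
genotype–phenotype dependence (phenotype features are drawn independently
of genotype). Passing tests on synthetic cohorts therefore demonstrate the
*internal consistency* of engine + statistics (planted truth is recovered
exactly; type-I error ≈ 0.05 at genome-wide counts; Woolf coverage ≈ 95%),
not robustness to noisy real-world annotation.

## Numerical and design choices

* Exhaustive (non-short-circuited) rule evaluation so reason combinations
  are countable; reasons are reported in a fixed canonical order.
* Strict inequality at the frequency/conservation/splice thresholds,
  inclusive at the heteroplasmy thresholds (see above).
* Fisher tie tolerance 1e-7 relative; oracle tests compare against
  exact-rational enumeration at 1e-10 relative on small tables.
* Monotonicity invariants are tested: enabling silent scoring only adds
  silent PDVs; tightening any threshold never adds a PDV.
* TSV cells distinguish absent ("", never a number) from observed zero;
  the three curated-table sentinels `common`, `just<0.0001` and `0.00%`
  map to 1.0, 9.9e-5 and 0.0.
* Calibration and monotonicity test sizes (2000 replicates at genome-wide
  counts; 50 synthetic cohorts of 40 subjects, de novo only) were chosen to
  give stable Monte-Carlo estimates at second-scale runtimes.

## Limitations

The rule thresholds are the study's operating point, not optimised values;
the engine provides no uncertainty on individual classifications; gene
categories are config and inherit any curation error; the phenotype fixture
supports only the published aggregate cross-tables; and the enrichment
analysis treats variants as independent draws, ignoring within-subject and
within-gene correlation.
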