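"""The PDV rule engine: individual rules, whole-cohort behaviour, and the
monotonicity invariants."""

from dataclasses import replace

import pytest

from pdvkit.engine import (
    Conservation,
    DEFAULT_OPTIONS,
    EngineOptions,
    RuleOutcome,
    UnresolvedGeneError,
    assess_ar,
    assess_conservation,
    assess_gene,
    assess_mtdna,
    assess_rarity,
    assess_splice,
    classify_cohort,
    classify_variant,
)
from pdvkit.model import (
    GeneAnnotation,
    GeneCategory,
    ManualConservation as MC,
    Reason,
    VariantClass as VC,
    VariantRecord,
)

OPT = DEFAULT_OPTIONS


# --- rarity ---------------------------------------------------------------

@pytest.mark.parametrize("af1,af2,patho,expected", [
    # borderline fail: combined prevalence just above 1/10,000
    (0.000099, 0.00014, False, RuleOutcome.FAIL),
    (0.0, 0.0, False, RuleOutcome.PASS),
    # pathogenic CNV override: passes despite prevalence above threshold
    (0.001, None, True, RuleOutcome.PASS),
    # combined mean below threshold though one source exceeds it
    (0.000085, 0.00011, False, RuleOutcome.PASS),
    (0.00023, 0.000079, False, RuleOutcome.FAIL),
    (9.9e-5, None, False, RuleOutcome.PASS),   # "just <0.0001"
    (1e-4, 1e-4, False, RuleOutcome.FAIL),     # threshold is strict
])
def test_rarity_rule(af1, af2, patho, expected):
    outcome, _ = assess_rarity(af1, af2, patho, OPT)
    assert outcome is expected


def test_rarity_indeterminate_passes_with_warning():
    outcome, warning = assess_rarity(None, None, False, OPT)
    assert outcome is RuleOutcome.PASS and warning


# --- conservation ---------------------------------------------------------

@pytest.mark.parametrize("vclass,phylop,phastcons,manual,expected", [
    (VC.MISSENSE, 0.935, 0.935, MC.NONE, Conservation.CONSERVED),
    (VC.MISSENSE, -0.836, 0.0, MC.NONE, Conservation.NOT_CONSERVED),
    # disagreeing scores resolved by the manual genome-browser verdict
    (VC.MISSENSE, 0.935, 0.52, MC.HIGH_MAMMALS, Conservation.CONSERVED),
    (VC.MISSENSE, 1.199, 0.548, MC.LOW_MAMMALS, Conservation.NOT_CONSERVED),
    (VC.MISSENSE, 0.892, 0.003, MC.HIGH_VERTEBRATES, Conservation.CONSERVED),
    (VC.MISSENSE, 0.146, 0.922, MC.HIGH_AMNIOTES, Conservation.CONSERVED),
    # both scores below the low bar override a recorded high verdict
    (VC.MISSENSE, -0.344, 0.177, MC.HIGH_VERTEBRATES,
     Conservation.NOT_CONSERVED),
    # truncating / synonymous / structural classes are exempt
    (VC.SILENT, None, None, MC.NONE, Conservation.EXEMPT),
    (VC.FRAMESHIFT, None, None, MC.NONE, Conservation.EXEMPT),
    (VC.NONSENSE, None, None, MC.NONE, Conservation.EXEMPT),
    (VC.CNV_DEL, None, None, MC.NONE, Conservation.EXEMPT),
    (VC.ANEUPLOIDY, None, None, MC.NONE, Conservation.EXEMPT),
])
def test_conservation_rule(vclass, phylop, phastcons, manual, expected):
    outcome, _ = assess_conservation(vclass, phylop, phastcons, manual, OPT)
    assert outcome is expected


def test_conservation_disagreement_without_verdict_warns():
    outcome, warning = assess_conservation(
        VC.MISSENSE, 0.9, 0.1, MC.NONE, OPT)
    assert outcome is Conservation.NOT_CONSERVED and warning


# --- gene association -----------------------------------------------------

def _g(cat, ar=False):
    return GeneAnnotation(symbol="G", category=GeneCategory(cat), ar_only=ar)


@pytest.mark.parametrize("cats,expected", [
    (["A2"], RuleOutcome.PASS),
    (["B0"], RuleOutcome.PASS),
    (["B3"], RuleOutcome.FAIL),
    (["B1"], RuleOutcome.FAIL),
    # a CNV spanning any associated gene is eligible
    (["B3", "A2", "B1"], RuleOutcome.PASS),
])
def test_gene_association_rule(cats, expected):
    assert assess_gene([_g(c) for c in cats], OPT) is expected


@pytest.mark.parametrize("ar,companion,expected", [
    (True, False, RuleOutcome.FAIL),   # lone hit in an AR gene = carrier
    (True, True, RuleOutcome.PASS),    # rescued by a same-gene second hit
    (False, False, RuleOutcome.PASS),
])
def test_ar_carrier_rule(ar, companion, expected):
    assert assess_ar(_g("A1", ar=ar), companion) is expected


# --- mtDNA heteroplasmy ---------------------------------------------------

@pytest.mark.parametrize("subj,mother,expected", [
    (66, 33, RuleOutcome.PASS),
    (44, 34, RuleOutcome.FAIL),   # below 2x the mother
    (20, 4, RuleOutcome.FAIL),    # below the 40% floor
    (40, 20, RuleOutcome.PASS),   # both bounds inclusive
    (50, 0, RuleOutcome.PASS),    # mother at 0% satisfies the ratio
])
def test_heteroplasmy_rule(subj, mother, expected):
    outcome, _ = assess_mtdna(subj, mother, OPT)
    assert outcome is expected


def test_heteroplasmy_untested_mother_fails_with_warning():
    outcome, warning = assess_mtdna(31, None, OPT)
    assert outcome is RuleOutcome.FAIL and warning


# --- splice ---------------------------------------------------------------

@pytest.mark.parametrize("rf,ada,cons,expected", [
    (0.928, 0.99999, Conservation.CONSERVED, RuleOutcome.PASS),
    # no predictions available but the nucleotide is conserved
    (None, None, Conservation.CONSERVED, RuleOutcome.PASS),
    (0.5, 0.5, Conservation.NOT_CONSERVED, RuleOutcome.FAIL),
    (0.61, 0.1, Conservation.NOT_CONSERVED, RuleOutcome.PASS),
    (None, None, Conservation.NOT_CONSERVED, RuleOutcome.FAIL),
])
def test_splice_rule(rf, ada, cons, expected):
    assert assess_splice(rf, ada, cons, OPT) is expected


# --- whole-variant classification on the packaged cohort ------------------

def _results_by_gene(fixture_classifications):
    out = {}
    for sid, results in fixture_classifications.items():
        for r in results:
            out[(sid, r.record.gene_symbols)] = r
    return out


@pytest.mark.parametrize("sid,gene,is_pdv,reasons", [
    ("1", ("GRIK5",), True, ()),            # rare silent in an A2 gene
    ("10", ("COL4A4",), False, (Reason.GENE_NOT_ASSOCIATED,)),
    ("78", ("RFXANK",), False, (Reason.AR_CARRIER,)),
    ("13", ("CHRX",), False, (Reason.NOT_RARE,)),  # monosomy X, "common"
    ("32", ("KDM5B",), True, ()),           # AR gene rescued by companion
    ("19", ("TWF2",), False, (Reason.NOT_RARE,)),
    ("50", ("MT-CYB",), True, ()),          # mito silent at 66%/33%
    ("75", ("MT-ND5",), False, (Reason.HETEROPLASMY_FAIL,)),
    ("71", ("MT-RNR2",), False,
     (Reason.HETEROPLASMY_FAIL, Reason.NONCODING_CLASS)),
    ("34", ("CBARP",), True, ()),           # splice, conserved, no scores
    ("44", ("CORO1A", "SEZ6L2", "KCTD13", "TAOK2", "MAPK3"), True, ()),
])
def test_fixture_rows_classify_as_recorded(fixture_classifications, sid,
                                           gene, is_pdv, reasons):
    res = _results_by_gene(fixture_classifications)[(sid, gene)]
    assert res.is_pdv is is_pdv
    assert set(res.reasons) == set(reasons)


def test_reason_sets_nonempty_iff_not_pdv(fixture_classifications):
    for results in fixture_classifications.values():
        for r in results:
            assert r.is_pdv == (len(r.reasons) == 0)


def test_classify_variant_is_pure(fixture_bundle):
    rec = fixture_bundle.de_novo[0]
    a = classify_variant(rec, fixture_bundle.genes, OPT)
    b = classify_variant(rec, fixture_bundle.genes, OPT)
    assert a == b


def test_classify_requires_de_novo(fixture_bundle):
    inherited = [v for v in fixture_bundle.variants if not v.is_de_novo][0]
    with pytest.raises(ValueError):
        classify_variant(inherited, fixture_bundle.genes, OPT)


def test_unresolved_symbol_raises_unless_permissive(fixture_bundle):
    rec = VariantRecord(subject_id="x", gene_symbols=("NOSUCHGENE",),
                        variant_class=VC.MISSENSE, phylop=1.0, phastcons=1.0,
                        allele_freq_1=0.0)
    with pytest.raises(UnresolvedGeneError):
        classify_variant(rec, fixture_bundle.genes, OPT)
    permissive = replace(OPT, strict_gene_resolution=False)
    res = classify_variant(rec, fixture_bundle.genes, permissive)
    assert Reason.GENE_NOT_ASSOCIATED in res.reasons


def test_cohort_classification_covers_every_de_novo_record(
        fixture_bundle, fixture_classifications):
    n = sum(len(v) for v in fixture_classifications.values())
    assert n == len(fixture_bundle.de_novo)
    # zero-variant subjects still appear in the map
    assert fixture_classifications["6"] == []
    assert len(fixture_classifications) == 100


def _pdv_set(bundle, options):
    out = set()
    for sid, results in classify_cohort(bundle, options).items():
        out.update((sid, r.record.label) for r in results if r.is_pdv)
    return out


def test_silent_toggle_superset_on_fixture(fixture_bundle):
    with_silent = _pdv_set(fixture_bundle, OPT)
    without = _pdv_set(fixture_bundle, replace(OPT, include_silent=False))
    assert without <= with_silent
    diff_labels = with_silent - without
    classes = {
        r.variant_class.value
        for r in fixture_bundle.de_novo
        if (r.subject_id, r.label) in diff_labels
    }
    assert classes == {"silent"}


@pytest.mark.parametrize("tightened", [
    dict(freq_threshold=1e-5),
    dict(cons_high=0.95),
    dict(splice_threshold=0.95),
    dict(het_min_pct=60.0),
    dict(manual_conservation_accepts=frozenset({MC.HIGH_MAMMALS})),
    dict(eligible_categories=frozenset({GeneCategory.A1, GeneCategory.A2})),
])
def test_tightening_thresholds_never_adds_pdvs(fixture_bundle, tightened):
    default = _pdv_set(fixture_bundle, OPT)
    tight = _pdv_set(fixture_bundle, replace(OPT, **tightened))
    assert tight <= default


# --- options from config --------------------------------------------------

def test_options_load_from_toml(tmp_path):
    from pdvkit.engine import load_options
    cfg = tmp_path / "engine.toml"
    cfg.write_text(
        "[engine]\ninclude_silent = false\nfreq_threshold = 5e-5\n"
        'manual_conservation_accepts = ["high_mammals"]\n'
        'eligible_categories = ["A1", "A2"]\n')
    opts = load_options(cfg)
    assert not opts.include_silent
    assert opts.freq_threshold == 5e-5
    assert opts.manual_conservation_accepts == frozenset({MC.HIGH_MAMMALS})
    assert opts.cons_high == OPT.cons_high  # unspecified keys keep defaults


def test_unknown_option_key_rejected(tmp_path):
    from pdvkit.engine import load_options
    cfg = tmp_path / "engine.toml"
    cfg.write_text("typo_threshold = 1\n")
    with pytest.raises(ValueError, match="typo_threshold"):
        load_options(cfg)
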