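"""Fisher exact test against independent oracles, Woolf intervals, and the
enrichment comparison matrix."""

import math
from fractions import Fraction

import numpy as np
import pytest

from pdvkit.io import read_table3_tallies
from pdvkit.model import ClassLabel as L, ClassTally
from pdvkit.stats import (
    bonferroni,
    build_tallies,
    compare_classes,
    fisher_exact_two_tailed,
    odds_ratio_ci,
    round_or,
    sfari_baseline,
)


def fisher_enumeration(a, b, c, d):
    """Independent oracle: exact-rational enumeration of the full support.

    Point probabilities are hypergeometric fractions C(r1,k)C(r2,c1-k)/C(n,c1);
    the two-tailed p sums every table whose probability is <= the observed
    table's (exact comparison, no floats until the end).
    """
    n = a + b + c + d
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
           for k in range(lo, hi + 1)}
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs))


def test_symmetric_table_gives_p_one():
    assert fisher_exact_two_tailed(1, 1, 1, 1) == pytest.approx(1.0)


def test_headline_table_is_highly_significant():
    # de novo missense PDVs vs up/downstream control
    assert fisher_exact_two_tailed(11, 32, 447, 7726) < 1e-4


def test_matches_enumeration_oracle_on_random_small_tables():
    rng = np.random.default_rng(20240917)
    for _ in range(200):
        r1, r2 = rng.integers(1, 31, size=2)
        c1 = int(rng.integers(1, r1 + r2))
        a = int(rng.integers(max(0, c1 - r2), min(r1, c1) + 1))
        b, c, d = int(r1) - a, c1 - a, int(r2) - (c1 - a)
        got = fisher_exact_two_tailed(a, b, c, d)
        want = fisher_enumeration(a, b, c, d)
        assert got == pytest.approx(want, rel=1e-10), (a, b, c, d)


def test_matches_scipy_on_large_margin_table():
    from scipy.stats import fisher_exact
    table = (696, 7142, 447, 7726)
    assert fisher_exact_two_tailed(*table) == pytest.approx(
        fisher_exact([[696, 7142], [447, 7726]])[1], rel=1e-9)


def test_invariance_under_transposition_and_row_column_swap():
    p = fisher_exact_two_tailed(4, 15, 447, 7726)
    assert fisher_exact_two_tailed(4, 447, 15, 7726) == pytest.approx(p, rel=1e-12)
    assert fisher_exact_two_tailed(7726, 447, 15, 4) == pytest.approx(p, rel=1e-12)


# --- odds ratio / Woolf interval ------------------------------------------

def test_woolf_interval_reproduces_published_cells():
    or_, lo, hi = odds_ratio_ci(506, 4020, 447, 7726)
    assert (round_or(or_), round_or(lo), round_or(hi)) == (2.2, 1.9, 2.5)
    or_, lo, hi = odds_ratio_ci(4, 15, 447, 7726)
    assert (round_or(or_), round_or(lo), round_or(hi)) == (4.6, 1.5, 14)


def test_balanced_table_gives_unit_odds_ratio():
    for k in (1, 5, 250):
        or_, lo, hi = odds_ratio_ci(k, k, k, k)
        assert or_ == pytest.approx(1.0)
        assert lo <= 1.0 <= hi


def test_matches_statsmodels_interval():
    sm_stats = pytest.importorskip("statsmodels.stats.contingency_tables")
    t = sm_stats.Table2x2([[696, 7142], [447, 7726]])
    or_, lo, hi = odds_ratio_ci(696, 7142, 447, 7726)
    sm_lo, sm_hi = t.oddsratio_confint()
    assert or_ == pytest.approx(t.oddsratio, rel=1e-12)
    assert lo == pytest.approx(sm_lo, rel=1e-6)
    assert hi == pytest.approx(sm_hi, rel=1e-6)


def test_zero_cell_requires_haldane_flag():
    with pytest.raises(ValueError, match="[Hh]aldane"):
        odds_ratio_ci(0, 10, 5, 10)
    or_, lo, hi = odds_ratio_ci(0, 10, 5, 10, haldane=True)
    assert 0 < lo <= or_ <= hi


def test_interval_widens_as_counts_shrink():
    _, lo1, hi1 = odds_ratio_ci(100, 200, 100, 200)
    _, lo2, hi2 = odds_ratio_ci(10, 20, 10, 20)
    assert (hi2 / lo2) > (hi1 / lo1)


# --- comparison matrix ----------------------------------------------------

def test_comparison_matrix_reciprocal_and_symmetric_p():
    tallies = read_table3_tallies()
    m = compare_classes(tallies)
    for x in L:
        for y in L:
            if x == y:
                continue
            fwd, rev = m.get(x, y), m.get(y, x)
            assert fwd.odds_ratio * rev.odds_ratio == pytest.approx(1.0, abs=1e-9)
            assert fwd.p_two_tailed == pytest.approx(rev.p_two_tailed, rel=1e-9)


def test_identical_tallies_give_null_comparison():
    a = ClassTally(L.INH_SILENT, 50, 1000, 100)
    b = ClassTally(L.INH_MISSENSE, 50, 1000, 100)
    r = compare_classes([a, b]).get(L.INH_SILENT, L.INH_MISSENSE)
    assert r.odds_ratio == pytest.approx(1.0)
    assert r.p_two_tailed == pytest.approx(1.0)


def test_self_comparison_rejected():
    tallies = read_table3_tallies()
    with pytest.raises(ValueError):
        compare_classes(tallies, [(L.INH_SILENT, L.INH_SILENT)])


# --- baseline and multiplicity --------------------------------------------

def test_sfari_baseline_percentage():
    assert sfari_baseline(1114, 20000) == pytest.approx(5.57)
    assert sfari_baseline(0, 20000) == 0.0


def test_control_class_proportion_close_to_baseline():
    # validates using up/downstream variants as the internal control
    assert abs(100 * 447 / 8173 - sfari_baseline()) < 0.15


def test_bonferroni_adjustment():
    assert bonferroni([1e-5, 0.5], 15) == [pytest.approx(1.5e-4), 1.0]
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], 1)


def test_primary_comparisons_survive_bonferroni():
    tallies = read_table3_tallies()
    ud = L.INH_UPDOWNSTREAM
    ps = [compare_classes(tallies, [(c, ud)]).get(c, ud).p_two_tailed
          for c in (L.DN_MISSENSE_PDV, L.INH_MISSENSE, L.INH_SILENT,
                    L.INH_UTR)]
    assert all(p < 0.05 for p in bonferroni(ps, 15))


# --- tallies from classifications -----------------------------------------

def test_fixture_tallies_count_small_nuclear_pdvs_only(
        fixture_bundle, fixture_classifications):
    tallies = {t.class_label: t
               for t in build_tallies(fixture_classifications, fixture_bundle)}
    # the packaged cohort has no inherited missense/silent/UTR rows
    assert tallies[L.INH_UTR].n_variants == 0
    # de novo silent: 18 nuclear silent PDVs (the mito silent PDV is
    # excluded from the genome-wide tally, as are CNVs)
    assert tallies[L.DN_SILENT_PDV].n_variants == 18
    dn_mis = tallies[L.DN_MISSENSE_PDV]
    assert dn_mis.n_variants == 46
    assert dn_mis.n_sfari <= dn_mis.n_variants
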