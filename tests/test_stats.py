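"""Contingency construction, exact-test oracles and proximity binning."""
import math
from itertools import product

import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from conftest import make_kb, make_record
from vusact.assay import AssayCall, AssayVerdict, BAF3
from vusact.classifier import ClassificationResult, RuleFired
from vusact.errors import DegenerateTableError, JoinError
from vusact.knowledgebase import ActionabilityValue
from vusact.stats import (
    ContingencyTable2x2,
    build_contingency,
    fisher_exact_2x2,
    proximity_distribution,
)
from vusact.variant import parse_protein_change

P, U = ActionabilityValue.POTENTIALLY, ActionabilityValue.UNKNOWN


def _cls(change, value, gene="G"):
    return ClassificationResult(
        parse_protein_change(gene, change), value, RuleFired.NO_RULE
    )


def _call(change, verdict, gene="G"):
    return AssayCall(parse_protein_change(gene, change), verdict, (BAF3,))


# --- independent oracles -----------------------------------------------------


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hypergeom_pmf(a, r1, r2, c1):
    """P(top-left cell = a) with margins (r1, r2) x (c1, .) under H0."""
    n = r1 + r2
    return math.exp(
        _log_binom(r1, a) + _log_binom(r2, c1 - a) - _log_binom(n, c1)
    )


def fisher_p_enumeration(a, b, c, d):
    """Two-sided exact p by exhaustive enumeration of all tables with the
    observed margins: sum point probabilities <= the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    p_obs = _hypergeom_pmf(a, r1, r2, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = _hypergeom_pmf(x, r1, r2, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def conditional_mle_or(a, b, c, d):
    """Odds parameter maximizing the noncentral hypergeometric likelihood,
    by direct scalar maximization over log-odds."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf

    support = range(lo, hi + 1)
    logw = {x: _log_binom(r1, x) + _log_binom(r2, c1 - x) for x in support}

    def neg_loglik(log_psi):
        terms = [logw[x] + x * log_psi for x in support]
        m = max(terms)
        log_norm = m + math.log(sum(math.exp(t - m) for t in terms))
        return -(logw[a] + a * log_psi - log_norm)

    res = minimize_scalar(neg_loglik, bounds=(-50, 50), method="bounded",
                          options={"xatol": 1e-12})
    return math.exp(res.x)


# --- fisher_exact_2x2 --------------------------------------------------------


@pytest.mark.parametrize(
    "table, or_expected, p_expected",
    [
        ((76, 128, 30, 200), 3.94, 4.08e-09),
        ((290, 369, 9, 109), 9.50, 4.719e-16),
    ],
)
def test_validation_tables_reproduce_reported_statistics(table, or_expected, p_expected):
    res = fisher_exact_2x2(ContingencyTable2x2(*table))
    assert res.odds_ratio == pytest.approx(or_expected, abs=0.01)
    assert res.p_two_sided == pytest.approx(p_expected, rel=0.01)


def test_symmetric_table_is_null():
    res = fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1))
    assert res.p_two_sided == pytest.approx(1.0)
    assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)


def test_row_swap_inverts_odds_ratio_and_preserves_p():
    t = ContingencyTable2x2(12, 5, 3, 9)
    r1 = fisher_exact_2x2(t)
    r2 = fisher_exact_2x2(ContingencyTable2x2(3, 9, 12, 5))
    assert r2.odds_ratio == pytest.approx(1 / r1.odds_ratio, rel=1e-6)
    assert r2.p_two_sided == pytest.approx(r1.p_two_sided, rel=1e-9)


def test_conditional_mle_differs_from_sample_or_on_validation_table():
    res = fisher_exact_2x2(ContingencyTable2x2(76, 128, 30, 200))
    assert res.sample_odds_ratio == pytest.approx(76 * 200 / (128 * 30), rel=1e-12)
    assert res.odds_ratio < res.sample_odds_ratio  # 3.945 vs 3.958
    assert res.odds_ratio == pytest.approx(
        conditional_mle_or(76, 128, 30, 200), rel=1e-4
    )


def test_p_matches_enumeration_oracle_for_all_small_tables():
    """Exact p equals exhaustive enumeration for every table with all
    margins <= 8 and no zero margin."""
    checked = 0
    for a, b, c, d in product(range(5), repeat=4):
        if 0 in (a + b, c + d, a + c, b + d):
            continue
        if max(a + b, c + d, a + c, b + d) > 8:
            continue
        res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert res.p_two_sided == pytest.approx(
            fisher_p_enumeration(a, b, c, d), rel=1e-7, abs=1e-12
        ), (a, b, c, d)
        checked += 1
    assert checked > 300


def test_conditional_mle_matches_likelihood_oracle():
    tables = [(5, 2, 1, 7), (3, 3, 2, 4), (8, 1, 2, 6), (2, 5, 5, 2), (1, 4, 2, 3)]
    for a, b, c, d in tables:
        res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert res.odds_ratio == pytest.approx(
            conditional_mle_or(a, b, c, d), rel=1e-4
        ), (a, b, c, d)


def test_boundary_tables_give_zero_or_infinite_or():
    assert fisher_exact_2x2(ContingencyTable2x2(0, 5, 3, 2)).odds_ratio == 0.0
    assert math.isinf(fisher_exact_2x2(ContingencyTable2x2(5, 0, 2, 3)).odds_ratio)


def test_degenerate_margin_rejected():
    with pytest.raises(DegenerateTableError):
        fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 2))


# --- build_contingency -------------------------------------------------------


def test_contingency_excludes_conflicting_and_non_informative():
    classifications = [
        _cls("A10V", P), _cls("A11V", P), _cls("A12V", U),
        _cls("A13V", U), _cls("A14V", P), _cls("A15V", U),
    ]
    calls = [
        _call("A10V", AssayVerdict.ONCOGENIC),
        _call("A11V", AssayVerdict.NOT_ONCOGENIC),
        _call("A12V", AssayVerdict.ONCOGENIC),
        _call("A13V", AssayVerdict.NOT_ONCOGENIC),
        _call("A14V", AssayVerdict.CONFLICTING),
        _call("A15V", AssayVerdict.NON_INFORMATIVE),
    ]
    t = build_contingency(classifications, calls)
    assert t.as_lists() == [[1, 1], [1, 1]]


def test_contingency_all_oncogenic_toy():
    classifications = [_cls(f"A{i}V", P) for i in range(10, 14)]
    calls = [_call(f"A{i}V", AssayVerdict.ONCOGENIC) for i in range(10, 14)]
    assert build_contingency(classifications, calls).as_lists() == [[4, 0], [0, 0]]


def test_contingency_strict_join():
    with pytest.raises(JoinError):
        build_contingency([_cls("A10V", P)], [], strict=True)


# --- proximity distribution --------------------------------------------------


def _v(change, gene="G"):
    return parse_protein_change(gene, change)


def test_binning_arithmetic():
    kb = make_kb(make_record("G", "A100V", ActionabilityValue.YES))
    vus = [_v("C100W"), _v("C100Y"), _v("C102W"), _v("C107W")]
    dist = proximity_distribution(vus, kb)
    assert dist.counts == {"0": 2, "1-2": 1, "3-5": 0, ">5": 1}
    assert dist.fractions["0"] == pytest.approx(0.5)
    assert sum(dist.fractions.values()) == pytest.approx(1.0)


def test_every_vus_on_an_anchor_gives_bin_zero_fraction_one():
    kb = make_kb(make_record("G", "A100V", ActionabilityValue.YES))
    vus = [_v("C100W"), _v("C100Y"), _v("C100T")]
    dist = proximity_distribution(vus, kb)
    assert dist.fractions["0"] == 1.0


def test_empty_input_flags_undefined_fractions():
    kb = make_kb(make_record("G", "A100V", ActionabilityValue.YES))
    dist = proximity_distribution([], kb)
    assert dist.n == 0
    assert all(math.isnan(f) for f in dist.fractions.values())


def test_truncating_input_rejected():
    kb = make_kb(make_record("G", "A100V", ActionabilityValue.YES))
    with pytest.raises(ValueError):
        proximity_distribution([_v("K132fs")], kb)


def test_unreached_variants_excluded_from_denominator():
    kb = make_kb(
        make_record("G", "A100V", ActionabilityValue.YES),
        make_record("H", "A10V", ActionabilityValue.UNKNOWN),
    )
    dist = proximity_distribution([_v("C100W"), _v("C5W", "H")], kb)
    assert dist.unreached == 1
    assert dist.n == 1
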