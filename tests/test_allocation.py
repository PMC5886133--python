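import numpy as np
import pytest
from helpers import toy_panel
from hypothesis import given, settings
from hypothesis import strategies as st

from fgaps.allocation import (
    GapResult,
    allocate,
    allocate_budget,
    compute_gaps,
    rank_countries,
)
from fgaps.errors import AlignmentError, ConfigError
from fgaps.expected_spend import ExpectedSpendResult
from fgaps.need import NeedResult
from fgaps.panel import RunConfig
from fgaps.potential_spend import PotentialSpendResult

money = st.floats(min_value=0.0, max_value=1e10, allow_nan=False)


def _gap(cid="A", n=100.0, ps=60.0, es=40.0) -> GapResult:
    return GapResult(cid, n, es, ps)


def test_gap_definitions():
    g = _gap(n=100, ps=60, es=40)
    assert (g.gap_a, g.gap_b, g.gap_total) == (40.0, 20.0, 60.0)
    zero = _gap(n=50, ps=50, es=50)
    assert (zero.gap_a, zero.gap_b, zero.gap_total) == (0.0, 0.0, 0.0)


def test_negative_gap_b_is_retained():
    # expected spending can exceed potential spending; Gap B stays negative
    g = _gap(n=100, ps=30, es=45)
    assert g.gap_b == -15.0
    assert g.gap_a + g.gap_b == g.gap_total


@settings(deadline=None, derandomize=True)
@given(n=money, es=money, ps=money)
def test_gap_decomposition_identity(n, es, ps):
    g = GapResult("A", n, es, ps)
    assert g.gap_a + g.gap_b == g.gap_total  # exact in floating point


def test_compute_gaps_requires_matching_country_sets():
    need = [NeedResult("A", [2030], [1.0], 1.0, 4205.0, 4205.0)]
    es = [ExpectedSpendResult("A", [2030], [0.1], [5.0], 5e6)]
    ps = [
        PotentialSpendResult("B", [2030], [1.0], [50.0], [0.1], [5.0], 5e6, ())
    ]
    with pytest.raises(AlignmentError, match="country sets differ"):
        compute_gaps(need, es, ps)


@pytest.mark.parametrize(
    "beta, expected_dah",
    [
        (0.0, 4.0),    # alpha (N - PS) = 0.1 * 40
        (1.0, 6.0),    # alpha (N - ES) = 0.1 * 60
        (-0.5, 3.0),   # 0.1 * (40 - 0.5 * 20)
    ],
)
def test_formula_reduction_cases(beta, expected_dah):
    allocs = allocate([_gap()], RunConfig(alpha=0.1, beta=beta))
    assert allocs[0].dah_usd == pytest.approx(expected_dah, rel=1e-12)


def test_beta_zero_ignores_expected_spending():
    base = allocate([_gap(es=40)], RunConfig(alpha=0.1, beta=0.0))
    moved = allocate([_gap(es=400)], RunConfig(alpha=0.1, beta=0.0))
    assert base[0].dah_usd == moved[0].dah_usd


def test_negative_raw_terms_floor_at_zero():
    allocs = allocate([_gap(n=10, ps=60, es=40)], RunConfig(alpha=0.1, beta=0.0))
    assert allocs[0].raw_term < 0
    assert allocs[0].dah_usd == 0.0
    assert allocs[0].clipped


def test_missing_alpha_and_budget_is_a_config_error():
    with pytest.raises(ConfigError, match="alpha or budget"):
        allocate([_gap()], RunConfig())


def test_budget_proportionality():
    gaps = [_gap("A", n=210, ps=60), _gap("B", n=110, ps=60)]  # terms 150, 50
    allocs = allocate_budget(gaps, budget=10.0, beta=0.0)
    assert allocs[0].alpha == pytest.approx(0.05)
    assert [a.dah_usd for a in allocs] == [pytest.approx(7.5), pytest.approx(2.5)]


def test_single_country_full_funding():
    allocs = allocate_budget([_gap(n=260, ps=60)], budget=200.0, beta=0.0)
    assert allocs[0].alpha == pytest.approx(1.0)
    assert allocs[0].dah_usd == pytest.approx(200.0)


def test_budget_with_nothing_to_fund_errors():
    with pytest.raises(ConfigError, match="nothing to fund"):
        allocate_budget([_gap(n=10, ps=60, es=70)], budget=5.0, beta=0.0)


@settings(deadline=None, derandomize=True)
@given(
    beta=st.floats(min_value=-1.0, max_value=1.0),
    seed=st.integers(min_value=0, max_value=999),
)
def test_budget_conservation_on_random_instances(beta, seed):
    rng = np.random.default_rng(seed)
    gaps = [
        GapResult(f"C{i}", *rng.uniform(0, 1e9, 3)) for i in range(20)
    ]
    if not any(max(0.0, g.gap_a + beta * g.gap_b) > 0 for g in gaps):
        return
    budget = 1e7
    allocs = allocate_budget(gaps, budget, beta)
    assert sum(a.dah_usd for a in allocs) == pytest.approx(budget, rel=1e-6)


@pytest.mark.parametrize("beta, direction", [(-0.5, 1), (0.5, -1)])
def test_incentive_direction_of_beta(beta, direction):
    """beta < 0 strictly rewards higher domestic spending; beta > 0 penalises."""
    lo = allocate([_gap(es=40)], RunConfig(alpha=0.1, beta=beta))[0].dah_usd
    hi = allocate([_gap(es=50)], RunConfig(alpha=0.1, beta=beta))[0].dah_usd
    assert np.sign(hi - lo) == direction


def _three_country_setup():
    panel = toy_panel(
        {
            "A": {"gdp_pc": 500.0, "u5mr": 90.0},
            "B": {"gdp_pc": 1500.0, "u5mr": 90.0},
            "C": {"gdp_pc": 1000.0, "u5mr": 40.0},
        },
        range(2013, 2016), 2015,
    )
    gaps = [
        _gap("A", n=300, ps=100, es=50),
        _gap("B", n=200, ps=100, es=50),
        _gap("C", n=100, ps=100, es=50),
    ]
    return panel, gaps


def test_rankings_sort_and_break_ties_deterministically():
    panel, gaps = _three_country_setup()
    by_gap = rank_countries(panel, gaps, "gap_total")
    assert list(by_gap["country_id"]) == ["A", "B", "C"]  # descending gap
    assert list(by_gap["rank"]) == [1, 2, 3]
    by_gdp = rank_countries(panel, gaps, "gdp_pc")
    assert list(by_gdp["country_id"]) == ["A", "C", "B"]  # ascending income
    by_mort = rank_countries(panel, gaps, "u5mr")
    # A and B tie on u5mr; lexicographic country id breaks the tie
    assert list(by_mort["country_id"]) == ["A", "B", "C"]


def test_spending_blind_mortality_ranking_can_differ_from_gap_a():
    """When spending is uncorrelated with mortality, ranking by Gap A
    disagrees with ranking by raw mortality somewhere, for most draws."""
    rng = np.random.default_rng(123)
    differs = 0
    for _ in range(20):
        u5 = rng.uniform(30, 150, 8)
        ps = rng.uniform(1e6, 1e8, 8)
        n = u5 * 1e6  # need scales with mortality burden
        panel = toy_panel(
            {f"C{i}": {"u5mr": float(u5[i])} for i in range(8)},
            range(2013, 2016), 2015,
        )
        gaps = [GapResult(f"C{i}", float(n[i]), 0.0, float(ps[i])) for i in range(8)]
        a = list(rank_countries(panel, gaps, "gap_a")["country_id"])
        m = list(rank_countries(panel, gaps, "u5mr")["country_id"])
        differs += a != m
    assert differs >= 18
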