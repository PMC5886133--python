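import numpy as np
import pytest
from helpers import toy_panel
from hypothesis import given, settings
from hypothesis import strategies as st

from fgaps.errors import AlignmentError, ConfigError, FgapsError
from fgaps.mortality import ExpectedTrend
from fgaps.need import (
    annual_rate_of_reduction,
    compute_need,
    lives_to_save,
    required_trajectory,
)
from fgaps.panel import RunConfig

YEARS_2016_2030 = list(range(2016, 2031))


def _trend(values, country="A", years=YEARS_2016_2030):
    values = list(np.broadcast_to(values, len(years)).astype(float))
    return ExpectedTrend(country, list(years), values)


def test_arr_closed_form_matches_iterated_multiplication():
    # Baseline 100 per 1000 in 2015, target 25 by 2030.
    arr = annual_rate_of_reduction(100.0, 25.0, 15)
    assert arr == pytest.approx(1 - 0.25 ** (1 / 15), abs=1e-15)
    level = 100.0
    for _ in range(15):
        level *= 1 - arr
    assert level == pytest.approx(25.0, rel=1e-9)


@settings(deadline=None, derandomize=True)
@given(baseline=st.floats(min_value=25.01, max_value=900.0))
def test_required_path_hits_target_exactly(baseline):
    req = required_trajectory(baseline, RunConfig(), _trend(baseline))
    assert req.u5mr_required[-1] == pytest.approx(25.0, rel=1e-9)
    ratios = np.diff(np.log(req.u5mr_required))
    np.testing.assert_allclose(ratios, ratios[0], atol=1e-9)  # geometric


def test_continuous_arr_mode_agrees_with_geometric():
    geo = required_trajectory(100.0, RunConfig(), _trend(100.0))
    cont = required_trajectory(
        100.0, RunConfig(arr_mode="continuous"), _trend(100.0)
    )
    np.testing.assert_allclose(geo.u5mr_required, cont.u5mr_required, rtol=1e-12)


def test_baseline_at_target_keeps_constant_path():
    expected = _trend(np.linspace(24.0, 30.0, 15))
    req = required_trajectory(25.0, RunConfig(), expected)
    assert req.arr_required == 0.0
    # capped by the expected path where that is lower than the target
    np.testing.assert_allclose(
        req.u5mr_required, np.minimum(expected.u5mr_expected, 25.0)
    )


def test_baseline_below_target_generates_zero_lives():
    panel = toy_panel({"A": {}, "B": {}, "C": {}}, range(2010, 2031), 2015)
    expected = _trend(20.0)
    req = required_trajectory(20.0, RunConfig(), expected)
    lives = lives_to_save(expected, req, panel, RunConfig())
    assert (lives == 0).all()


def test_nonpositive_baseline_rejected():
    with pytest.raises(ConfigError, match="positive"):
        required_trajectory(0.0, RunConfig(), _trend(50.0))


def test_lives_arithmetic_single_year():
    panel = toy_panel(
        {"A": {"live_births": 1e5}, "B": {}, "C": {}}, range(2010, 2031), 2015
    )
    expected = _trend(50.0)
    req = required_trajectory(50.0, RunConfig(), expected)
    # force a flat required path at 40 for the arithmetic check
    req = type(req)("A", req.years, [40.0] * len(req.years), 0.0)
    lives = lives_to_save(expected, req, panel, RunConfig())
    np.testing.assert_allclose(lives, 1000.0)  # (50-40)/1000 * 1e5


def test_lives_floored_when_expected_below_required():
    panel = toy_panel({"A": {}, "B": {}, "C": {}}, range(2010, 2031), 2015)
    expected = _trend(30.0)
    req = type(required_trajectory(50.0, RunConfig(), expected))(
        "A", YEARS_2016_2030, [45.0] * 15, 0.0
    )
    lives = lives_to_save(expected, req, panel, RunConfig())
    assert (lives == 0).all()


def test_lives_match_spreadsheet_style_evaluation():
    """Constant expected 60, geometric required 60 -> 25 over 5 years,
    constant births: year-by-year hand evaluation is the oracle."""
    years = list(range(2016, 2021))
    births = 2e5
    panel = toy_panel(
        {"A": {"live_births": births}, "B": {}, "C": {}},
        range(2010, 2021), 2015,
    )
    config = RunConfig(goal_target_year=2020)
    expected = _trend(60.0, years=years)
    req = required_trajectory(60.0, config, expected)
    lives = lives_to_save(expected, req, panel, config)
    arr = 1 - (25 / 60) ** (1 / 5)
    oracle = []
    for k in range(1, 6):
        required_k = 60.0 * (1 - arr) ** k
        oracle.append(max(0.0, 60.0 - required_k) / 1000 * births)
    np.testing.assert_allclose(lives.to_numpy(), oracle, rtol=1e-12)


def test_population_denominator_option():
    panel = toy_panel(
        {"A": {"population": 1e6, "live_births": 1e4}, "B": {}, "C": {}},
        range(2010, 2031), 2015,
    )
    expected = _trend(50.0)
    req = required_trajectory(50.0, RunConfig(), expected)
    by_births = lives_to_save(expected, req, panel, RunConfig())
    by_pop = lives_to_save(
        expected, req, panel, RunConfig(denominator="population")
    )
    np.testing.assert_allclose(by_pop.loc[2016:2030], by_births * 100)


def test_year_misalignment_rejected():
    expected = _trend(50.0)
    req = required_trajectory(50.0, RunConfig(), _trend(50.0))
    req = type(req)("A", [y + 1 for y in req.years], req.u5mr_required, req.arr_required)
    panel = toy_panel({"A": {}, "B": {}, "C": {}}, range(2010, 2032), 2015)
    with pytest.raises(AlignmentError, match="year mismatch"):
        lives_to_save(expected, req, panel, RunConfig())


@pytest.mark.parametrize(
    "lives_total, group, expected_usd",
    [
        (1000.0, "low", 4_205_000.0),
        (0.0, "low", 0.0),
        (10.0, "upper-middle", 100_160.0),
        (100.0, "lower-middle", 649_600.0),
    ],
)
def test_need_is_lives_times_published_unit_cost(lives_total, group, expected_usd):
    import pandas as pd

    lives = pd.Series([lives_total], index=pd.Index([2030], name="year"))
    result = compute_need(lives, group, RunConfig(), country_id="A")
    assert result.need_usd == expected_usd
    assert result.need_usd == result.lives_total * result.unit_cost


def test_high_income_with_positive_lives_errors():
    import pandas as pd

    lives = pd.Series([5.0], index=pd.Index([2030], name="year"))
    with pytest.raises(FgapsError, match="high"):
        compute_need(lives, "high", RunConfig(), country_id="A")
    zero = pd.Series([0.0], index=pd.Index([2030], name="year"))
    assert compute_need(zero, "high", RunConfig()).need_usd == 0.0


@settings(deadline=None, derandomize=True)
@given(
    bump=st.floats(min_value=0.0, max_value=50.0),
    year_idx=st.integers(min_value=0, max_value=14),
)
def test_need_monotone_in_expected_trend(bump, year_idx):
    panel = toy_panel({"A": {}, "B": {}, "C": {}}, range(2010, 2031), 2015)
    config = RunConfig()
    base_vals = np.full(15, 60.0)
    bumped = base_vals.copy()
    bumped[year_idx] += bump
    req = required_trajectory(60.0, config, _trend(base_vals))
    lo = compute_need(
        lives_to_save(_trend(base_vals), req, panel, config), "low", config
    )
    hi = compute_need(
        lives_to_save(_trend(bumped), req, panel, config), "low", config
    )
    assert hi.need_usd >= lo.need_usd
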