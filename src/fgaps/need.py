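"""Goal-compliant mortality trajectories, lives to save, and Need (N) in USD.

The required trajectory applies a constant annual rate of reduction (ARR)
taking baseline under-five mortality to the goal level exactly at the target
year. Additional lives to save in a year are the rate difference between the
expected trend and the required path, applied to live births (5q0 is a
probability per live birth). Need is lives times the income-group cost per
child life saved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, FgapsError
from .mortality import ExpectedTrend
from .panel import CountryYearPanel, RunConfig


@dataclass(frozen=True)
class RequiredTrajectory:
    """Geometric mortality path from the base-year level to the goal."""

    country_id: str
    years: list[int]
    u5mr_required: list[float]
    arr_required: float  # constant annual proportional reduction in [0, 1)

    def as_series(self) -> pd.Series:
        return pd.Series(self.u5mr_required, index=pd.Index(self.years, name="year"))


@dataclass(frozen=True)
class NeedResult:
    """Lives to save and their cost for one country over the horizon."""

    country_id: str
    years: list[int]
    lives_by_year: list[float]
    lives_total: float
    unit_cost: float
    need_usd: float


def annual_rate_of_reduction(
    baseline: float, target: float, n_years: int, mode: str = "geometric"
) -> float:
    """Constant yearly proportional reduction taking baseline to target.

    geometric: rate r with baseline * (1 - r)**n = target.
    continuous: r = 1 - exp(ln(target/baseline)/n), identical algebraically
    for the one-input case but kept explicit for config symmetry.
    """
    if baseline <= 0:
        raise ConfigError(f"baseline mortality must be positive, got {baseline}")
    if target >= baseline:
        return 0.0
    if mode == "continuous":
        return 1.0 - math.exp(math.log(target / baseline) / n_years)
    return 1.0 - (target / baseline) ** (1.0 / n_years)


def required_trajectory(
    baseline_u5mr: float,
    config: RunConfig,
    expected: ExpectedTrend,
) -> RequiredTrajectory:
    """Goal-compliant path for a country whose base-year rate is ``baseline_u5mr``.

    If the baseline exceeds the goal rate, the path declines geometrically so
    that it equals the goal exactly at the target year. If the country is
    already at or below the goal, the required path is the expected path
    capped at the goal, so no need is generated downstream.
    """
    if baseline_u5mr <= 0:
        raise ConfigError(f"baseline u5mr must be positive, got {baseline_u5mr}")
    years = expected.years
    target = config.goal_target_rate
    t0 = years[0] - 1  # base year precedes the first horizon year
    n = config.goal_target_year - t0
    if baseline_u5mr > target:
        arr = annual_rate_of_reduction(baseline_u5mr, target, n, config.arr_mode)
        path = [baseline_u5mr * (1.0 - arr) ** (y - t0) for y in years]
    else:
        arr = 0.0
        path = [min(e, target) for e in expected.u5mr_expected]
    return RequiredTrajectory(expected.country_id, list(years), path, arr)


def lives_to_save(
    expected: ExpectedTrend,
    required: RequiredTrajectory,
    panel: CountryYearPanel,
    config: RunConfig,
) -> pd.Series:
    """Additional under-five deaths to avert per year, floored at zero.

    lives(t) = max(0, u5mr_expected(t) - u5mr_required(t)) / 1000 * denom(t),
    with the denominator series (live births by default, total population as
    a config alternative) read from the panel.
    """
    if expected.years != required.years:
        raise AlignmentError(
            f"year mismatch for {expected.country_id}: "
            f"{expected.years} vs {required.years}"
        )
    col = "live_births" if config.denominator == "births" else "population"
    cdf = panel.country(expected.country_id).set_index("year")
    missing = [y for y in expected.years if y not in cdf.index or pd.isna(cdf.loc[y, col])]
    if missing:
        raise AlignmentError(
            f"{col} missing for {expected.country_id} in years {missing}"
        )
    denom = cdf.loc[expected.years, col].to_numpy(float)
    diff = np.asarray(expected.u5mr_expected) - np.asarray(required.u5mr_required)
    lives = np.maximum(0.0, diff) / 1000.0 * denom
    return pd.Series(lives, index=pd.Index(expected.years, name="year"), name="lives")


def compute_need(
    lives: pd.Series, income_group: str, config: RunConfig, country_id: str = ""
) -> NeedResult:
    """Need in USD: total lives to save times the income-group unit cost."""
    total = float(lives.sum())
    cost = config.cost_schedule.get(income_group)
    if cost is None:
        if total > 0:
            raise FgapsError(
                f"no cost per life saved defined for income group "
                f"{income_group!r} (country {country_id or '?'}) "
                f"but {total:.1f} lives to save"
            )
        cost = 0.0
    return NeedResult(
        country_id=country_id,
        years=[int(y) for y in lives.index],
        lives_by_year=[float(v) for v in lives],
        lives_total=total,
        unit_cost=float(cost),
        need_usd=total * float(cost),
    )


def need_to_frame(results: list[NeedResult]) -> pd.DataFrame:
    """Long-format need table: per-year lives plus country totals repeated."""
    rows = []
    for r in results:
        for y, l in zip(r.years, r.lives_by_year):
            rows.append((r.country_id, y, l, r.lives_total, r.unit_cost, r.need_usd))
    return pd.DataFrame(
        rows,
        columns=["country_id", "year", "lives", "lives_total", "unit_cost", "need_usd"],
    )
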